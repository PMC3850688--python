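"""5hmC site inference from PvuRts1I fragment ends, plus naive peak tools.

PvuRts1I cleaves double-stranded DNA at a fixed distance 3' of a
5-hydroxymethylcytosine: mostly 11-13 nucleotides away on the top strand
and 9-10 on the bottom strand.  Sequenced fragment ends therefore localise
5hmC sites: a top-strand cut at p votes for every cytosine at p - d
(d in the top offset set), a bottom-strand cut at p for every minus-strand
cytosine (reference G) at p + d.  Sites accumulating at least
``min_support`` votes are called.

Also provides a deliberately simple sliding-window peak caller for
synthetic immunoprecipitation coverage and a peak-concordance measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .refmodel import Genome
from .util import C, G

__all__ = [
    "HmcEvidence",
    "IntervalPeak",
    "infer_hmc_sites",
    "call_peaks_naive",
    "peak_concordance",
    "read_cuts_bed",
    "write_sites",
]


@dataclass(frozen=True)
class IntervalPeak:
    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("peak requires start < end")


class HmcEvidence:
    """Per-base, per-strand support counts for inferred 5hmC sites."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self._support = {
            (c, s): np.zeros(genome.length(c), dtype=np.int64)
            for c in genome
            for s in "+-"
        }
        self.n_skipped = 0  # out-of-bounds cut records

    def support_array(self, chrom: str, strand: str) -> np.ndarray:
        return self._support[(chrom, strand)]

    def support(self, chrom: str, pos: int, strand: str) -> int:
        return int(self._support[(chrom, strand)][pos])

    def to_frame(self, min_support: int = 1) -> pd.DataFrame:
        rows = []
        for (chrom, strand), arr in sorted(self._support.items()):
            pos = np.flatnonzero(arr >= min_support)
            if len(pos):
                rows.append(
                    pd.DataFrame(
                        {"chrom": chrom, "pos": pos, "strand": strand, "support": arr[pos]}
                    )
                )
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "strand", "support"])
        return (
            pd.concat(rows, ignore_index=True)
            .sort_values(["chrom", "pos", "strand"])
            .reset_index(drop=True)
        )


def infer_hmc_sites(
    cuts: pd.DataFrame,
    genome: Genome,
    offsets_top: Sequence[int] = (11, 12, 13),
    offsets_bottom: Sequence[int] = (9, 10),
    min_support: int = 2,
) -> tuple[HmcEvidence, pd.DataFrame]:
    """Accumulate cut-offset votes and call supported 5hmC candidate sites.

    A cut votes for ALL cytosines in its offset window (no probabilistic
    weighting); candidate positions that are not cytosines on the implied
    strand are silently skipped.  Cut positions outside the chromosome are
    skipped and counted in ``evidence.n_skipped``.
    """
    if not len(offsets_top) or not len(offsets_bottom):
        raise ValueError("offset sets must be non-empty")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    ev = HmcEvidence(genome)
    for chrom, grp in cuts.groupby("chrom", sort=False):
        if chrom not in genome:
            ev.n_skipped += len(grp)
            continue
        codes = genome.codes(chrom)
        L = len(codes)
        for strand, offsets, sign, base in (
            ("+", offsets_top, -1, C),
            ("-", offsets_bottom, +1, G),
        ):
            p = grp.loc[grp["strand"] == strand, "pos"].to_numpy()
            oob = (p < 0) | (p >= L)
            ev.n_skipped += int(oob.sum())
            p = p[~oob]
            sup = ev.support_array(chrom, strand)
            for d in offsets:
                q = p + sign * d
                ok = (q >= 0) & (q < L)
                q = q[ok]
                q = q[codes[q] == base]
                np.add.at(sup, q, 1)
    called = ev.to_frame(min_support=min_support)
    return ev, called


def _as_frame(peaks) -> pd.DataFrame:
    if isinstance(peaks, pd.DataFrame):
        return peaks
    return pd.DataFrame(
        [(p.chrom, p.start, p.end, p.score) for p in peaks],
        columns=["chrom", "start", "end", "score"],
    )


def call_peaks_naive(
    intervals: pd.DataFrame,
    genome: Genome,
    window: int = 200,
    min_fold: float = 2.0,
) -> list[IntervalPeak]:
    """Sliding-window enrichment peaks over fragment coverage.

    Per-base coverage is smoothed with a centred ``window``-base mean;
    maximal runs of positions exceeding ``min_fold`` times the genome-wide
    mean coverage become peaks scored by their maximum fold enrichment.
    A stand-in for external model-based peak callers, intended for
    synthetic data.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(intervals) == 0:
        return []
    total_len = sum(genome.lengths.values())
    cov = {}
    total_bases = 0
    for chrom, grp in intervals.groupby("chrom", sort=False):
        L = genome.length(chrom)
        diff = np.zeros(L + 1, dtype=np.int64)
        start = np.clip(grp["start"].to_numpy(), 0, L)
        end = np.clip(grp["end"].to_numpy(), 0, L)
        np.add.at(diff, start, 1)
        np.add.at(diff, end, -1)
        cov[chrom] = np.cumsum(diff[:-1])
        total_bases += int((end - start).sum())
    gmean = total_bases / total_len
    if gmean == 0:
        return []

    peaks = []
    half = window // 2
    for chrom, c in cov.items():
        L = len(c)
        cs = np.concatenate([[0], np.cumsum(c)])
        lo = np.clip(np.arange(L) - half, 0, L)
        hi = np.clip(np.arange(L) + window - half, 0, L)
        sm = (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)
        mask = sm > min_fold * gmean
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
        for s, e in zip(run_starts, run_ends):
            score = float(sm[s:e].max() / gmean)
            peaks.append(IntervalPeak(chrom, int(s), int(e), score))
    return peaks


def peak_concordance(
    peaks_a: Union[Sequence[IntervalPeak], pd.DataFrame],
    peaks_b: Union[Sequence[IntervalPeak], pd.DataFrame],
) -> float:
    """Fraction of A peaks overlapping at least one B peak (NaN if A empty)."""
    a = _as_frame(peaks_a)
    b = _as_frame(peaks_b)
    if len(a) == 0:
        return float("nan")
    if len(b) == 0:
        return 0.0
    hit = 0
    for chrom, grp in a.groupby("chrom", sort=False):
        bb = b[b["chrom"] == chrom].sort_values("start")
        if len(bb) == 0:
            continue
        bs = bb["start"].to_numpy()
        be = bb["end"].to_numpy()
        # max end among B peaks starting at or before each A end
        be_cummax = np.maximum.accumulate(be)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            i = np.searchsorted(bs, e, side="left") - 1
            if i >= 0 and be_cummax[i] > s:
                hit += 1
    return hit / len(a)


def read_cuts_bed(path: str | Path) -> pd.DataFrame:
    """Read fragment-end records from BED6 (strand column = cut strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"], "strand": df["strand"]}
    )


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    """Called-site TSV (chrom, pos 1-based, strand, support)."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)
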