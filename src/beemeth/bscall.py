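"""Three-level probabilistic methylation calling from bisulfite pileups.

The caller treats methylation like a diploid genotype: each strand-specific
cytosine site is methylated at level 0, 0.5 or 1 (none / hemi / full), and
the posterior over the three levels is computed from per-read C-retained
versus converted observations under a Bernoulli mixture:

    P(C | m) = m (1 - e) + (1 - m) (c (1 - e) + (1 - c) e)

with c the bisulfite non-conversion failure rate and e the per-base error
derived from the read base quality (floored).  The call is the maximum
a-posteriori level (ties broken toward the lower level), with a phred
quality Q = -10 log10(1 - posterior) capped at 255; calls with Q < 20 are
filtered.

Pileup construction applies two read-level filters: an observation is
discarded when the read mismatches the reference (in the reduced bisulfite
alphabet) within 2 bases of the cytosine, and optionally the whole read is
discarded when it carries three consecutive methylated CHH cytosines (the
"CHH filter"; off by default, matching the unbiased-caller mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bsalign import AlignedRead
from .refmodel import (
    CTX_CG,
    CTX_CHG,
    CTX_CHH,
    CTX_NONE,
    CONTEXT_NAMES,
    CytosineContext,
    Genome,
    context_code_arrays,
    partner_position,
)
from .util import A, C, G, T, revcomp

__all__ = [
    "CallModelParams",
    "MethylCall",
    "Pileup",
    "build_pileup",
    "chh_read_filter",
    "call_methylation",
    "call_all",
    "symmetric_calls",
    "write_calls",
    "read_calls",
]

LEVELS = (0.0, 0.5, 1.0)
MAX_Q = 255.0
PASS_Q = 20.0

CALL_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "trinucleotide",
    "level",
    "qual",
    "depth",
    "c_count",
    "t_count",
    "pass",
]


@dataclass
class CallModelParams:
    """Parameters of the three-level call model."""

    conv_fail: float = 0.005
    error_floor: float = 1e-4
    prior: tuple = (1 / 3, 1 / 3, 1 / 3)
    min_depth: int = 1

    def __post_init__(self):
        if not 0.0 <= self.conv_fail < 0.5:
            raise ValueError("conv_fail must be in [0, 0.5)")

    def error_rate(self, qual: float) -> float:
        return max(10.0 ** (-qual / 10.0), self.error_floor)


@dataclass
class MethylCall:
    chrom: Optional[str]
    pos: Optional[int]
    strand: Optional[str]
    context: Optional[str]
    level: float
    qual: float
    depth: int
    c_count: int
    t_count: int
    passed: bool
    posterior: tuple = ()


def p_retained(m: float, e: float, c: float) -> float:
    """Probability a read shows C at a level-m site (error e, non-conversion c)."""
    return m * (1 - e) + (1 - m) * (c * (1 - e) + (1 - c) * e)


class Pileup:
    """Per-site C-retained / converted observation counts, grouped by quality.

    Observations at the same site with the same base quality are
    exchangeable under the call model, so the pileup stores per-chromosome
    count arrays keyed by (strand, quality) rather than observation lists.
    ``observations`` reconstitutes the per-observation view.
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self._ret: dict[tuple[str, str, int], np.ndarray] = {}
        self._conv: dict[tuple[str, str, int], np.ndarray] = {}
        self.n_reads_used = 0
        self.n_reads_chh_filtered = 0

    def _arrays(self, chrom, strand, qual):
        key = (chrom, strand, int(qual))
        if key not in self._ret:
            L = self.genome.length(chrom)
            self._ret[key] = np.zeros(L, dtype=np.uint32)
            self._conv[key] = np.zeros(L, dtype=np.uint32)
        return self._ret[key], self._conv[key]

    def add(self, chrom, strand, qual, retained_pos, converted_pos):
        ret, conv = self._arrays(chrom, strand, qual)
        np.add.at(ret, retained_pos, 1)
        np.add.at(conv, converted_pos, 1)

    def quals(self, chrom, strand):
        return sorted(q for (c, s, q) in self._ret if c == chrom and s == strand)

    def counts(self, chrom, strand, qual):
        return self._ret[(chrom, strand, qual)], self._conv[(chrom, strand, qual)]

    def depth(self, chrom, strand) -> np.ndarray:
        L = self.genome.length(chrom)
        d = np.zeros(L, dtype=np.int64)
        for q in self.quals(chrom, strand):
            r, c = self.counts(chrom, strand, q)
            d += r
            d += c
        return d

    def observations(self, chrom, pos, strand) -> list[tuple[bool, int]]:
        """(evidence, quality) pairs at one site; evidence True = C-retained."""
        obs = []
        for q in self.quals(chrom, strand):
            r, c = self.counts(chrom, strand, q)
            obs += [(True, q)] * int(r[pos]) + [(False, q)] * int(c[pos])
        return obs


def chh_read_filter(cytosine_states: Iterable[tuple[str, bool]]) -> bool:
    """True (keep) unless >=3 consecutive CHH cytosines are all C-retained.

    ``cytosine_states`` are the read's cytosines in position order as
    (context class, retained) pairs; only CHH entries participate in the
    run, and non-CHH entries neither extend nor break it.
    """
    run = 0
    for ctx, retained in cytosine_states:
        if ctx != "CHH":
            continue
        run = run + 1 if retained else 0
        if run >= 3:
            return False
    return True


def build_pileup(
    alignments: Sequence[AlignedRead],
    genome: Genome,
    chh_filter: bool = False,
    mismatch_window: int = 2,
) -> Pileup:
    """Accumulate per-site evidence from unique alignments.

    On the plus strand a read C over a reference C is a retained
    observation and a read T is converted; on the minus strand the read is
    stored in forward orientation, so reference G with read G is retained
    and read A converted.  An observation is dropped when the read has a
    reduced-alphabet mismatch within ``mismatch_window`` bases of the
    cytosine; with ``chh_filter`` the whole read is dropped when it shows
    three consecutive methylated CHH cytosines.
    """
    pile = Pileup(genome)
    ctx_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    kernel = np.ones(2 * mismatch_window + 1)
    from .util import encode  # local import to avoid cycle at module load

    for aln in alignments:
        if not aln.unique:
            continue
        codes = genome.codes(aln.chrom)
        n = len(aln.sequence)
        if aln.start < 0 or aln.start + n > len(codes):
            raise ValueError(
                f"alignment {aln.read_id!r} beyond bounds of {aln.chrom}"
            )
        seg = codes[aln.start : aln.start + n]
        rarr = encode(aln.sequence)
        if aln.bs_strand == "+":
            red_g = np.where(seg == C, T, seg)
            red_r = np.where(rarr == C, T, rarr)
            target, conv_to = C, T
        else:
            red_g = np.where(seg == G, A, seg)
            red_r = np.where(rarr == G, A, rarr)
            target, conv_to = G, A
        mm = red_r != red_g
        cyt = seg == target
        retained = cyt & (rarr == target)
        converted = cyt & (rarr == conv_to)

        if chh_filter:
            if aln.chrom not in ctx_cache:
                ctx_cache[aln.chrom] = context_code_arrays(genome, aln.chrom)
            ctx = ctx_cache[aln.chrom][0 if aln.bs_strand == "+" else 1]
            cyt_idx = np.flatnonzero(retained | converted)
            states = [
                (CONTEXT_NAMES[code] if code != CTX_NONE else "NA", bool(retained[i]))
                for i, code in zip(cyt_idx, ctx[aln.start + cyt_idx])
            ]
            if not chh_read_filter(states):
                pile.n_reads_chh_filtered += 1
                continue

        if mm.any():
            near = np.convolve(mm.astype(float), kernel, mode="same") > 0
        else:
            near = np.zeros(n, dtype=bool)
        keep = ~near
        ret_pos = aln.start + np.flatnonzero(retained & keep)
        conv_pos = aln.start + np.flatnonzero(converted & keep)
        if len(ret_pos) == 0 and len(conv_pos) == 0:
            pile.n_reads_used += 1
            continue
        quals = aln.quals
        obs_mask = (retained | converted) & keep
        obs_quals = quals[obs_mask]
        for q in np.unique(obs_quals):
            qmask = quals == q
            pile.add(
                aln.chrom,
                aln.bs_strand,
                int(q),
                aln.start + np.flatnonzero(retained & keep & qmask),
                aln.start + np.flatnonzero(converted & keep & qmask),
            )
        pile.n_reads_used += 1
    return pile


def call_methylation(
    observations: Sequence[tuple[bool, int]],
    params: CallModelParams = CallModelParams(),
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
    strand: Optional[str] = None,
    context: Optional[str] = None,
) -> MethylCall:
    """Call one site from (retained, quality) observations.

    Log-space likelihood under the three-level Bernoulli mixture; maximum
    a-posteriori call with ties broken toward the lower level.
    """
    if not observations:
        raise ValueError("cannot call a site with zero depth")
    c = params.conv_fail
    ll = np.log(np.asarray(params.prior, dtype=float))
    n_ret = n_conv = 0
    for retained, q in observations:
        e = params.error_rate(q)
        for j, m in enumerate(LEVELS):
            pC = p_retained(m, e, c)
            p = pC if retained else 1.0 - pC
            ll[j] += math.log(p) if p > 0 else -math.inf
        if retained:
            n_ret += 1
        else:
            n_conv += 1
    lse = logsumexp(ll)
    post = np.exp(ll - lse)
    call = int(np.argmax(post))  # first max = lowest level on ties
    one_minus = max(1.0 - post[call], 10 ** (-MAX_Q / 10.0))
    q_phred = min(MAX_Q, -10.0 * math.log10(one_minus))
    depth = n_ret + n_conv
    return MethylCall(
        chrom,
        pos,
        strand,
        context,
        LEVELS[call],
        q_phred,
        depth,
        n_ret,
        n_conv,
        q_phred >= PASS_Q and depth >= params.min_depth,
        tuple(post),
    )


def call_all(
    pileup: Pileup,
    genome: Genome,
    params: CallModelParams = CallModelParams(),
) -> pd.DataFrame:
    """Vectorised three-level calls for every covered cytosine site.

    Returns a DataFrame (one row per site with depth >= 1 and a defined
    context) with the standard per-cytosine report columns.
    """
    frames = []
    c = params.conv_fail
    log_prior = np.log(np.asarray(params.prior, dtype=float))
    for chrom in pileup.genome:
        ctx_arrays = context_code_arrays(genome, chrom)
        seq = genome[chrom]
        for strand, ctx in zip("+-", ctx_arrays):
            quals = pileup.quals(chrom, strand)
            if not quals:
                continue
            depth = pileup.depth(chrom, strand)
            sites = np.flatnonzero(depth > 0)
            sites = sites[ctx[sites] != CTX_NONE]
            if len(sites) == 0:
                continue
            ll = np.tile(log_prior[:, None], (1, len(sites)))
            c_count = np.zeros(len(sites), dtype=np.int64)
            t_count = np.zeros(len(sites), dtype=np.int64)
            for q in quals:
                e = params.error_rate(q)
                r, cv = pileup.counts(chrom, strand, q)
                rs, cs = r[sites], cv[sites]
                c_count += rs
                t_count += cs
                for j, m in enumerate(LEVELS):
                    pC = p_retained(m, e, c)
                    with np.errstate(divide="ignore"):
                        ll[j] += rs * np.log(pC) + cs * np.log(1.0 - pC)
            lse = logsumexp(ll, axis=0)
            post = np.exp(ll - lse)
            call = np.argmax(post, axis=0)
            pcall = post[call, np.arange(len(sites))]
            one_minus = np.maximum(1.0 - pcall, 10 ** (-MAX_Q / 10.0))
            q_phred = np.minimum(MAX_Q, -10.0 * np.log10(one_minus))
            level = np.asarray(LEVELS)[call]
            dep = c_count + t_count
            if strand == "+":
                trinuc = [seq[p : p + 3] for p in sites]
            else:
                trinuc = [revcomp(seq[p - 2 : p + 1]) for p in sites]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": sites,
                        "strand": strand,
                        "context": np.asarray(CONTEXT_NAMES)[ctx[sites]],
                        "trinucleotide": trinuc,
                        "level": level,
                        "qual": q_phred,
                        "depth": dep,
                        "c_count": c_count,
                        "t_count": t_count,
                        "pass": (q_phred >= PASS_Q) & (dep >= params.min_depth),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )


def symmetric_calls(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Symmetric-methylation pairing of passing modified CG/CHG calls.

    A modified site is symmetric when its palindromic partner site is also
    a passing modified call.  The percentage denominator is all modified
    passing sites of the context, whether or not the partner is covered.
    CHH sites have no partner, so their symmetric percentage is 0 by
    construction (reported when CHH calls are present).
    """
    mod = calls[(calls["pass"]) & (calls["level"] > 0)]
    modified_keys = set(zip(mod["chrom"], mod["pos"], mod["strand"]))
    rows = []
    pct: dict[str, float] = {}
    for klass, step in (("CG", 1), ("CHG", 2)):
        sub = mod[mod["context"] == klass]
        if len(sub) == 0:
            continue
        ppos = np.where(sub["strand"] == "+", sub["pos"] + step, sub["pos"] - step)
        pstrand = np.where(sub["strand"] == "+", "-", "+")
        both = [
            (c, int(p), s) in modified_keys
            for c, p, s in zip(sub["chrom"], ppos, pstrand)
        ]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "strand": sub["strand"].to_numpy(),
                    "context": klass,
                    "partner_pos": ppos,
                    "partner_strand": pstrand,
                    "both_modified": both,
                }
            )
        )
        pct[klass] = 100.0 * float(np.mean(both)) if len(both) else float("nan")
    if (mod["context"] == "CHH").any():
        pct["CHH"] = 0.0
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "strand",
                "context",
                "partner_pos",
                "partner_strand",
                "both_modified",
            ]
        )
    )
    return table, pct


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Per-cytosine TSV report (1-based positions, documented header)."""
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df
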