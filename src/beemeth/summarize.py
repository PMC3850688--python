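"""Region x context summaries, metagene profiles, splice-junction analysis.

The summary tables have the shape of the classic modification-by-region
report: for every (region label, context class), the number of analyzed
(passing-called) cytosine sites, the number modified (level > 0, counting
hemi and full alike) and the percentage, rounded half-up to two decimals.
A site contributes to every region label it carries, so per-label counts
deliberately sum to more than the genome-wide totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .refmodel import (
    ACCEPTOR,
    DONOR,
    DOWNSTREAM,
    EXON,
    INTERGENIC,
    INTRAGENIC,
    INTRON,
    UPSTREAM,
    CONTEXT_NAMES,
    Gene,
    Genome,
    RegionIndex,
)
from .util import percent, revcomp

__all__ = [
    "summarize_by_region",
    "summarize_intervals_by_region",
    "metagene_profile",
    "splice_junction_methylation",
    "PanelSpec",
    "GenePanelSelection",
    "classify_genes_by_oe",
    "write_summary",
    "INTERVAL_PRECEDENCE",
]

# exclusive label precedence used when assigning whole intervals/reads
INTERVAL_PRECEDENCE = (
    ACCEPTOR,
    DONOR,
    EXON,
    INTRON,
    INTRAGENIC,
    UPSTREAM,
    DOWNSTREAM,
    INTERGENIC,
)


def summarize_by_region(
    calls: pd.DataFrame,
    index: RegionIndex,
    labels: Optional[Sequence[str]] = None,
    contexts: Sequence[str] = CONTEXT_NAMES,
) -> pd.DataFrame:
    """Per-(region, context) analyzed/modified counts and percentages.

    Only passing calls are counted; "modified" means call level > 0.  The
    percent column is NaN (written as "NA") when nothing was analyzed.
    """
    labels = list(labels) if labels is not None else list(index.labels)
    passing = calls[calls["pass"]] if "pass" in calls.columns else calls
    rows = []
    for context in contexts:
        sub = passing[passing["context"] == context]
        analyzed = {lab: 0 for lab in labels}
        modified = {lab: 0 for lab in labels}
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            mod = (grp["level"] > 0).to_numpy()
            for lab in labels:
                m = index.mask(chrom, lab, pos)
                analyzed[lab] += int(m.sum())
                modified[lab] += int((m & mod).sum())
        for lab in labels:
            rows.append(
                {
                    "Type": lab,
                    "Context": context,
                    "Analyzed": analyzed[lab],
                    "Methylated": modified[lab],
                    "Methylated %": percent(modified[lab], analyzed[lab]),
                }
            )
    return pd.DataFrame(rows)


def summarize_intervals_by_region(
    intervals: pd.DataFrame,
    index: RegionIndex,
    precedence: Sequence[str] = INTERVAL_PRECEDENCE,
) -> pd.DataFrame:
    """Assign each interval (or read) to one region label by its midpoint.

    Intervals are tallied exclusively: the midpoint's highest-precedence
    label wins, so the percentages sum to 100.  Empty input gives an empty
    table.
    """
    if len(intervals) == 0:
        return pd.DataFrame(columns=["Type", "Count", "Percent"])
    counts = {lab: 0 for lab in precedence}
    counts["None"] = 0
    for chrom, grp in intervals.groupby("chrom", sort=False):
        if "start" in grp.columns and "end" in grp.columns:
            mid = ((grp["start"].to_numpy() + grp["end"].to_numpy() - 1) // 2)
        else:
            mid = grp["pos"].to_numpy()
        assigned = np.zeros(len(mid), dtype=bool)
        for lab in precedence:
            m = index.mask(chrom, lab, mid) & ~assigned
            counts[lab] += int(m.sum())
            assigned |= m
        counts["None"] += int((~assigned).sum())
    total = sum(counts.values())
    rows = [
        {"Type": lab, "Count": n, "Percent": percent(n, total)}
        for lab, n in counts.items()
        if n > 0 or lab != "None"
    ]
    return pd.DataFrame(rows)


def metagene_profile(
    calls: pd.DataFrame,
    genes: Sequence[Gene],
    nbins: int = 30,
    flank: int = 3000,
    min_covered: int = 100,
) -> dict[str, pd.DataFrame]:
    """Binned modification profiles over upstream / exons / introns / downstream.

    Every feature is scaled to ``nbins`` equal spans ordered in
    transcription direction (bins of minus-strand genes run opposite to
    genome coordinates).  Genes with fewer than ``min_covered`` covered
    cytosines in gene body plus upstream flank are excluded.  Features
    shorter than ``nbins`` spread their bases over bins proportionally.
    Returns per-feature DataFrames with analyzed/modified counts and the
    per-bin modified/analyzed ratio, pooled over genes.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    features = ("upstream", "exon", "intron", "downstream")
    analyzed = {f: np.zeros(nbins, dtype=np.int64) for f in features}
    modified = {f: np.zeros(nbins, dtype=np.int64) for f in features}

    passing = calls[calls["pass"]] if "pass" in calls.columns else calls
    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in passing.groupby("chrom", sort=False)
    }

    def take(chrom, a, b):
        grp = by_chrom.get(chrom)
        if grp is None:
            return np.array([], dtype=np.int64), np.array([], dtype=bool)
        pos = grp["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [a, b])
        return pos[lo:hi], (grp["level"].to_numpy()[lo:hi] > 0)

    for gene in genes:
        gs, ge = gene.span
        if gene.strand == "+":
            up_iv = (max(0, gs - flank), gs)
            down_iv = (ge, ge + flank)
        else:
            up_iv = (ge, ge + flank)
            down_iv = (max(0, gs - flank), gs)
        body_pos, _ = take(gene.chrom, gs, ge)
        up_pos, _ = take(gene.chrom, *up_iv)
        if len(body_pos) + len(up_pos) < min_covered:
            continue
        tr = max(gene.transcripts, key=lambda t: t.span[1] - t.span[0])
        feature_ivals = (
            [("upstream", up_iv)]
            + [("exon", iv) for iv in tr.exons]
            + [("intron", iv) for iv in tr.introns]
            + [("downstream", down_iv)]
        )
        for fname, (a, b) in feature_ivals:
            if b <= a:
                continue
            pos, mod = take(gene.chrom, a, b)
            if len(pos) == 0:
                continue
            off = pos - a if gene.strand == "+" else (b - 1) - pos
            bins = (off * nbins) // (b - a)
            np.add.at(analyzed[fname], bins, 1)
            np.add.at(modified[fname], bins, mod.astype(np.int64))

    out = {}
    for f in features:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(analyzed[f] > 0, modified[f] / np.maximum(analyzed[f], 1), np.nan)
        out[f] = pd.DataFrame(
            {
                "bin": np.arange(nbins),
                "analyzed": analyzed[f],
                "modified": modified[f],
                "ratio": ratio,
            }
        )
    return out


def splice_junction_methylation(
    calls: pd.DataFrame,
    genes: Sequence[Gene],
    genome: Genome,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Template-strand cytosine modification at splice donor/acceptor sites.

    The template strand is the strand complementary to the pre-mRNA.  At a
    canonical donor the sense strand reads GT, i.e. the template reads AC
    and its C sits opposite the sense G (the -1 template position); at a
    canonical acceptor the sense AG corresponds to template CT with the C
    opposite the sense G (the +1 template position).  A record is emitted
    for every junction whose template cytosine carries a passing modified
    call, whatever the actual motif; the summary counts how many modified
    junctions are canonical (GT donors / AG acceptors).
    """
    passing = calls[(calls["pass"]) & (calls["level"] > 0)]
    modified = set(zip(passing["chrom"], passing["pos"], passing["strand"]))
    rows = []
    for gene in genes:
        seq = genome[gene.chrom]
        for tr in gene.transcripts:
            for (s, e) in tr.introns:
                if gene.strand == "+":
                    junctions = [
                        ("donor", s, "-", seq[s : s + 2]),
                        ("acceptor", e - 1, "-", seq[e - 2 : e]),
                    ]
                else:
                    junctions = [
                        ("donor", e - 1, "+", revcomp(seq[e - 2 : e])),
                        ("acceptor", s, "+", revcomp(seq[s : s + 2])),
                    ]
                for kind, cpos, tstrand, sense in junctions:
                    if (gene.chrom, cpos, tstrand) in modified:
                        rows.append(
                            {
                                "gene_id": gene.id,
                                "junction": kind,
                                "intron_start": s,
                                "intron_end": e,
                                "template_c_pos": cpos,
                                "template_strand": tstrand,
                                "motif_sense": sense,
                                "motif_template": revcomp(sense),
                            }
                        )
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "junction",
            "intron_start",
            "intron_end",
            "template_c_pos",
            "template_strand",
            "motif_sense",
            "motif_template",
        ],
    )
    summary_rows = []
    for kind, canon in (("donor", "GT"), ("acceptor", "AG")):
        sub = records[records["junction"] == kind]
        n_can = int((sub["motif_sense"] == canon).sum())
        summary_rows.append(
            {
                "junction": kind,
                "modified": len(sub),
                "canonical": n_can,
                "canonical_fraction": n_can / len(sub) if len(sub) else float("nan"),
            }
        )
    return records, pd.DataFrame(summary_rows)


@dataclass(frozen=True)
class PanelSpec:
    """Gene-panel selection rule over one (region, context) restriction.

    ``op`` is '>', '<' or '=' applied to the gene's modification percent;
    ``min_sites`` is the minimum number of analyzed sites for a gene to be
    eligible (the guard that keeps sparsely covered genes out of the
    zero-percent panels).
    """

    panel_id: str
    context: str
    region: str  # "exon" or "intron"
    op: str
    value: float
    min_sites: int = 0


@dataclass
class GenePanelSelection:
    panel_id: str
    description: str
    genes: pd.DataFrame  # gene_id, oe, analyzed, modified, percent


def classify_genes_by_oe(
    calls: pd.DataFrame,
    genes: Sequence[Gene],
    oe: dict[str, float],
    panel: PanelSpec,
) -> GenePanelSelection:
    """Select genes by per-gene modification percent; report their o/e ratios.

    A gene's percent is 100 * modified / analyzed over passing calls of the
    panel's context restricted to the gene's own exons or introns.
    """
    if panel.context not in CONTEXT_NAMES:
        raise ValueError(f"unknown context {panel.context!r}")
    if panel.region not in ("exon", "intron"):
        raise ValueError(f"unknown region {panel.region!r} (use 'exon' or 'intron')")
    if panel.op not in (">", "<", "="):
        raise ValueError(f"unknown comparison {panel.op!r}")

    passing = calls[(calls["pass"]) & (calls["context"] == panel.context)]
    by_chrom = {}
    for chrom, grp in passing.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        mod = np.concatenate([[0], np.cumsum((grp["level"].to_numpy() > 0))])
        by_chrom[chrom] = (pos, mod)

    rows = []
    for gene in genes:
        if gene.chrom not in by_chrom:
            analyzed = modified = 0
        else:
            pos, modcum = by_chrom[gene.chrom]
            analyzed = modified = 0
            for tr in gene.transcripts:
                ivals = tr.exons if panel.region == "exon" else tr.introns
                for a, b in ivals:
                    lo, hi = np.searchsorted(pos, [a, b])
                    analyzed += int(hi - lo)
                    modified += int(modcum[hi] - modcum[lo])
        if analyzed < max(panel.min_sites, 1):
            continue
        pct = 100.0 * modified / analyzed
        keep = (
            pct > panel.value
            if panel.op == ">"
            else pct < panel.value
            if panel.op == "<"
            else pct == panel.value
        )
        if keep:
            rows.append(
                {
                    "gene_id": gene.id,
                    "oe": oe.get(gene.id, float("nan")),
                    "analyzed": analyzed,
                    "modified": modified,
                    "percent": pct,
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "oe", "analyzed", "modified", "percent"])
    desc = (
        f"{panel.context} in {panel.region}s {panel.op} {panel.value}% "
        f"(>= {panel.min_sites} analyzed sites)"
    )
    return GenePanelSelection(panel.panel_id, desc, df)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """TSV with the table dialect headers; NaN percents written as NA."""
    summary.to_csv(path, sep="\t", index=False, na_rep="NA")
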