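"""Differential-modification statistics.

Per-gene 2x2 Fisher exact tests, Wilcoxon rank-sum gene-set enrichment in
a fixed and a greedy (best prefix cutoff, permutation-corrected) variant,
classic quantile normalization of count profiles, and Benjamini-Hochberg
FDR.  The greedy procedure scans every prefix cutoff of the score-ranked
gene list, takes the cutoff where set members are most enriched above it
(standardized rank-sum of the membership indicator between prefix and
suffix), and corrects the resulting selection bias by permuting the set
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .refmodel import Gene

__all__ = [
    "EnrichmentResult",
    "fisher_test_2x2",
    "ranksum_enrichment",
    "quantile_normalize",
    "bh_fdr",
    "gene_count_profile",
    "differential_genes",
    "read_gene_sets",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    unit_id: str
    statistic: float
    p_value: float
    q_value: Optional[float] = None
    direction: str = "none"
    cutoff: Optional[int] = None
    n_dropped: int = 0


def fisher_test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns (sample odds ratio a*d / b*c, p).  The two-sided p sums the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's.  A fully empty table returns
    (nan, nan); an odds ratio with zero denominator is inf (or nan when
    the numerator is zero as well).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return float("nan"), float("nan")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsr = float("nan") if a * d == 0 else float("inf")
    else:
        oddsr = (a * d) / (b * c)
    return oddsr, float(p)


def _greedy_scan(member: np.ndarray) -> tuple[float, int]:
    """Best standardized prefix-enrichment statistic over all cutoffs.

    ``member`` is the membership indicator ordered by descending score.
    At cutoff k the statistic is the standardized rank-sum of the binary
    indicator between the top-k prefix and the suffix (equivalently a
    finite-population z for the member count in the prefix); the scan
    returns the maximum and its cutoff.
    """
    n = len(member)
    m_total = int(member.sum())
    k = np.arange(1, n)
    m_k = np.cumsum(member)[:-1].astype(float)
    mean = k * m_total / n
    var = k * (n - k) * m_total * (n - m_total) / (n**2 * (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m_k - mean) / np.sqrt(var)
    z = np.where(var > 0, z, -np.inf)
    best = int(np.argmax(z))
    return float(z[best]), int(k[best])


def ranksum_enrichment(
    scores: Mapping[str, float] | pd.Series,
    gene_set: set,
    mode: str = "fixed",
    set_id: str = "set",
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Wilcoxon rank-sum enrichment of a gene set within a scored gene list.

    fixed mode: standard two-sample two-sided rank-sum of member versus
    non-member scores (exact enumeration when both groups have <= 10
    untied values, normal approximation with tie correction otherwise).

    greedy mode: genes are ranked by descending score and the one-sided
    prefix-enrichment statistic is maximized over every cutoff; the
    reported p-value is corrected for that cutoff search by label
    permutation (``n_perm`` permutations, seeded).

    Set members missing from the score list are dropped with a logged count.
    """
    scores = pd.Series(scores, dtype=float)
    members_present = set(scores.index) & set(gene_set)
    n_dropped = len(gene_set) - len(members_present)
    if n_dropped:
        logger.warning("%d gene-set members missing from score list", n_dropped)
    if not members_present:
        raise ValueError("gene set has no members in the score list")
    if len(members_present) == len(scores):
        raise ValueError("gene set covers the whole score list")
    member = scores.index.isin(members_present)

    if mode == "fixed":
        x = scores[member].to_numpy()
        y = scores[~member].to_numpy()
        have_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 10 and len(y) <= 10 and not have_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        direction = "up" if np.median(x) > np.median(y) else "down"
        return EnrichmentResult(
            set_id, float(res.statistic), float(res.pvalue), None, direction, None, n_dropped
        )

    if mode != "greedy":
        raise ValueError(f"unknown mode {mode!r}")

    order = np.argsort(-scores.to_numpy(), kind="stable")
    ind = member[order].astype(float)
    z_obs, cutoff = _greedy_scan(ind)

    rng = np.random.default_rng(seed)
    n = len(ind)
    m_total = int(ind.sum())
    k = np.arange(1, n)
    mean = k * m_total / n
    var = k * (n - k) * m_total * (n - m_total) / (n**2 * (n - 1))
    sd = np.sqrt(np.where(var > 0, var, np.inf))
    perms = rng.permuted(np.tile(ind, (n_perm, 1)), axis=1)
    m_k = np.cumsum(perms, axis=1)[:, :-1]
    z_perm = ((m_k - mean) / sd).max(axis=1)
    p = (1 + int((z_perm >= z_obs).sum())) / (n_perm + 1)
    return EnrichmentResult(set_id, z_obs, float(p), None, "up", cutoff, n_dropped)


def quantile_normalize(matrix) -> pd.DataFrame | np.ndarray:
    """Classic quantile normalization across columns (samples).

    Each column is mapped through its ranks onto the across-column mean of
    the sorted values; tied entries receive the mean of the rank-averaged
    values (average ranks interpolate between adjacent sorted means).
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_count_profile(
    calls: pd.DataFrame,
    genes: Sequence[Gene],
    region: Optional[str] = None,
    context: Optional[str] = None,
) -> pd.DataFrame:
    """(modified, analyzed) passing-call counts per gene.

    ``region`` restricts to the gene's exons or introns; ``context`` to one
    context class.  The backbone of the per-gene differential tests.
    """
    sub = calls[calls["pass"]]
    if context is not None:
        sub = sub[sub["context"] == context]
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        mod = np.concatenate([[0], np.cumsum(grp["level"].to_numpy() > 0)])
        by_chrom[chrom] = (pos, mod)
    rows = []
    for gene in genes:
        analyzed = modified = 0
        if gene.chrom in by_chrom:
            pos, modcum = by_chrom[gene.chrom]
            for tr in gene.transcripts:
                if region == "exon":
                    ivals = tr.exons
                elif region == "intron":
                    ivals = tr.introns
                elif region is None:
                    ivals = (tr.span,)
                else:
                    raise ValueError(f"unknown region {region!r}")
                for a, b in ivals:
                    lo, hi = np.searchsorted(pos, [a, b])
                    analyzed += int(hi - lo)
                    modified += int(modcum[hi] - modcum[lo])
        rows.append({"gene_id": gene.id, "modified": modified, "analyzed": analyzed})
    return pd.DataFrame(rows).set_index("gene_id")


def differential_genes(
    profile_a: pd.DataFrame, profile_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Fisher tests between two samples with BH-FDR across genes.

    Each gene's table is (modified, unmodified) x (sample A, sample B);
    genes absent from either profile or with zero analyzed sites in both
    are skipped.
    """
    common = profile_a.index.intersection(profile_b.index)
    rows = []
    for g in common:
        ma, na = int(profile_a.loc[g, "modified"]), int(profile_a.loc[g, "analyzed"])
        mb, nb = int(profile_b.loc[g, "modified"]), int(profile_b.loc[g, "analyzed"])
        if na == 0 and nb == 0:
            continue
        oddsr, p = fisher_test_2x2(ma, na - ma, mb, nb - mb)
        rows.append(
            {
                "gene_id": g,
                "odds_ratio": oddsr,
                "p_value": p,
                "direction": "up" if (ma / na if na else 0) > (mb / nb if nb else 0) else "down",
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "odds_ratio", "p_value", "direction"])
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    else:
        df["q_value"] = []
    return df.set_index("gene_id")


def read_gene_sets(path) -> dict[str, set]:
    """Two-column TSV (set-id, gene-id) -> {set-id: {gene ids}}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene_id"])
    return {k: set(v) for k, v in df.groupby("set_id")["gene_id"]}
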