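"""Synthetic-data generator for the whole pipeline.

Emulates: a gene-bearing genome whose two gene classes differ in CpG
density (so the observed/expected CpG ratio is bimodal, modes near 0.6 and
1.2); a planted methylome with region- and context-dependent 5mC/5hmC
rates (high CG methylation in exons, high non-CG modification in introns);
bisulfite reads with a non-conversion failure rate and sequencing error;
PvuRts1I double-strand cuts at fixed offsets 3' of planted 5hmC sites
(11-13 nt on the top strand, 9-10 nt on the bottom strand); and 300-600 bp
immunoprecipitation fragments.

Every operation is deterministic given (seed, config): each operation
derives its own numpy Generator from the config seed and a fixed
per-operation salt, so the outputs do not depend on call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import refmodel
from .refmodel import (
    CTX_CG,
    CTX_CHG,
    CTX_CHH,
    CTX_NONE,
    CONTEXT_NAMES,
    Gene,
    Genome,
    Transcript,
    build_region_index,
    context_code_arrays,
)
from .util import A, C, G, N, T, decode, revcomp

__all__ = [
    "SimConfig",
    "MethylomeTruth",
    "FastqRead",
    "ehb_like_rates",
    "simulate_genome",
    "plant_methylome",
    "simulate_bs_reads",
    "simulate_pvu_digestion",
    "simulate_dip_fragments",
    "read_fastq",
    "write_fastq",
    "write_bed",
]

UNMODIFIED, MC, HMC = 0, 1, 2
STATE_NAMES = {UNMODIFIED: "unmodified", MC: "5mC", HMC: "5hmC"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

# fixed per-operation RNG salts (documented draw independence)
_SALT_GENOME, _SALT_METH, _SALT_BS, _SALT_PVU, _SALT_DIP = 1, 2, 3, 4, 5

# regions consulted, in precedence order, when looking up modification rates
RATE_REGIONS = (
    refmodel.EXON,
    refmodel.INTRON,
    refmodel.UPSTREAM,
    refmodel.DOWNSTREAM,
    refmodel.INTERGENIC,
    refmodel.INTRAGENIC,
)


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


def ehb_like_rates() -> dict:
    """Default (region, context) -> state -> probability table.

    The pattern mirrors a European-honey-bee-like head methylome: CG
    methylation concentrated in exons (6.26%), non-CG modification
    concentrated in introns (CHH 3.99%, CHG 1.08%) with the intronic non-CG
    signal carried half by 5hmC, and intermediate levels in flanks and
    intergenic sequence.
    """
    r = {}

    def put(region, context, mc, hmc=0.0):
        r[(region, context)] = {"5mC": mc, "5hmC": hmc}

    put(refmodel.EXON, "CG", 0.0626)
    put(refmodel.EXON, "CHG", 0.0112)
    put(refmodel.EXON, "CHH", 0.0233)
    put(refmodel.INTRON, "CG", 0.0109)
    put(refmodel.INTRON, "CHG", 0.0054, 0.0054)
    put(refmodel.INTRON, "CHH", 0.0200, 0.0199)
    put(refmodel.UPSTREAM, "CG", 0.0356)
    put(refmodel.UPSTREAM, "CHG", 0.0126)
    put(refmodel.UPSTREAM, "CHH", 0.0346)
    put(refmodel.DOWNSTREAM, "CG", 0.0397)
    put(refmodel.DOWNSTREAM, "CHG", 0.0135)
    put(refmodel.DOWNSTREAM, "CHH", 0.0364)
    put(refmodel.INTERGENIC, "CG", 0.0107)
    put(refmodel.INTERGENIC, "CHG", 0.0110)
    put(refmodel.INTERGENIC, "CHH", 0.0300, 0.0107)
    # gene hull outside any transcript span: treat like intron
    put(refmodel.INTRAGENIC, "CG", 0.0109)
    put(refmodel.INTRAGENIC, "CHG", 0.0054, 0.0054)
    put(refmodel.INTRAGENIC, "CHH", 0.0200, 0.0199)
    return r


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults follow the emulated study design: 76 bp reads at 20-fold
    coverage, bisulfite non-conversion 0.005, sequencing error 0.001,
    PvuRts1I offsets {11,12,13} top / {9,10} bottom, 300-600 bp DIP
    fragments, 3 kb flanks, 2 bp splice-site windows, and a 21% chance that
    a modified CG site carries the modification on its partner strand too.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_genes: int = 100
    coverage: float = 20.0
    read_length: int = 76
    conv_fail: float = 0.005
    seq_error: float = 0.001
    rates: dict = field(default_factory=ehb_like_rates)
    hemi_fraction: float = 0.2
    cg_comod: float = 0.21
    read_quality: int = 40
    pvu_offsets_top: tuple = (11, 12, 13)
    pvu_offsets_bottom: tuple = (9, 10)
    pvu_background_cut_rate: float = 0.0
    pvu_mean_frags: Optional[float] = None  # None -> coverage
    dip_fragment_range: tuple = (300, 600)
    dip_mean_frags: float = 10.0
    dip_background_rate: float = 0.0
    flank: int = 3000
    splice_site: int = 2
    gc_content: float = 0.35
    oe_low: float = 0.6
    oe_high: float = 1.2

    def __post_init__(self):
        for p in (self.conv_fail, self.seq_error, self.hemi_fraction, self.cg_comod):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.pvu_offsets_top or not self.pvu_offsets_bottom:
            raise ValueError("offset sets must be non-empty")
        lo, hi = self.dip_fragment_range
        if not lo < hi:
            raise ValueError("dip fragment range must satisfy low < high")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])


class MethylomeTruth:
    """Planted ground truth: per-strand state and level arrays per chromosome.

    state is 0 (unmodified), 1 (5mC) or 2 (5hmC); level is 0, 0.5 or 1 and
    is 0 exactly when the site is unmodified.  Level 0.5 means the site is
    modified in half of the molecules of its own strand (hemi-modification
    as seen by the three-level caller).
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self._state = {
            (c, s): np.zeros(genome.length(c), dtype=np.uint8)
            for c in genome
            for s in "+-"
        }
        self._level = {
            (c, s): np.zeros(genome.length(c), dtype=np.float32)
            for c in genome
            for s in "+-"
        }

    def state_array(self, chrom: str, strand: str) -> np.ndarray:
        return self._state[(chrom, strand)]

    def level_array(self, chrom: str, strand: str) -> np.ndarray:
        return self._level[(chrom, strand)]

    def set_site(self, chrom, pos, strand, state, level):
        if state == UNMODIFIED and level != 0:
            raise ValueError("unmodified site must have level 0")
        if state != UNMODIFIED and level not in (0.5, 1.0):
            raise ValueError("modified site level must be 0.5 or 1")
        self._state[(chrom, strand)][pos] = state
        self._level[(chrom, strand)][pos] = level

    def state(self, chrom, pos, strand) -> int:
        return int(self._state[(chrom, strand)][pos])

    def level(self, chrom, pos, strand) -> float:
        return float(self._level[(chrom, strand)][pos])

    def sites(self, state: Optional[int] = None) -> pd.DataFrame:
        """All modified sites (optionally one state) as a DataFrame."""
        rows = []
        for (chrom, strand), arr in self._state.items():
            mask = arr > 0 if state is None else arr == state
            pos = np.flatnonzero(mask)
            if len(pos) == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "state": [STATE_NAMES[s] for s in arr[pos]],
                        "level": self._level[(chrom, strand)][pos].astype(float),
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "strand", "state", "level"])
        return (
            pd.concat(rows, ignore_index=True)
            .sort_values(["chrom", "pos", "strand"])
            .reset_index(drop=True)
        )

    def hmc_sites(self) -> pd.DataFrame:
        return self.sites(state=HMC)

    def to_tsv(self, path: str | Path) -> None:
        """Write the truth table (1-based positions) with context annotation."""
        df = self.sites()
        ctx = []
        for chrom, grp in df.groupby("chrom", sort=False):
            plus, minus = context_code_arrays(self.genome, chrom)
            for _, row in grp.iterrows():
                arr = plus if row.strand == "+" else minus
                code = arr[row.pos]
                ctx.append(CONTEXT_NAMES[code] if code != CTX_NONE else "NA")
        df = df.assign(context=ctx)
        df["pos"] = df["pos"] + 1
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------


def _adjust_cpg(seq: np.ndarray, lo: int, hi: int, target_oe: float, rng) -> None:
    """Mutate seq[lo:hi] in place so its CpG o/e ratio approaches target_oe."""
    sub = seq[lo:hi]
    L = hi - lo
    nc = int((sub == C).sum())
    ng = int((sub == G).sum())
    if nc == 0 or ng == 0:
        return
    expected = nc * ng / L
    cg_pos = np.flatnonzero((sub[:-1] == C) & (sub[1:] == G))
    target = int(round(target_oe * expected))
    if len(cg_pos) > target:
        kill = rng.choice(cg_pos, size=len(cg_pos) - target, replace=False)
        sub[kill + 1] = T  # CG -> CT
    elif len(cg_pos) < target:
        need = target - len(cg_pos)
        cand = rng.permutation(L - 1)
        placed = 0
        for p in cand:
            if placed >= need:
                break
            if sub[p] == C and sub[p + 1] == G:
                continue
            # avoid creating an overlapping second CG
            sub[p] = C
            sub[p + 1] = G
            placed += 1


def simulate_genome(config: SimConfig) -> tuple[Genome, list[Gene]]:
    """Random genome with non-overlapping multi-exon genes in two CpG classes.

    Genes alternate between a CpG-poor class (o/e near ``config.oe_low``)
    and a CpG-rich class (near ``config.oe_high``), so the o/e distribution
    over genes is bimodal.  Intron boundaries carry canonical GT...AG splice
    motifs on the sense strand.  Deterministic given the config seed.
    """
    rng = config.rng(_SALT_GENOME)
    L = config.genome_length
    probs = [
        (1 - config.gc_content) / 2,
        config.gc_content / 2,
        config.gc_content / 2,
        (1 - config.gc_content) / 2,
    ]
    seq = rng.choice(4, size=L, p=probs).astype(np.uint8)

    # draw gene structures
    structures = []
    total_span = 0
    for _ in range(config.n_genes):
        n_exons = int(rng.integers(2, 7))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(150, 801, size=n_exons - 1)
        structures.append((exon_lens, intron_lens))
        total_span += int(exon_lens.sum() + intron_lens.sum())

    min_gap = 200
    free = L - total_span - (config.n_genes + 1) * min_gap
    if config.n_genes and free < 0:
        raise ValueError(
            f"cannot pack {config.n_genes} genes (total span {total_span}) "
            f"into {L} bases"
        )

    genes: list[Gene] = []
    if config.n_genes:
        extra = rng.multinomial(free, np.ones(config.n_genes + 1) / (config.n_genes + 1))
        cursor = 0
        for i, (exon_lens, intron_lens) in enumerate(structures):
            cursor += min_gap + int(extra[i])
            start = cursor
            exons = []
            p = start
            for j, el in enumerate(exon_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if j < len(intron_lens):
                    p += int(intron_lens[j])
            cursor = p
            strand = "+" if rng.random() < 0.5 else "-"
            target_oe = config.oe_low if i % 2 == 0 else config.oe_high
            _adjust_cpg(seq, start, p, target_oe, rng)
            # canonical splice motifs on the sense strand (GT...AG)
            tr = Transcript(f"g{i:04d}.t1", tuple(exons), tuple(exons))
            for (a, b) in tr.introns:
                if strand == "+":
                    seq[a], seq[a + 1] = G, T  # donor GT
                    seq[b - 2], seq[b - 1] = A, G  # acceptor AG
                else:
                    seq[b - 2], seq[b - 1] = A, C  # sense GT on minus strand
                    seq[a], seq[a + 1] = C, T  # sense AG on minus strand
            genes.append(Gene(f"g{i:04d}", "chr1", strand, (tr,)))

    genome = Genome({"chr1": decode(seq)})
    return genome, genes


# ---------------------------------------------------------------------------
# methylome planting
# ---------------------------------------------------------------------------


def plant_methylome(
    genome: Genome,
    genes: Sequence[Gene],
    config: SimConfig,
    index: Optional[refmodel.RegionIndex] = None,
) -> MethylomeTruth:
    """Assign a modification state to every defined cytosine site.

    Each strand-specific cytosine draws its state independently from the
    (region, context) rate table; the region is the first matching label in
    precedence order Exon > Intron > Upstream > Downstream > Intergenic >
    Intragenic.  Modified sites are hemi (level 0.5) with probability
    ``hemi_fraction``, else fully modified (level 1).

    CG sites are planted pair-wise so that the marginal per-site
    modification probability equals the (region, context) rate while a
    fraction ``cg_comod`` of modified CG sites carry the modification on
    the partner strand as well: a pair is modified on both strands with
    probability ``cg_comod * r`` and on a single random strand with
    probability ``(1 - cg_comod) * r`` each.  The pair draws its rate from
    the plus-strand site's region.
    """
    rng = config.rng(_SALT_METH)
    if index is None:
        index = build_region_index(
            genes, genome, flank=config.flank, splice_site=config.splice_site
        )
    truth = MethylomeTruth(genome)

    def rates_for(key):
        if key not in config.rates:
            raise KeyError(f"rate table is missing the key {key!r}")
        p_mc = config.rates[key].get("5mC", 0.0)
        p_hmc = config.rates[key].get("5hmC", 0.0)
        if p_mc + p_hmc > 1.0:
            raise ValueError(f"rates for {key!r} sum above 1")
        return p_mc, p_hmc

    def draw_levels(n):
        return np.where(rng.random(n) < config.hemi_fraction, 0.5, 1.0).astype(
            np.float32
        )

    for chrom in genome:
        L = genome.length(chrom)
        ctx_p, ctx_m = context_code_arrays(genome, chrom)

        def region_ids(pos):
            rid = np.full(len(pos), -1, dtype=np.int8)
            for i in range(len(RATE_REGIONS) - 1, -1, -1):
                m = index.mask(chrom, RATE_REGIONS[i], pos)
                rid[m] = i
            if (rid < 0).any():
                bad = pos[rid < 0][0]
                raise ValueError(f"position {chrom}:{bad} carries no rated region label")
            return rid

        # CG pairs with both strand contexts defined and a shared region are
        # planted jointly; pairs straddling a region boundary fall back to
        # independent per-site draws at their own rates
        pair = np.flatnonzero(ctx_p == CTX_CG)
        pair = pair[pair + 1 < L]
        pair = pair[ctx_m[pair + 1] == CTX_CG]
        if len(pair):
            pair = pair[region_ids(pair) == region_ids(pair + 1)]
        paired_plus = np.zeros(L, dtype=bool)
        paired_minus = np.zeros(L, dtype=bool)
        paired_plus[pair] = True
        paired_minus[pair + 1] = True

        # independent draws: non-CG sites, and CG sites without a defined partner
        for strand, ctx, paired in (("+", ctx_p, paired_plus), ("-", ctx_m, paired_minus)):
            pos = np.flatnonzero(ctx != CTX_NONE)
            pos = pos[~paired[pos]]
            if len(pos) == 0:
                continue
            rid = region_ids(pos)
            state = truth.state_array(chrom, strand)
            level = truth.level_array(chrom, strand)
            u = rng.random(len(pos))
            for i, region in enumerate(RATE_REGIONS):
                for code, cname in enumerate(CONTEXT_NAMES):
                    sel = (rid == i) & (ctx[pos] == code)
                    if not sel.any():
                        continue
                    p_mc, p_hmc = rates_for((region, cname))
                    psel, usel = pos[sel], u[sel]
                    state[psel[usel < p_mc]] = MC
                    state[psel[(usel >= p_mc) & (usel < p_mc + p_hmc)]] = HMC
            mod = np.flatnonzero(state > 0)
            if len(mod):
                level[mod] = draw_levels(len(mod))

        # joint CG-pair draw: each strand's marginal equals the table rate;
        # P(both strands modified) = max(cg_comod * r, 2r - 1), the Frechet
        # lower bound taking over only for (unrealistically) high rates.
        if len(pair):
            rid = region_ids(pair)
            f = config.cg_comod
            u = rng.random(len(pair))  # plus-strand draw
            v = rng.random(len(pair))  # minus-strand conditional draw
            w = rng.random(len(pair))  # 5mC-vs-5hmC choice (shared by the pair)
            sp = truth.state_array(chrom, "+")
            sm = truth.state_array(chrom, "-")
            lp = truth.level_array(chrom, "+")
            lm = truth.level_array(chrom, "-")
            for i, region in enumerate(RATE_REGIONS):
                sel = rid == i
                if not sel.any():
                    continue
                p_mc, p_hmc = rates_for((region, "CG"))
                r = p_mc + p_hmc
                if r == 0:
                    continue
                psel, usel, vsel, wsel = pair[sel], u[sel], v[sel], w[sel]
                b = max(f * r, 2 * r - 1.0)
                plus_mod = usel < r
                q_given = b / r
                q_not = (r - b) / (1.0 - r) if r < 1.0 else 0.0
                minus_mod = np.where(plus_mod, vsel < q_given, vsel < q_not)
                st = np.where(wsel < (p_mc / r), MC, HMC).astype(np.uint8)
                pp = psel[plus_mod]
                pm = psel[minus_mod]
                sp[pp] = st[plus_mod]
                sm[pm + 1] = st[minus_mod]
                lp[pp] = draw_levels(len(pp))
                lm[pm + 1] = draw_levels(len(pm))
    return truth


# ---------------------------------------------------------------------------
# bisulfite reads
# ---------------------------------------------------------------------------


def simulate_bs_reads(
    genome: Genome, truth: MethylomeTruth, config: SimConfig
) -> list[FastqRead]:
    """Uniformly sampled ungapped bisulfite reads.

    For each cytosine on the read's strand of origin: the molecule is
    modified with probability equal to the site level (then the base is
    protected and reads C), otherwise it converts with probability
    1 - conv_fail; finally the interrogated base flips C<->T with the
    sequencing error probability.  Non-cytosine bases substitute to a random
    other base with the same error probability.  Read names carry origin
    metadata after '|' separators: name|chrom|start|strand.
    """
    rng = config.rng(_SALT_BS)
    rl = config.read_length
    c_fail, e = config.conv_fail, config.seq_error
    lengths = genome.lengths
    for chrom, L in lengths.items():
        if rl > L:
            raise ValueError(f"read length {rl} exceeds chromosome {chrom} ({L})")
    total = sum(lengths.values())
    n_reads = math.ceil(total * config.coverage / rl)
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(n_reads, weights / weights.sum())
    qual = chr(33 + config.read_quality) * rl

    reads: list[FastqRead] = []
    idx = 0
    for chrom, n in zip(chroms, per_chrom):
        codes = genome.codes(chrom)
        lv = {s: truth.level_array(chrom, s) for s in "+-"}
        starts = rng.integers(0, lengths[chrom] - rl + 1, size=n)
        strands = rng.integers(0, 2, size=n)  # 0 -> '+', 1 -> '-'
        for s0, st in zip(starts, strands):
            strand = "+" if st == 0 else "-"
            seg = codes[s0 : s0 + rl].copy()
            target = C if strand == "+" else G
            conv_to = T if strand == "+" else A
            cmask = seg == target
            level = lv[strand][s0 : s0 + rl]
            modified = rng.random(rl) < level
            converts = cmask & ~modified & (rng.random(rl) >= c_fail)
            seg[converts] = conv_to
            err = rng.random(rl) < e
            flip = cmask & err  # symmetric C<->T (G<->A on the minus strand)
            was_target = flip & (seg == target)
            seg[flip & (seg == conv_to)] = target
            seg[was_target] = conv_to
            other = ~cmask & err
            n_other = int(other.sum())
            if n_other:
                shift = rng.integers(1, 4, size=n_other).astype(np.uint8)
                seg[other] = (seg[other] + shift) % 4
            out = decode(seg)
            if strand == "-":
                out = revcomp(out)
            reads.append(FastqRead(f"r{idx}|{chrom}|{int(s0)}|{strand}", out, qual))
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# PvuRts1I digestion and DIP fragments
# ---------------------------------------------------------------------------


def simulate_pvu_digestion(
    genome: Genome, truth: MethylomeTruth, config: SimConfig
) -> pd.DataFrame:
    """Fragment-end (cut) records from PvuRts1I digestion of the 5hmC sites.

    A 5hmC at (q, +) emits top-strand cuts at q + d with d drawn uniformly
    from the top offset set; a 5hmC at (q, -) emits bottom-strand cuts at
    q - d with d from the bottom offsets.  Each site emits a Poisson number
    of fragment ends (mean ``pvu_mean_frags``, defaulting to the coverage),
    plus uniform background cuts at ``pvu_background_cut_rate`` per base.
    """
    rng = config.rng(_SALT_PVU)
    mean_frags = config.pvu_mean_frags if config.pvu_mean_frags is not None else config.coverage
    rows = []
    for chrom in genome:
        L = genome.length(chrom)
        for strand, offsets, sign in (
            ("+", np.asarray(config.pvu_offsets_top), +1),
            ("-", np.asarray(config.pvu_offsets_bottom), -1),
        ):
            sites = np.flatnonzero(truth.state_array(chrom, strand) == HMC)
            if len(sites):
                counts = rng.poisson(mean_frags, size=len(sites))
                q = np.repeat(sites, counts)
                d = rng.choice(offsets, size=len(q))
                cut = q + sign * d
                ok = (cut >= 0) & (cut < L)
                rows.append(pd.DataFrame({"chrom": chrom, "pos": cut[ok], "strand": strand}))
        if config.pvu_background_cut_rate > 0:
            n_bg = rng.poisson(config.pvu_background_cut_rate * 2 * L)
            if n_bg:
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": rng.integers(0, L, size=n_bg),
                            "strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand"])
    return (
        pd.concat(rows, ignore_index=True)
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )


def simulate_dip_fragments(
    genome: Genome,
    truth: MethylomeTruth,
    config: SimConfig,
    target_state: str = "5hmC",
) -> pd.DataFrame:
    """Immunoprecipitation fragments around modified sites (BED-like table).

    For every site of the targeted state, a Poisson number of fragments
    (mean ``dip_mean_frags``) is emitted; each fragment's length is uniform
    on the configured range and the site sits at a uniform internal offset.
    Fragments are shifted to stay within the chromosome (still containing
    the site).  Background fragments are added at ``dip_background_rate``
    per base.
    """
    rng = config.rng(_SALT_DIP)
    want = STATE_CODES[target_state]
    lo, hi = config.dip_fragment_range
    rows = []
    for chrom in genome:
        L = genome.length(chrom)
        sites = np.concatenate(
            [np.flatnonzero(truth.state_array(chrom, s) == want) for s in "+-"]
        )
        if len(sites):
            counts = rng.poisson(config.dip_mean_frags, size=len(sites))
            pos = np.repeat(sites, counts)
            flen = rng.integers(lo, hi + 1, size=len(pos))
            off = (rng.random(len(pos)) * flen).astype(np.int64)
            start = np.clip(pos - off, 0, np.maximum(L - flen, 0))
            end = np.minimum(start + flen, L)
            rows.append(pd.DataFrame({"chrom": chrom, "start": start, "end": end}))
        if config.dip_background_rate > 0:
            n_bg = rng.poisson(config.dip_background_rate * L)
            if n_bg:
                flen = rng.integers(lo, hi + 1, size=n_bg)
                start = rng.integers(0, np.maximum(L - flen, 1))
                rows.append(
                    pd.DataFrame({"chrom": chrom, "start": start, "end": start + flen})
                )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return (
        pd.concat(rows, ignore_index=True)
        .sort_values(["chrom", "start", "end"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.description, str(rec.seq), qual))
    return out


def write_fastq(reads: Sequence[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a (chrom, start, end[, strand]) table as BED."""
    cols = ["chrom", "start", "end"]
    out = df.copy()
    if "start" not in out.columns and "pos" in out.columns:
        out["start"] = out["pos"]
        out["end"] = out["pos"] + 1
    if "strand" in out.columns:
        out["name"] = "."
        out["score"] = 0
        cols = ["chrom", "start", "end", "name", "score", "strand"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)
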