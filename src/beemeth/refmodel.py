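"""Reference genome and annotation model.

Provides sequence access, strand-specific cytosine context classification
(CG / CHG / CHH, H = A, T or C), symmetric-partner lookup for palindromic
contexts, an interval index mapping genomic positions to region labels
(exon, intron, splice sites, flanks, ...) and the observed/expected CpG
ratio used to separate historically methylated from unmethylated genes.

Coordinates are 0-based half-open internally; text formats (GFF3, the TSV
reports) use 1-based inclusive coordinates.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import A, C, G, N, T, encode, revcomp

__all__ = [
    "Genome",
    "Transcript",
    "Gene",
    "CytosineContext",
    "RegionIndex",
    "classify_context",
    "partner_position",
    "context_code_arrays",
    "build_region_index",
    "compute_oe",
    "read_gff3",
    "write_gff3",
    "CTX_CG",
    "CTX_CHG",
    "CTX_CHH",
    "CTX_NONE",
    "CONTEXT_NAMES",
    "REGION_LABELS",
]

_VALID_ALPHABET = frozenset("ACGTN")

# region label vocabulary (the row names of the summary tables)
EXON = "Exon"
CDS = "Cds"
INTRON = "Intron"
DONOR = "SpliceSiteDonor"
ACCEPTOR = "SpliceSiteAcceptor"
GENE = "Gene"
TRANSCRIPT = "Transcript"
UPSTREAM = "Upstream"
DOWNSTREAM = "Downstream"
INTERGENIC = "Intergenic"
INTRAGENIC = "Intragenic"

REGION_LABELS = (
    CDS,
    DOWNSTREAM,
    EXON,
    GENE,
    INTERGENIC,
    INTRAGENIC,
    INTRON,
    ACCEPTOR,
    DONOR,
    TRANSCRIPT,
    UPSTREAM,
)

# context codes for the vectorised per-position arrays
CTX_CG, CTX_CHG, CTX_CHH, CTX_NONE = 0, 1, 2, 3
CONTEXT_NAMES = ("CG", "CHG", "CHH")


class Genome(Mapping):
    """Reference sequences: chromosome name -> uppercase A/C/G/T/N string."""

    def __init__(self, records: Mapping[str, str]):
        recs = {}
        for name, seq in records.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            if not set(seq) <= _VALID_ALPHABET:
                bad = sorted(set(seq) - _VALID_ALPHABET)
                raise ValueError(f"invalid characters {bad} in chromosome {name!r}")
            recs[name] = seq
        self._records = recs
        self._codes: dict[str, np.ndarray] = {}

    def __getitem__(self, chrom: str) -> str:
        return self._records[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def length(self, chrom: str) -> int:
        return len(self._records[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._records.items()}

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 code array (A=0,C=1,G=2,T=3,N=4) for a chromosome."""
        if chrom not in self._codes:
            self._codes[chrom] = encode(self._records[chrom])
        return self._codes[chrom]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=c, description="") for c, s in self._records.items()]
        SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class Transcript:
    """One transcript: ordered, non-overlapping exons plus optional CDS."""

    id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s},{e}) in {self.id!r}")
            if s < prev_end:
                raise ValueError(f"exons of {self.id!r} unsorted or overlapping")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (a, b), (c2, d) in zip(self.exons, self.exons[1:]):
            if c2 > b:
                out.append((b, c2))
        return tuple(out)


@dataclass(frozen=True)
class Gene:
    """A gene: strand, chromosome and one or more transcripts."""

    id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"gene {self.id!r} has no transcripts")

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


@dataclass(frozen=True)
class CytosineContext:
    """Sequence context of one strand-specific cytosine."""

    klass: str  # "CG", "CHG" or "CHH"
    strand: str
    trinucleotide: str  # 3-mer 5'->3' on the cytosine's own strand


def classify_context(
    genome: Genome, chrom: str, pos: int, strand: str
) -> Optional[CytosineContext]:
    """Classify the cytosine at (chrom, pos, strand).

    Returns None (an "undefined" sentinel, not an error) when the 3-base
    window runs off the chromosome or contains an N.  Raises if the position
    is out of range or is not a cytosine on the requested strand (on the
    minus strand the reference base must be G).
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} out of range for {chrom} (len {len(seq)})")
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]!r}, not C")
        if pos + 2 >= len(seq):
            return None
        tri = seq[pos : pos + 3]
    else:
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) reference base is {seq[pos]!r}, not G")
        if pos - 2 < 0:
            return None
        tri = revcomp(seq[pos - 2 : pos + 1])
    if "N" in tri:
        return None
    if tri[1] == "G":
        klass = "CG"
    elif tri[2] == "G":
        klass = "CHG"
    else:
        klass = "CHH"
    return CytosineContext(klass, strand, tri)


def partner_position(context: CytosineContext, pos: int) -> Optional[tuple[int, str]]:
    """Symmetric partner cytosine of a CG or CHG site; None for CHH.

    CG and CHG are palindromic: the opposite strand carries a cytosine in the
    same context offset by 1 (CG) or 2 (CHG) bases.  CHH has no partner.
    """
    if context.klass == "CHH":
        return None
    step = 1 if context.klass == "CG" else 2
    if context.strand == "+":
        return pos + step, "-"
    return pos - step, "+"


def context_code_arrays(genome: Genome, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for both strands of one chromosome.

    Returns (plus, minus) uint8 arrays with CTX_CG/CTX_CHG/CTX_CHH at
    cytosine positions of the respective strand and CTX_NONE elsewhere
    (including windows containing N or running off the chromosome).
    Agrees with :func:`classify_context` position by position.
    """
    codes = genome.codes(chrom)
    n = len(codes)
    plus = np.full(n, CTX_NONE, dtype=np.uint8)
    minus = np.full(n, CTX_NONE, dtype=np.uint8)
    if n == 0:
        return plus, minus

    pad = np.full(2, N, dtype=np.uint8)
    ext = np.concatenate([pad, codes, pad])
    here = ext[2:-2]
    nxt1, nxt2 = ext[3:-1], ext[4:]
    prv1, prv2 = ext[1:-3], ext[:-4]

    def is_h(x):  # H = A, T or C (i.e. not G and not N)
        return (x != G) & (x != N)

    is_c = here == C
    # the full 3-base window must be on-chromosome and N-free, even for CG
    plus[is_c & (nxt1 == G) & (nxt2 != N)] = CTX_CG
    plus[is_c & is_h(nxt1) & (nxt2 == G)] = CTX_CHG
    plus[is_c & is_h(nxt1) & is_h(nxt2)] = CTX_CHH

    # minus strand: reference G at pos; the next base 5'->3' on the minus
    # strand is the complement of the reference base at pos-1, and so on.
    def is_h_minus(x):  # complement in {A,T,C} <=> reference base not C, not N
        return (x != C) & (x != N)

    is_g = here == G
    minus[is_g & (prv1 == C) & (prv2 != N)] = CTX_CG
    minus[is_g & is_h_minus(prv1) & (prv2 == C)] = CTX_CHG
    minus[is_g & is_h_minus(prv1) & is_h_minus(prv2)] = CTX_CHH

    # window running off the chromosome is undefined on that strand
    plus[max(0, n - 2) :] = CTX_NONE
    minus[: min(2, n)] = CTX_NONE
    return plus, minus


def _merge_intervals(ivals: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as sorted (starts, ends) arrays."""
    ivals = sorted((s, e) for s, e in ivals if e > s)
    starts, ends = [], []
    for s, e in ivals:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _complement(starts, ends, length) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for s, e in zip(starts, ends):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


class RegionIndex:
    """Position -> set-of-region-labels lookup built from merged intervals.

    Labels are deliberately non-exclusive: a base can be Exon, Cds, Gene and
    Transcript at once, and summaries count it once per label it carries.
    """

    def __init__(
        self,
        intervals: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
        chrom_lengths: Mapping[str, int],
        flank: int = 3000,
        splice_site: int = 2,
    ):
        self.flank = flank
        self.splice_site = splice_site
        self.chrom_lengths = dict(chrom_lengths)
        self._ivals: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        labels = set()
        for (chrom, label), iv in intervals.items():
            self._ivals[(chrom, label)] = _merge_intervals(iv)
            labels.add(label)
        self.labels = tuple(sorted(labels))

    def mask(self, chrom: str, label: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of `positions` in `label` on `chrom` (vectorised)."""
        positions = np.asarray(positions)
        key = (chrom, label)
        if key not in self._ivals:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._ivals[key]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    def labels_at(self, chrom: str, pos: int) -> frozenset:
        return frozenset(
            lab for lab in self.labels if self.mask(chrom, lab, np.array([pos]))[0]
        )

    def intervals(self, chrom: str, label: str) -> list[tuple[int, int]]:
        starts, ends = self._ivals.get((chrom, label), (np.array([]), np.array([])))
        return [(int(s), int(e)) for s, e in zip(starts, ends)]

    def to_bed(self, path: str | Path, labels: Optional[Sequence[str]] = None) -> None:
        """Export merged label intervals as BED (0-based half-open)."""
        labels = list(labels) if labels is not None else list(self.labels)
        with open(path, "w") as fh:
            for chrom in sorted(self.chrom_lengths):
                for label in labels:
                    for s, e in self.intervals(chrom, label):
                        fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def build_region_index(
    genes: Sequence[Gene],
    genome: Genome,
    flank: int = 3000,
    splice_site: int = 2,
) -> RegionIndex:
    """Index every genomic position by its region labels.

    Conventions: splice donor = first `splice_site` bases of an intron in
    transcription order, acceptor = the last; Upstream/Downstream follow the
    gene's transcription direction; Gene = hull of its transcript spans;
    Intragenic = inside the gene hull but in no transcript span; Intergenic
    = in no transcript span and no flank.  Labels of overlapping genes union.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if splice_site <= 0:
        raise ValueError("splice_site must be > 0")

    acc: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def add(chrom, label, s, e):
        L = genome.length(chrom)
        s, e = max(0, s), min(L, e)
        if e > s:
            acc.setdefault((chrom, label), []).append((s, e))

    tx_or_flank: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    for gene in genes:
        chrom = gene.chrom
        if chrom not in genome:
            raise ValueError(f"gene {gene.id!r} on unknown chromosome {chrom!r}")
        L = genome.length(chrom)
        tx_spans = []
        for t in gene.transcripts:
            ts, te = t.span
            if te > L:
                raise ValueError(f"transcript {t.id!r} extends past {chrom} (len {L})")
            tx_spans.append((ts, te))
            add(chrom, TRANSCRIPT, ts, te)
            for s, e in t.exons:
                add(chrom, EXON, s, e)
            for s, e in t.cds:
                add(chrom, CDS, s, e)
            for s, e in t.introns:
                add(chrom, INTRON, s, e)
                ss = min(splice_site, e - s)
                if gene.strand == "+":
                    add(chrom, DONOR, s, s + ss)
                    add(chrom, ACCEPTOR, e - ss, e)
                else:
                    add(chrom, DONOR, e - ss, e)
                    add(chrom, ACCEPTOR, s, s + ss)
        gs, ge = gene.span
        add(chrom, GENE, gs, ge)
        if gene.strand == "+":
            add(chrom, UPSTREAM, gs - flank, gs)
            add(chrom, DOWNSTREAM, ge, ge + flank)
            tx_or_flank[chrom] += [(max(0, gs - flank), gs), (ge, min(L, ge + flank))]
        else:
            add(chrom, UPSTREAM, ge, ge + flank)
            add(chrom, DOWNSTREAM, gs - flank, gs)
            tx_or_flank[chrom] += [(max(0, gs - flank), gs), (ge, min(L, ge + flank))]
        tx_or_flank[chrom] += tx_spans
        # hull minus transcript spans: only non-empty with disjoint transcripts
        ms, me = _merge_intervals(tx_spans)
        for s, e in _complement(ms, me, ge):
            if s >= gs:
                add(chrom, INTRAGENIC, s, e)

    for chrom in genome:
        starts, ends = _merge_intervals(tx_or_flank.get(chrom, []))
        for s, e in _complement(starts, ends, genome.length(chrom)):
            acc.setdefault((chrom, INTERGENIC), []).append((s, e))

    return RegionIndex(acc, genome.lengths, flank=flank, splice_site=splice_site)


def compute_oe(genes: Sequence[Gene], genome: Genome) -> dict[str, float]:
    """Observed/expected CpG ratio per gene.

    Per transcript span sequence of length L with nC cytosines and nG
    guanines: o/e = #CG dinucleotides / (nC * nG / L).  Genes with several
    transcripts get the span-length-weighted average; a zero expected count
    yields NaN.  The statistic is strand-invariant: CG is its own reverse
    complement and nC/nG swap under complementation.
    """
    out: dict[str, float] = {}
    for gene in genes:
        seq = genome[gene.chrom]
        num = den = 0.0
        for t in gene.transcripts:
            ts, te = t.span
            sub = seq[ts:te]
            L = len(sub)
            if L < 2:
                continue
            nc, ng = sub.count("C"), sub.count("G")
            expected = nc * ng / L
            if expected == 0:
                continue
            oe = sub.count("CG") / expected
            num += L * oe
            den += L
        out[gene.id] = num / den if den else float("nan")
    return out


# ---------------------------------------------------------------------------
# GFF3 input/output (gene -> mRNA -> exon/CDS; ID/Parent attributes)
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[Gene]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for m in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(
                (f.start - 1, f.end)
                for f in db.children(m, featuretype="exon", order_by="start")
            )
            cds = tuple(
                (f.start - 1, f.end)
                for f in db.children(m, featuretype="CDS", order_by="start")
            )
            transcripts.append(Transcript(m.id, exons, cds))
        if transcripts:
            genes.append(Gene(g.id, g.seqid, g.strand, tuple(transcripts)))
    return genes


def write_gff3(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(
                f"{g.chrom}\tbeemeth\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                fh.write(
                    f"{g.chrom}\tbeemeth\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tbeemeth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={t.id}.exon{i};Parent={t.id}\n"
                    )
                for i, (s, e) in enumerate(t.cds, 1):
                    fh.write(
                        f"{g.chrom}\tbeemeth\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={t.id}.cds{i};Parent={t.id}\n"
                    )
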