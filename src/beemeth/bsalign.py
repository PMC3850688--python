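"""Minimal bisulfite-aware read mapper and SAM ingestion.

Bisulfite conversion turns unmethylated C into T, so reads are aligned in a
reduced alphabet: the genome is collapsed C->T for reads interrogating the
plus strand and G->A for reads interrogating the minus strand, and reads
are collapsed the same way.  Mapping is exact k-mer seeding on the first k
bases followed by ungapped extension counting reduced-alphabet mismatches;
a read is reported only if it has a single best location with at most
``max_mismatch`` mismatches (ties are discarded as ambiguous).

For real data aligned with an external tool, :func:`read_sam` ingests SAM
records instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .refmodel import Genome
from .simulate import FastqRead
from .util import revcomp

__all__ = ["AlignedRead", "map_bs_reads", "read_sam", "write_sam"]

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


@dataclass
class AlignedRead:
    """One ungapped alignment.

    ``sequence`` and ``quals`` are stored in forward genome orientation
    (for bs_strand '-' the read was reverse-complemented); ``bs_strand`` is
    the genomic strand whose cytosines the read interrogates.
    """

    read_id: str
    chrom: str
    start: int
    bs_strand: str
    sequence: str
    quals: np.ndarray
    mismatches: int = 0
    unique: bool = True


def _byte_arr(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _build_index(seqs: dict[str, str], k: int) -> dict[bytes, list]:
    index: dict[bytes, list] = {}
    for chrom, seq in seqs.items():
        b = seq.encode("ascii")
        for i in range(len(b) - k + 1):
            index.setdefault(b[i : i + k], []).append((chrom, i))
    return index


def map_bs_reads(
    genome: Genome,
    reads: Sequence[FastqRead],
    k: int = 20,
    max_mismatch: int = 2,
) -> list[AlignedRead]:
    """Map bisulfite reads by reduced-alphabet seed-and-extend.

    Returns one AlignedRead per uniquely best-mapping read; ambiguous
    (tied) and unmappable reads are omitted.
    """
    if not reads:
        return []
    if k < 8:
        warnings.warn(f"seed length {k} < 8: expect high mapping ambiguity")
    ct_seqs = {c: genome[c].translate(_CT) for c in genome}
    ga_seqs = {c: genome[c].translate(_GA) for c in genome}
    ct_arr = {c: _byte_arr(s) for c, s in ct_seqs.items()}
    ga_arr = {c: _byte_arr(s) for c, s in ga_seqs.items()}
    ct_index = _build_index(ct_seqs, k)
    ga_index = _build_index(ga_seqs, k)

    out: list[AlignedRead] = []
    for read in reads:
        seq = read.sequence.upper()
        n = len(seq)
        if n < k:
            continue
        quals = _byte_arr(read.quality).astype(np.int16) - 33
        rc = revcomp(seq)

        best_mm = max_mismatch + 1
        best_hits: list[tuple[str, int, str]] = []
        for reduced, ref_arr, index, strand in (
            (seq.translate(_CT), ct_arr, ct_index, "+"),
            (rc.translate(_GA), ga_arr, ga_index, "-"),
        ):
            arr = _byte_arr(reduced)
            for chrom, p in index.get(reduced[:k].encode("ascii"), ()):
                ref = ref_arr[chrom]
                if p + n > len(ref):
                    continue
                mm = int(np.count_nonzero(ref[p : p + n] != arr))
                if mm < best_mm:
                    best_mm = mm
                    best_hits = [(chrom, p, strand)]
                elif mm == best_mm:
                    best_hits.append((chrom, p, strand))
        if best_mm > max_mismatch or len(best_hits) != 1:
            continue  # unmapped or ambiguous tie
        chrom, p, strand = best_hits[0]
        if strand == "+":
            out.append(AlignedRead(read.name, chrom, p, "+", seq, quals, best_mm))
        else:
            out.append(AlignedRead(read.name, chrom, p, "-", rc, quals[::-1].copy(), best_mm))
    return out


def read_sam(
    path: str | Path,
    genome: Genome,
    bs_tag: str = "XG",
    min_mapq: int = 0,
) -> list[AlignedRead]:
    """Ingest externally aligned reads from SAM.

    The bisulfite strand comes from the ``bs_tag`` tag when present
    ("CT" -> '+', "GA" -> '-') and otherwise from the reverse flag.
    Secondary/supplementary/unmapped records and records below the mapping
    quality floor are dropped; an unknown chromosome is an error.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, aln in enumerate(sam, 1):
            try:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.mapping_quality < min_mapq:
                    continue
                chrom = aln.reference_name
                if chrom not in genome:
                    raise ValueError(f"chromosome {chrom!r} not in genome")
                if aln.has_tag(bs_tag):
                    val = aln.get_tag(bs_tag)
                    if val == "CT":
                        bs = "+"
                    elif val == "GA":
                        bs = "-"
                    else:
                        raise ValueError(f"unrecognised {bs_tag} tag value {val!r}")
                else:
                    bs = "-" if aln.is_reverse else "+"
                seq = aln.query_sequence
                if seq is None:
                    raise ValueError("record has no sequence")
                quals = (
                    np.asarray(aln.query_qualities, dtype=np.int16)
                    if aln.query_qualities is not None
                    else np.full(len(seq), 40, dtype=np.int16)
                )
                out.append(
                    AlignedRead(
                        aln.query_name,
                        chrom,
                        aln.reference_start,
                        bs,
                        seq.upper(),
                        quals,
                        int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"SAM record {i}: {exc}") from exc
    return out


def write_sam(
    alignments: Sequence[AlignedRead], genome: Genome, path: str | Path
) -> None:
    """Write alignments in a minimal SAM dialect (flags 0/16, <len>M CIGAR)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome],
    }
    refids = {c: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for a in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            rec.reference_id = refids[a.chrom]
            rec.reference_start = a.start
            rec.flag = 16 if a.bs_strand == "-" else 0
            rec.mapping_quality = 37
            rec.cigarstring = f"{len(a.sequence)}M"
            rec.query_sequence = a.sequence
            rec.query_qualities = [int(q) for q in a.quals]
            rec.set_tag("XG", "CT" if a.bs_strand == "+" else "GA")
            rec.set_tag("NM", a.mismatches)
            sam.write(rec)
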