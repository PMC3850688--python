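"""Small shared helpers: base encoding, reverse complement, table rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# integer base codes used by all vectorised routines
A, C, G, T, N = 0, 1, 2, 3, 4
BASES = "ACGTN"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A=0,C=1,G=2,T=3,N=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DEC[codes].tobytes().decode("ascii")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed summary tables.

    Python's built-in ``round`` is banker's rounding; percentages in report
    tables are conventionally rounded half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(modified: int, analyzed: int, ndigits: int = 2) -> float:
    """``100 * modified / analyzed`` rounded half-up; NaN when analyzed == 0.

    Computed in exact decimal arithmetic so printed-table cells reproduce
    bit-for-bit regardless of magnitude.
    """
    if analyzed == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100 * modified) / Decimal(analyzed)).quantize(q, rounding=ROUND_HALF_UP)
    )
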