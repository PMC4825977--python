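"""Shared character-set definitions and small numeric helpers."""

from __future__ import annotations

import decimal

import numpy as np

# Canonical nucleotides; everything is stored uppercase with U mapped to T.
BASES = "ACGT"
AMBIGUITY = "RYSWKMBDHV"
GAP = "-"
MISSING = "?N"
# Full normalized alphabet accepted in stored alignments.
ALPHABET = set(BASES) | set(AMBIGUITY) | set(GAP) | set(MISSING)

BASE_CODES = np.frombuffer(BASES.encode(), dtype=np.uint8)

# Characters treated as missing for site classification, pairwise identity and
# distance computation: gaps, explicit missing and ambiguity codes alike.
_MISSING_CHARS = set(AMBIGUITY) | set(GAP) | set(MISSING)
MISSING_CODES = np.frombuffer("".join(sorted(_MISSING_CHARS)).encode(), dtype=np.uint8)

_IS_BASE = np.zeros(256, dtype=bool)
_IS_BASE[BASE_CODES] = True


def is_base(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of positions holding an unambiguous A/C/G/T."""
    return _IS_BASE[codes]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as the reported percentage tables do.

    Python's builtin ``round`` uses banker's rounding; report tables use the
    conventional half-up rule (e.g. 2.345 -> 2.35).
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "?": "?", "-": "-",
}
_COMPLEMENT_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v for k, v in _COMPLEMENT.items()}}
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_TABLE)[::-1]
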