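"""Aligned-sequence container and FASTA input/output.

The :class:`Alignment` is the central object of every analysis stage: a
rectangular matrix of nucleotide characters over named taxa.  Characters are
normalized on construction — uppercased, with RNA ``U`` mapped to ``T`` — and
validated against the IUPAC nucleotide alphabet plus gap (``-``) and missing
(``?``/``N``) symbols.  Coordinates are 0-based half-open throughout the
library; user-facing reports print 1-based inclusive positions.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._util import ALPHABET, is_base
from .errors import (
    AlphabetError,
    CoordinateError,
    DuplicateTaxonError,
    EmptyInputError,
    LabelError,
    RaggedAlignmentError,
)

__all__ = ["Alignment", "read_alignment", "write_alignment"]


class Alignment:
    """A rectangular multiple sequence alignment over named taxa.

    Parameters
    ----------
    taxa:
        Unique, non-empty taxon labels, one per row, order preserved.
    sequences:
        Aligned sequences, one per taxon, all of identical length >= 1.
        Input is case-insensitive; ``U`` is stored as ``T``.
    """

    def __init__(self, taxa: Sequence[str], sequences: Sequence[str]):
        taxa = list(taxa)
        if len(taxa) != len(sequences):
            raise LabelError(
                f"{len(taxa)} taxa but {len(sequences)} sequences"
            )
        if not taxa:
            raise EmptyInputError("alignment has no sequences")
        seen: set[str] = set()
        for t in taxa:
            if not t:
                raise LabelError("empty taxon label")
            if t in seen:
                raise DuplicateTaxonError(f"duplicate taxon label: {t!r}")
            seen.add(t)
        length = len(sequences[0])
        if length == 0:
            raise EmptyInputError(f"zero-length sequence for taxon {taxa[0]!r}")
        rows = []
        for t, s in zip(taxa, sequences):
            if len(s) != length:
                raise RaggedAlignmentError(
                    f"record {t!r} has length {len(s)}, expected {length}"
                )
            s = s.upper().replace("U", "T")
            bad = set(s) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {t!r} contains invalid characters: {sorted(bad)}"
                )
            rows.append(np.frombuffer(s.encode("ascii"), dtype=np.uint8))
        self.taxa: list[str] = taxa
        self._index = {t: i for i, t in enumerate(taxa)}
        # (n_taxa, n_columns) matrix of ASCII codes; uint8 keeps the hot
        # per-column statistics vectorizable.
        self.codes: np.ndarray = np.vstack(rows)
        self.codes.setflags(write=False)

    # -- basic protocol ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return self.codes.shape[1]

    def __len__(self) -> int:
        return self.n_taxa

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.codes, other.codes)

    def __repr__(self) -> str:
        return f"<Alignment {self.n_taxa} taxa x {self.length} columns>"

    def sequence(self, taxon: str) -> str:
        """Return the stored (normalized) sequence of one taxon."""
        try:
            i = self._index[taxon]
        except KeyError:
            raise LabelError(f"unknown taxon: {taxon!r}") from None
        return self.codes[i].tobytes().decode("ascii")

    def sequences(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.codes]

    def base_mask(self) -> np.ndarray:
        """Boolean (n_taxa, length) mask of unambiguous A/C/G/T cells."""
        return is_base(self.codes)

    # -- derived alignments ------------------------------------------------

    def extract_region(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of columns ``[start, end)`` (same taxa, same order)."""
        if not (0 <= start < end <= self.length):
            raise CoordinateError(
                f"invalid interval [{start}, {end}) for alignment of "
                f"length {self.length}"
            )
        return self._from_codes(self.taxa, self.codes[:, start:end])

    def subset_taxa(self, taxa: Iterable[str]) -> "Alignment":
        """Row-subset alignment; column count unchanged, given order kept."""
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self._index]
        if missing:
            raise LabelError(f"unknown taxa: {missing}")
        idx = [self._index[t] for t in taxa]
        return self._from_codes(taxa, self.codes[idx])

    def take_columns(self, indices: np.ndarray) -> "Alignment":
        """Column resample (used by the bootstrap); indices may repeat."""
        return self._from_codes(self.taxa, self.codes[:, np.asarray(indices)])

    @classmethod
    def _from_codes(cls, taxa: Sequence[str], codes: np.ndarray) -> "Alignment":
        # Internal fast path: codes are already normalized/validated.
        obj = cls.__new__(cls)
        obj.taxa = list(taxa)
        obj._index = {t: i for i, t in enumerate(obj.taxa)}
        obj.codes = np.ascontiguousarray(codes)
        obj.codes.setflags(write=False)
        return obj


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises
    ------
    EmptyInputError
        If the file contains no records.
    RaggedAlignmentError
        If records differ in length (message names the offending record).
    DuplicateTaxonError
        If two records share an identifier.
    """
    taxa: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    if not taxa:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment(taxa, seqs)


def write_alignment(aln: Alignment, path, width: int = 70) -> None:
    """Write an alignment as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences()):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
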