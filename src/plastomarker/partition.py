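"""Named partition intervals over alignment columns (quadripartite regions).

A plastome alignment is conventionally partitioned into the large single-copy
(LSC), small single-copy (SSC) and inverted-repeat (IR) regions.  Boundaries
are treated as *input*, not inferred: placing them is a judgement call made on
the alignment, and an automated inverted-repeat finder is provided separately
(:func:`plastomarker.variability.detect_inverted_repeat`).

Intervals are 0-based half-open internally (BED convention); printed reports
use 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import CoordinateError, EmptyInputError, PartitionConflictError

__all__ = ["Region", "PartitionMap", "read_partition", "write_partition"]


@dataclass(frozen=True)
class Region:
    """A named half-open column interval ``[start, end)``."""

    name: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


class PartitionMap:
    """Non-overlapping named regions over the columns of an alignment.

    The reserved names ``LSC``, ``SSC`` and ``IR`` (or ``IRa``/``IRb``) are
    recognized by the downstream variability statistics; other names are
    carried through untouched.
    """

    def __init__(self, regions, alignment_length: int):
        if alignment_length < 1:
            raise CoordinateError("alignment_length must be >= 1")
        regs = [r if isinstance(r, Region) else Region(*r) for r in regions]
        names = [r.name for r in regs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PartitionConflictError(f"duplicate region names: {dupes}")
        for r in regs:
            if not r.name:
                raise PartitionConflictError("empty region name")
            if not (0 <= r.start < r.end <= alignment_length):
                raise PartitionConflictError(
                    f"region {r.name!r} [{r.start}, {r.end}) outside "
                    f"[0, {alignment_length})"
                )
        ordered = sorted(regs, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise PartitionConflictError(
                    f"regions {a.name!r} and {b.name!r} overlap"
                )
        self.regions: list[Region] = ordered
        self.alignment_length = alignment_length

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def total_width(self) -> int:
        """Summed width of all regions (<= alignment_length)."""
        return sum(r.width for r in self.regions)

    def tiles_alignment(self) -> bool:
        """True when the regions cover every column exactly once."""
        return self.total_width() == self.alignment_length and (
            not self.regions
            or (
                self.regions[0].start == 0
                and self.regions[-1].end == self.alignment_length
            )
        )


def read_partition(path, alignment_length: int) -> PartitionMap:
    """Read a BED-like partition file (0-based half-open).

    Columns: reference name (ignored), start, end, and an optional fourth
    column giving the region name; unnamed intervals are called
    ``region_<k>`` in file order.
    """
    regions = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PartitionConflictError(
                    f"line {k + 1}: expected at least 3 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PartitionConflictError(
                    f"line {k + 1}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else f"region_{len(regions) + 1}"
            regions.append(Region(name, start, end))
    if not regions:
        raise EmptyInputError(f"no intervals in {path}")
    return PartitionMap(regions, alignment_length)


def write_partition(pmap: PartitionMap, path, chrom: str = "alignment") -> None:
    with open(path, "w") as fh:
        for r in pmap:
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.name}\n")
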