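"""Per-partition variability statistics, base composition and assembly summaries.

The central statistic is the classification of alignment columns into
*constant*, *variable but parsimony-uninformative*, *parsimony-informative*
and *excluded* sites.  A column is parsimony-informative when at least two
distinct unambiguous states each occur in at least two taxa — exactly the
columns whose Fitch parsimony length depends on the tree topology.  Gaps
(``-``), missing characters (``?``/``N``) and IUPAC ambiguity codes are all
treated as missing for classification; columns with fewer than two
non-missing taxa are *excluded* (they can support no comparison at all).

Percentages are reported against the full partition length, rounded half-up
to two decimals, matching the convention of published plastome variability
tables.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, is_base, reverse_complement, round_half_up
from .alignment import Alignment
from .errors import EmptyInputError, PartitionConflictError, PlastomarkerError
from .partition import PartitionMap

__all__ = [
    "SiteClass",
    "classify_site",
    "classify_columns",
    "percentages_from_counts",
    "variability_table",
    "base_composition",
    "assembly_stats",
    "detect_inverted_repeat",
]

WHOLE_ROW = "whole_alignment"


class SiteClass(enum.Enum):
    CONSTANT = "constant"
    VARIABLE_UNINFORMATIVE = "variable_uninformative"
    PARSIMONY_INFORMATIVE = "parsimony_informative"
    EXCLUDED = "excluded"


def _state_counts(codes: np.ndarray) -> np.ndarray:
    """(4, L) counts of A, C, G, T per column, missing characters ignored."""
    return np.stack([(codes == ord(b)).sum(axis=0) for b in BASES])


def classify_columns(aln: Alignment) -> np.ndarray:
    """Vectorized site classification for every column of an alignment.

    Returns an object array of :class:`SiteClass`, one entry per column.
    """
    counts = _state_counts(aln.codes)
    n_nonmissing = counts.sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    n_states_ge2 = (counts >= 2).sum(axis=0)

    out = np.full(aln.length, SiteClass.VARIABLE_UNINFORMATIVE, dtype=object)
    out[n_states_ge2 >= 2] = SiteClass.PARSIMONY_INFORMATIVE
    out[n_states == 1] = SiteClass.CONSTANT
    out[n_nonmissing < 2] = SiteClass.EXCLUDED
    return out


def classify_site(column: Sequence[str] | str) -> SiteClass:
    """Classify a single alignment column (one character per taxon)."""
    column = list(column)
    if len(column) < 2:
        raise PlastomarkerError("a column needs at least two taxa")
    aln = Alignment([f"t{i}" for i in range(len(column))], column)
    return classify_columns(aln)[0]


def percentages_from_counts(
    length: int, n_uninformative: int, n_informative: int
) -> dict[str, float]:
    """Percentage fields of a variability-table row from raw counts.

    Percentages use the full partition length as denominator and are rounded
    half-up to two decimals; total variability is computed from the summed
    count (not by adding the two rounded percentages).
    """
    if length < 1:
        raise EmptyInputError("length must be >= 1")
    return {
        "pct_uninformative": round_half_up(100.0 * n_uninformative / length),
        "pct_informative": round_half_up(100.0 * n_informative / length),
        "pct_total_variability": round_half_up(
            100.0 * (n_uninformative + n_informative) / length
        ),
    }


def _row(aln: Alignment, start: int, end: int) -> dict[str, float]:
    classes = classify_columns(aln.extract_region(start, end))
    length = end - start
    n_const = int((classes == SiteClass.CONSTANT).sum())
    n_uninf = int((classes == SiteClass.VARIABLE_UNINFORMATIVE).sum())
    n_inf = int((classes == SiteClass.PARSIMONY_INFORMATIVE).sum())
    n_excl = int((classes == SiteClass.EXCLUDED).sum())
    row = {
        "alignment_length": length,
        "n_constant": n_const,
        "n_uninformative": n_uninf,
        "n_informative": n_inf,
        "n_excluded": n_excl,
    }
    row.update(percentages_from_counts(length, n_uninf, n_inf))
    return row


def variability_table(aln: Alignment, partition: PartitionMap | None = None) -> pd.DataFrame:
    """Per-partition (and whole-alignment) site-class counts and percentages.

    Rows are indexed by region name plus a ``whole_alignment`` row; columns
    follow the shape of published plastome variability tables: counts of
    constant / parsimony-uninformative / parsimony-informative / excluded
    sites and the corresponding percentages.
    """
    if partition is not None and partition.alignment_length != aln.length:
        raise PartitionConflictError(
            f"partition is over {partition.alignment_length} columns but the "
            f"alignment has {aln.length}"
        )
    rows = {WHOLE_ROW: _row(aln, 0, aln.length)}
    if partition is not None:
        for region in partition:
            rows[region.name] = _row(aln, region.start, region.end)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


def base_composition(seqs: Iterable[str] | Alignment) -> tuple[float, float]:
    """(AT, GC) fractions over unambiguous bases only.

    Gaps, missing characters and ambiguity codes are excluded from the
    denominator; the two fractions sum to 1.
    """
    if isinstance(seqs, Alignment):
        codes = seqs.codes
    else:
        seqs = list(seqs)
        if not seqs:
            raise EmptyInputError("no sequences")
        joined = "".join(s.upper().replace("U", "T") for s in seqs)
        codes = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    codes = codes[is_base(codes.ravel())]
    if codes.size == 0:
        raise EmptyInputError("no unambiguous A/C/G/T characters to count")
    at = int(np.isin(codes, np.frombuffer(b"AT", dtype=np.uint8)).sum())
    frac_at = at / codes.size
    return frac_at, 1.0 - frac_at


def assembly_stats(contig_lengths: Sequence[int]) -> dict[str, int]:
    """Summary statistics of a contig length distribution.

    N50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the total assembly size;
    ``n_in_n50`` is the number of contigs in that cumulative set.
    """
    lengths = list(contig_lengths)
    if not lengths:
        raise EmptyInputError("empty contig list")
    if any(x <= 0 for x in lengths):
        raise PlastomarkerError("contig lengths must be positive")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    cum = 0
    for k, x in enumerate(desc, start=1):
        cum += x
        if 2 * cum >= total:
            n50, n_in_n50 = x, k
            break
    return {
        "n50": n50,
        "n_in_n50": n_in_n50,
        "max_contig": desc[0],
        "total_bases": total,
        "n_contigs": len(desc),
        "n_ge_1kb": sum(1 for x in desc if x >= 1000),
        "bases_in_ge_1kb": sum(x for x in desc if x >= 1000),
    }


def detect_inverted_repeat(
    genome: str, min_length: int = 1000
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Find the longest pair of disjoint exact inverted repeats.

    Returns two half-open intervals ``(a, b)`` with ``genome[b0:b1]`` equal to
    the reverse complement of ``genome[a0:a1]`` and length >= ``min_length``,
    or ``None`` if no such pair exists.  Matching is exact, which suits the
    near-identical inverted repeats of plastid genomes.
    """
    seq = genome.upper().replace("U", "T")
    n = len(seq)
    if n < 2 * min_length:
        return None
    lo, hi = min_length, n // 2
    best = None
    while lo <= hi:
        mid = (lo + hi) // 2
        hit = _find_ir_of_length(seq, mid)
        if hit is not None:
            best = hit
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def _find_ir_of_length(seq: str, m: int):
    """First disjoint (forward, reverse-complement) interval pair of length m."""
    rc = reverse_complement(seq)
    n = len(seq)
    mod = (1 << 61) - 1
    base = 131
    powm = pow(base, m - 1, mod)

    # Positions of each m-mer hash in seq.
    data = seq.encode("ascii")
    rdata = rc.encode("ascii")
    table: dict[int, list[int]] = {}
    h = 0
    for c in data[:m]:
        h = (h * base + c) % mod
    table.setdefault(h, []).append(0)
    for i in range(1, n - m + 1):
        h = ((h - data[i - 1] * powm) * base + data[i + m - 1]) % mod
        table.setdefault(h, []).append(i)

    h = 0
    for c in rdata[:m]:
        h = (h * base + c) % mod
    candidates = [(0, h)]
    for j in range(1, n - m + 1):
        h = ((h - rdata[j - 1] * powm) * base + rdata[j + m - 1]) % mod
        candidates.append((j, h))

    best = None
    for j, h in candidates:
        # rc[j:j+m] corresponds to revcomp of seq[n-j-m : n-j]
        a0 = n - j - m
        for i in table.get(h, ()):
            # verify (guards against hash collision)
            if seq[i : i + m] != rc[j : j + m]:
                continue
            first, second = sorted([(i, i + m), (a0, a0 + m)])
            if first[1] <= second[0]:  # disjoint
                if best is None or first < best[0]:
                    best = (first, second)
                break
    return best
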