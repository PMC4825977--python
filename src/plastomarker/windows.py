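"""Sliding-window mean pairwise identity and candidate-marker extraction.

The divergence scan mirrors the classic marker-hunting workflow: compute mean
pairwise identity in short windows (default 10 bp, step 1) across the whole
alignment, then pull out runs of low-identity windows as candidate marker
regions of amplifiable size (default 800-2000 bp) with little missing data.

Identity convention: a position is *comparable* for a sequence pair only when
both characters are unambiguous bases; gap-versus-base is not a mismatch, it
is excluded from the denominator.  A pair with no comparable position in a
window is undefined and is skipped when averaging; a window where every pair
is undefined has no identity value (NaN in the profile).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .alignment import Alignment
from .errors import ConfigError, CoordinateError

__all__ = [
    "IdentityProfile",
    "CandidateRegion",
    "pairwise_identity",
    "mean_pairwise_identity",
    "identity_profile",
    "extract_candidates",
]


@dataclass(frozen=True)
class IdentityProfile:
    """Windowed mean-pairwise-identity track over an alignment."""

    window_size: int
    step: int
    starts: np.ndarray  # window start columns (0-based)
    values: np.ndarray  # mean pairwise identity per window, NaN if undefined

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate marker interval ``[start, end)`` in alignment columns."""

    start: int
    end: int
    mean_identity: float
    missing_fraction: float
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def pairwise_identity(a: str, b: str, start: int = 0, end: int | None = None) -> float | None:
    """Identity of two aligned sequences over ``[start, end)``.

    Returns matches / comparable positions, or ``None`` when the pair has no
    comparable position in the interval.
    """
    if len(a) != len(b):
        raise CoordinateError("sequences differ in length")
    if end is None:
        end = len(a)
    if not (0 <= start < end <= len(a)):
        raise CoordinateError(f"invalid interval [{start}, {end})")
    sub = Alignment(["a", "b"], [a[start:end], b[start:end]])
    comparable = sub.base_mask().all(axis=0)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return None
    matches = int((comparable & (sub.codes[0] == sub.codes[1])).sum())
    return matches / n_comp


def _pair_stats(aln: Alignment, start: int, end: int):
    """Per-pair (matches, comparable) counts over one column interval."""
    base = aln.base_mask()[:, start:end]
    codes = aln.codes[:, start:end]
    for i, j in combinations(range(aln.n_taxa), 2):
        comp = base[i] & base[j]
        yield int((comp & (codes[i] == codes[j])).sum()), int(comp.sum())


def mean_pairwise_identity(aln: Alignment, start: int = 0, end: int | None = None) -> float:
    """Mean over all unordered taxon pairs of pairwise identity; NaN if all undefined."""
    if end is None:
        end = aln.length
    total, n_defined = 0.0, 0
    for m, c in _pair_stats(aln, start, end):
        if c > 0:
            total += m / c
            n_defined += 1
    return total / n_defined if n_defined else float("nan")


def identity_profile(aln: Alignment, window_size: int = 10, step: int = 1) -> IdentityProfile:
    """Sliding-window mean pairwise identity across the alignment.

    For each window, every unordered taxon pair contributes
    matches/comparable within the window; undefined pairs are skipped, and a
    window where all pairs are undefined gets NaN.
    """
    if window_size < 1 or step < 1:
        raise ConfigError("window_size and step must be >= 1")
    L = aln.length
    if window_size > L:
        raise ConfigError(f"window_size {window_size} exceeds alignment length {L}")
    n_windows = (L - window_size) // step + 1
    starts = np.arange(n_windows) * step
    ends = starts + window_size

    base = aln.base_mask()
    codes = aln.codes
    sum_identity = np.zeros(n_windows)
    n_defined = np.zeros(n_windows, dtype=np.int64)
    for i, j in combinations(range(aln.n_taxa), 2):
        comp = (base[i] & base[j]).astype(np.int64)
        match = (comp.astype(bool) & (codes[i] == codes[j])).astype(np.int64)
        ccum = np.concatenate([[0], np.cumsum(comp)])
        mcum = np.concatenate([[0], np.cumsum(match)])
        c = ccum[ends] - ccum[starts]
        m = mcum[ends] - mcum[starts]
        defined = c > 0
        sum_identity[defined] += m[defined] / c[defined]
        n_defined += defined
    values = np.full(n_windows, np.nan)
    ok = n_defined > 0
    values[ok] = sum_identity[ok] / n_defined[ok]
    return IdentityProfile(window_size, step, starts, values)


def _missing_fraction(aln: Alignment, start: int, end: int) -> float:
    sub = aln.base_mask()[:, start:end]
    return 1.0 - float(sub.mean())


def extract_candidates(
    profile: IdentityProfile,
    aln: Alignment,
    identity_threshold: float = 0.95,
    min_length: int = 800,
    max_length: int = 2000,
    max_missing_fraction: float = 0.2,
    merge_gap: int = 200,
) -> list[CandidateRegion]:
    """Extract candidate marker regions from a low-identity window scan.

    Maximal runs of windows with identity strictly below ``identity_threshold``
    (NaN windows break runs) are merged when their column gap is smaller than
    ``merge_gap``, split into chunks no longer than ``max_length``, and kept
    when at least ``min_length`` long with missing-data fraction at most
    ``max_missing_fraction``.  Output is sorted by start and deterministic.
    """
    if not (0.0 <= identity_threshold <= 1.0 and 0.0 <= max_missing_fraction <= 1.0):
        raise ConfigError("thresholds must lie in [0, 1]")
    if min_length < 1 or max_length < min_length:
        raise ConfigError("need 1 <= min_length <= max_length")

    low = np.zeros(profile.n_windows, dtype=bool)
    defined = ~np.isnan(profile.values)
    low[defined] = profile.values[defined] < identity_threshold

    # Column intervals of maximal low-identity window runs.
    runs: list[list[int]] = []
    k = 0
    while k < profile.n_windows:
        if low[k]:
            j = k
            while j + 1 < profile.n_windows and low[j + 1]:
                j += 1
            runs.append(
                [int(profile.starts[k]), int(profile.starts[j]) + profile.window_size]
            )
            k = j + 1
        else:
            k += 1

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out: list[CandidateRegion] = []
    n = 0
    for start, end in merged:
        # Split over-long intervals into max_length chunks.
        for s in range(start, end, max_length):
            e = min(s + max_length, end)
            if e - s < min_length:
                continue
            miss = _missing_fraction(aln, s, e)
            if miss > max_missing_fraction:
                continue
            n += 1
            out.append(
                CandidateRegion(
                    start=s,
                    end=e,
                    mean_identity=mean_pairwise_identity(aln, s, e),
                    missing_fraction=miss,
                    label=f"candidate_{n}",
                )
            )
    return out
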