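"""Self-contained tree machinery at desk scale.

Distance estimation (p-distance with Jukes-Cantor correction), neighbor
joining, Fitch parsimony scoring, nonparametric bootstrap over alignment
columns, majority-rule consensus and Robinson-Foulds topology comparison.
All operations are deterministic given their inputs and seed: neighbor
joining breaks Q-criterion ties on the lowest index pair, and the bootstrap
draws from a single seeded NumPy generator.

This is intentionally lightweight machinery for marker assessment — it makes
no attempt at heuristic tree search or likelihood/Bayesian inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .alignment import Alignment
from .errors import (
    ConfigError,
    IncomparablePairError,
    LabelError,
    PlastomarkerError,
    SaturationError,
)
from .trees import PhyloTree

__all__ = [
    "DistanceMatrix",
    "SupportThresholds",
    "p_distance",
    "jc_distance",
    "nj_tree",
    "fitch_length",
    "fitch_lengths",
    "bootstrap_trees",
    "majority_consensus",
    "rf_distance",
    "classify_support",
    "enumerate_topologies",
]


class DistanceMatrix:
    """A symmetric non-negative distance matrix over ordered taxa."""

    def __init__(self, taxa: Sequence[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        n = len(taxa)
        if d.shape != (n, n):
            raise PlastomarkerError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise PlastomarkerError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise PlastomarkerError("diagonal must be zero")
        if np.any(d < 0):
            raise PlastomarkerError("distances must be non-negative")
        self.taxa = list(taxa)
        self.d = d

    def __repr__(self) -> str:
        return f"<DistanceMatrix {len(self.taxa)} taxa>"


@dataclass(frozen=True)
class SupportThresholds:
    """Support-interpretation thresholds (percent scale).

    Defaults follow common practice for nonparametric bootstrap: >= 70%
    moderate, >= 85% well supported; posterior-probability analyses
    conventionally use 90/95.
    """

    method: Literal["bootstrap", "posterior"] = "bootstrap"
    moderate: float = 70.0
    well: float = 85.0

    def __post_init__(self):
        if not (0.0 < self.moderate < self.well <= 100.0):
            raise ConfigError("need 0 < moderate < well <= 100")

    @classmethod
    def posterior_defaults(cls) -> "SupportThresholds":
        return cls(method="posterior", moderate=90.0, well=95.0)


def classify_support(value: float, thresholds: SupportThresholds) -> str:
    """Bucket a support value into unsupported / moderate / well_supported."""
    if not (0.0 <= value <= 100.0):
        raise PlastomarkerError(f"support {value} outside [0, 100]")
    if value >= thresholds.well:
        return "well_supported"
    if value >= thresholds.moderate:
        return "moderate"
    return "unsupported"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Proportion of mismatching comparable positions for every taxon pair.

    A position is comparable when both sequences hold an unambiguous base.
    A pair with no comparable position raises :class:`IncomparablePairError`.
    """
    if aln.n_taxa < 2:
        raise PlastomarkerError("need at least two taxa")
    base = aln.base_mask()
    codes = aln.codes
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        comp = base[i] & base[j]
        n_comp = int(comp.sum())
        if n_comp == 0:
            raise IncomparablePairError(
                f"no comparable positions between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
            )
        mism = int((comp & (codes[i] != codes[j])).sum())
        d[i, j] = d[j, i] = mism / n_comp
    return DistanceMatrix(aln.taxa, d)


def jc_distance(p):
    """Jukes-Cantor corrected distance -(3/4) ln(1 - 4p/3).

    Accepts a scalar proportion or an array; raises
    :class:`SaturationError` at or beyond p = 3/4.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.75):
        raise SaturationError("p-distance must lie in [0, 0.75)")
    out = -0.75 * np.log1p(-4.0 * arr / 3.0)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def jc_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Apply the Jukes-Cantor correction entrywise to a p-distance matrix."""
    d = dm.d.copy()
    off = ~np.eye(len(dm.taxa), dtype=bool)
    d[off] = jc_distance(d[off])
    return DistanceMatrix(dm.taxa, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: ties in the Q criterion are broken on the lowest (i, j)
    index pair; negative branch-length estimates are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PlastomarkerError("neighbor joining needs at least 3 taxa")
    # Active nodes as newick fragments.
    nodes = [f"{t}" for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # Lowest-index tie-break: np.argmin returns the first minimum in
        # row-major order, i.e. the lexicographically smallest (i, j), i < j.
        ai, aj = divmod(int(np.argmin(q)), m)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # Distances from the new node to every other active node.
        new = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new[:-1]
        d[:-1, -1] = new[:-1]
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [a for a in active if a not in (i, j)] + [d.shape[0] - 1]

    a, b, c = active
    # Three-point formulas for the final star join.
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    return PhyloTree.from_newick(newick)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

_FITCH_CODE = np.zeros(256, dtype=np.uint8)
_FITCH_CODE[:] = 0b1111  # missing/ambiguous characters: full state set
for _b, _bit in zip(b"ACGT", (1, 2, 4, 8)):
    _FITCH_CODE[_b] = _bit


def fitch_length(tree: PhyloTree, aln: Alignment) -> int:
    """Total Fitch parsimony length of an alignment on a tree."""
    return int(fitch_lengths(tree, aln).sum())


def fitch_lengths(tree: PhyloTree, aln: Alignment) -> np.ndarray:
    """Fitch parsimony length of every alignment column on a tree.

    Missing and ambiguous leaf characters are assigned the full state set
    (they never force a change).  Exact on binary (and trifurcating-root)
    trees; on other multifurcations the children are folded sequentially,
    which equals the score of an arbitrary binary refinement.
    """
    if tree.taxa != frozenset(aln.taxa):
        raise LabelError("tree leaves do not match alignment taxa")
    idx = {t: k for k, t in enumerate(aln.taxa)}
    leaf_sets = _FITCH_CODE[aln.codes]
    changes = np.zeros(aln.length, dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = leaf_sets[idx[node.taxon.label]]
            continue
        children = node.child_nodes()
        acc = state.pop(id(children[0]))
        for ch in children[1:]:
            s = state.pop(id(ch))
            inter = acc & s
            empty = inter == 0
            acc = np.where(empty, acc | s, inter)
            changes += empty
        state[id(node)] = acc
    return changes


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------


def bootstrap_trees(
    aln: Alignment, n_reps: int, seed: int, builder: Literal["nj"] = "nj"
) -> list[PhyloTree]:
    """Column bootstrap: resample columns with replacement, build NJ trees.

    Each replicate keeps the original alignment length.  Reproducible: the
    same seed yields byte-identical trees.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if builder != "nj":
        raise ConfigError(f"unknown tree builder: {builder!r}")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_reps):
        idx = rng.integers(0, aln.length, aln.length)
        rep = aln.take_columns(idx)
        trees.append(nj_tree(jc_matrix(p_distance(rep))))
    return trees


def majority_consensus(trees: Sequence[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Majority-rule consensus with split supports in percent.

    Contains exactly the non-trivial splits present in strictly more than
    ``threshold`` of the input trees (splits at exactly the threshold are
    excluded), each annotated with its percentage occurrence.
    """
    if not trees:
        raise ConfigError("no input trees")
    if not (0.5 <= threshold < 1.0):
        raise ConfigError("threshold must lie in [0.5, 1)")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise LabelError("input trees have inconsistent leaf sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    keep = {
        s: 100.0 * c / len(trees)
        for s, c in counts.items()
        if c / len(trees) > threshold
    }
    return _tree_from_splits(taxa, keep)


def _tree_from_splits(
    taxa: frozenset[str], supports: dict[frozenset[str], float]
) -> PhyloTree:
    """Build a tree from a compatible (laminar) family of canonical splits.

    Canonical splits never contain the reference taxon min(taxa), so with the
    tree rooted next to that taxon each split is a clade; strict-majority
    splits are pairwise compatible, hence the clades nest.
    """
    ref = min(taxa)
    clades = sorted(supports, key=len, reverse=True)

    children: dict[object, list] = {None: []}
    for c in clades:
        children[c] = []
    parent_of: dict[frozenset[str], object] = {}
    # Assign each clade to the smallest strictly-containing clade.
    for c in clades:
        par = None
        for other in clades:
            if other is not c and c < other:
                if par is None or len(other) < len(par):
                    par = other
        parent_of[c] = par
        children[par].append(c)
    # Assign each non-reference leaf to the smallest clade containing it.
    leaf_parent: dict[str, object] = {}
    for leaf in taxa - {ref}:
        par = None
        for c in clades:
            if leaf in c and (par is None or len(c) < len(par)):
                par = c
        leaf_parent[leaf] = par

    def render(node) -> str:
        parts = [render(c) for c in children.get(node, [])]
        parts += sorted(l for l, p in leaf_parent.items() if p is node)
        inner = ",".join(parts)
        if node is None:
            return f"({ref},{inner});" if inner else f"({ref});"
        return f"({inner}){supports[node]:.10g}"

    return PhyloTree.from_newick(render(None))


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: |symmetric difference of non-trivial splits|."""
    if t1.taxa != t2.taxa:
        raise LabelError("trees have different leaf sets")
    return len(t1.splits() ^ t2.splits())


def rf_max(n_leaves: int) -> int:
    """Maximum RF distance between two fully resolved unrooted trees."""
    return max(2 * (n_leaves - 3), 1)


# ---------------------------------------------------------------------------
# Topology enumeration (small n; oracle substrate)
# ---------------------------------------------------------------------------


def enumerate_topologies(labels: Sequence[str]) -> list[PhyloTree]:
    """All distinct unrooted binary topologies over ``labels`` (n <= 8 sane).

    Built by sequential leaf insertion into every edge: 1, 3, 15, 105, ...
    trees for 3, 4, 5, 6 leaves.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ConfigError("need at least 3 labels")

    # An unrooted tree is a nested tuple with a virtual root of degree 3;
    # each new leaf is attached on every existing edge in turn.
    trees = [(labels[0], labels[1], labels[2])]
    for leaf in labels[3:]:
        nxt = []
        for t in trees:
            variants = []

            def walk(node, replace):
                variants.append(replace((node, leaf)))
                if isinstance(node, tuple):
                    for k, ch in enumerate(node):
                        walk(
                            ch,
                            lambda sub, node=node, k=k, replace=replace: replace(
                                tuple(
                                    sub if m == k else c for m, c in enumerate(node)
                                )
                            ),
                        )

            for k, child in enumerate(t):
                walk(
                    child,
                    lambda sub, k=k, t=t: tuple(
                        sub if m == k else c for m, c in enumerate(t)
                    ),
                )
            nxt.extend(variants)
        trees = nxt

    def to_newick(node) -> str:
        if isinstance(node, tuple):
            return "(" + ",".join(to_newick(c) for c in node) + ")"
        return node

    return [PhyloTree.from_newick(to_newick(t) + ";") for t in trees]
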