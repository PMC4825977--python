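"""Unrooted phylogenetic trees: Newick I/O, bipartitions, supports.

Trees are thin wrappers around :class:`dendropy.Tree` (which handles Newick
parsing and writing); topology comparison is done on *canonical splits*
computed here.  A split (bipartition) is stored as the frozenset of leaf
labels on the side **not** containing the lexicographically smallest taxon,
so two trees over the same leaf set can be compared by set operations alone.
Internal-node Newick labels are interpreted as support values on a 0-100
scale, as written by bootstrap consensus.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

from .errors import LabelError, TreeParseError

__all__ = ["PhyloTree", "read_tree", "write_tree"]


class PhyloTree:
    """An unrooted leaf-labelled tree with optional lengths and supports."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise LabelError("duplicate leaf labels in tree")
        if not labels:
            raise TreeParseError("tree has no leaves")
        self.taxa: frozenset[str] = frozenset(labels)
        for sup in self.split_supports().values():
            if sup is not None and not (0.0 <= sup <= 100.0):
                raise TreeParseError(f"support value {sup} outside [0, 100]")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, taxa: Optional[Iterable[str]] = None) -> "PhyloTree":
        """Parse a Newick string; optionally check leaves against ``taxa``."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"could not parse Newick: {exc}") from exc
        obj = cls(tree)
        if taxa is not None:
            expected = frozenset(taxa)
            if obj.taxa != expected:
                raise LabelError(
                    f"tree leaves {sorted(obj.taxa)} != expected {sorted(expected)}"
                )
        return obj

    # -- properties --------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves} leaves>"

    # -- splits ------------------------------------------------------------

    def canonical_split(self, side: Iterable[str]) -> frozenset[str]:
        """Canonicalize one side of a bipartition of this tree's leaf set."""
        return canonical_split(side, self.taxa)

    def splits(self) -> frozenset[frozenset[str]]:
        """The set of non-trivial canonical splits (internal edges)."""
        return frozenset(self.split_supports())

    def split_supports(self) -> dict[frozenset[str], Optional[float]]:
        """Map each non-trivial split to its support value (or None)."""
        n = len(self.taxa)
        out: dict[frozenset[str], Optional[float]] = {}
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            if len(below) <= 1 or len(below) >= n - 1:
                continue  # trivial split
            split = canonical_split(below, self.taxa)
            sup = _parse_support(node.label)
            # The two child edges of a rooted representation's root describe
            # the same unrooted split; keep an annotated value if either has one.
            if split in out and out[split] is not None:
                continue
            out[split] = sup
        return out

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s


def canonical_split(side: Iterable[str], taxa: frozenset[str]) -> frozenset[str]:
    """Return the side of the bipartition not containing min(taxa)."""
    side = frozenset(side)
    if not side <= taxa:
        raise LabelError(f"labels {sorted(side - taxa)} not in leaf set")
    if min(taxa) in side:
        side = taxa - side
    return side


def _parse_support(label: Optional[str]) -> Optional[float]:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def read_tree(path, taxa: Optional[Iterable[str]] = None) -> PhyloTree:
    """Read a Newick tree from a file."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read(), taxa=taxa)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
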