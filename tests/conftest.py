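"""Shared fixtures: random alignments, random trees, additive matrices."""

from __future__ import annotations

import numpy as np
import pytest

from plastomarker.alignment import Alignment


def random_alignment(
    rng: np.random.Generator,
    n_taxa: int,
    length: int,
    gap_fraction: float = 0.0,
    missing_fraction: float = 0.0,
) -> Alignment:
    """A uniformly random alignment with optional gaps and missing cells."""
    chars = np.array(list("ACGT"))
    mat = chars[rng.integers(0, 4, size=(n_taxa, length))]
    if gap_fraction:
        mat[rng.random(mat.shape) < gap_fraction] = "-"
    if missing_fraction:
        mat[rng.random(mat.shape) < missing_fraction] = "?"
    return Alignment(
        [f"t{i:02d}" for i in range(n_taxa)], ["".join(r) for r in mat]
    )


def divergent_alignment(
    rng: np.random.Generator, n_taxa: int, length: int, divergence: float = 0.1
) -> Alignment:
    """Low-divergence alignment: each row mutates one ancestral sequence.

    Keeps pairwise p-distances well below the Jukes-Cantor saturation limit,
    unlike uniformly random rows.
    """
    chars = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=length)
    rows = []
    for _ in range(n_taxa):
        row = root.copy()
        mut = rng.random(length) < divergence
        row[mut] = (row[mut] + rng.integers(1, 4, int(mut.sum()))) % 4
        rows.append("".join(chars[row]))
    return Alignment([f"t{i:02d}" for i in range(n_taxa)], rows)


def random_tree_adjacency(rng: np.random.Generator, labels: list[str]):
    """Random unrooted binary tree as (adjacency {node: {nbr: length}}, newick).

    Built by sequential attachment of each leaf to a uniformly chosen edge,
    with edge lengths drawn uniformly in [0.05, 1.0].  Used as an independent
    source of additive distance matrices.
    """

    def elen():
        return float(rng.uniform(0.05, 1.0))

    adj: dict[object, dict[object, float]] = {}
    nxt = [0]

    def new_internal():
        nxt[0] += 1
        return f"__i{nxt[0]}"

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def del_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    a, b, c = labels[:3]
    hub = new_internal()
    for leaf in (a, b, c):
        add_edge(hub, leaf, elen())
    for leaf in labels[3:]:
        edges = sorted(
            (str(u), str(v)) for u in adj for v in adj[u] if str(u) < str(v)
        )
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        mid = new_internal()
        del_edge(u, v)
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, elen())

    def newick(node, parent):
        nbrs = [n for n in adj[node] if n != parent]
        if not nbrs:
            return node
        inner = ",".join(
            f"{newick(n, node)}:{adj[node][n]:.10g}" for n in nbrs
        )
        return f"({inner})"

    return adj, newick(hub, None) + ";"


def path_distances(adj, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of a weighted tree (BFS per leaf)."""
    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return d


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160408)
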