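"""Distances, neighbor joining, Fitch parsimony, bootstrap, consensus, RF."""

import itertools

import dendropy
import numpy as np
import pytest

from plastomarker import (
    Alignment,
    DistanceMatrix,
    PhyloTree,
    SupportThresholds,
    bootstrap_trees,
    classify_support,
    fitch_length,
    jc_distance,
    majority_consensus,
    nj_tree,
    p_distance,
    rf_distance,
)
from plastomarker.errors import (
    ConfigError,
    IncomparablePairError,
    LabelError,
    PlastomarkerError,
    SaturationError,
)
from plastomarker.phylo import enumerate_topologies, jc_matrix

from conftest import (
    divergent_alignment,
    path_distances,
    random_alignment,
    random_tree_adjacency,
)


class TestPDistance:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        assert np.all(p_distance(aln).d == 0)

    def test_quarter_mismatch(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        assert p_distance(aln).d[0, 1] == pytest.approx(0.25)

    def test_matches_bruteforce_counts(self, rng):
        aln = random_alignment(rng, 6, 80, gap_fraction=0.1, missing_fraction=0.05)
        dm = p_distance(aln)
        seqs = aln.sequences()
        for i, j in itertools.combinations(range(6), 2):
            mism = comp = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x in "ACGT" and y in "ACGT":
                    comp += 1
                    mism += x != y
            assert dm.d[i, j] == pytest.approx(mism / comp)

    def test_incomparable_pair_names_taxa(self):
        aln = Alignment(["left", "right"], ["AC--", "--GT"])
        with pytest.raises(IncomparablePairError, match="left.*right"):
            p_distance(aln)


class TestJCDistance:
    def test_closed_form_values(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.3) == pytest.approx(-0.75 * np.log(0.6))
        assert jc_distance(0.3) == pytest.approx(0.383119, abs=1e-6)

    def test_monotone(self):
        ps = np.linspace(0, 0.74, 50)
        ds = jc_distance(ps)
        assert np.all(np.diff(ds) > 0)

    @pytest.mark.parametrize("p", [0.75, 0.9, -0.1])
    def test_saturation(self, p):
        with pytest.raises(SaturationError):
            jc_distance(p)


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.dendropy_tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))  # 0.1
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))  # 0.2
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))  # 0.4

    @pytest.mark.parametrize("n_leaves", [4, 8, 12])
    def test_recovers_generating_topology_on_additive_matrix(self, rng, n_leaves):
        labels = [f"t{i:02d}" for i in range(n_leaves)]
        adj, newick = random_tree_adjacency(rng, labels)
        truth = PhyloTree.from_newick(newick)
        dm = DistanceMatrix(labels, path_distances(adj, labels))
        assert nj_tree(dm).splits() == truth.splits()

    def test_taxon_order_invariance(self, rng):
        labels = [f"t{i:02d}" for i in range(8)]
        adj, _ = random_tree_adjacency(rng, labels)
        d = path_distances(adj, labels)
        base = nj_tree(DistanceMatrix(labels, d)).splits()
        perm = rng.permutation(8)
        permuted = nj_tree(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert permuted.splits() == base

    def test_agrees_with_dendropy_nj(self, rng):
        """Independent cross-check against dendropy's NJ on clean data."""
        aln = divergent_alignment(rng, 7, 400, divergence=0.15)
        dm = jc_matrix(p_distance(aln))
        ours = nj_tree(dm).splits()

        csv = "," + ",".join(dm.taxa) + "\n"
        for i, t in enumerate(dm.taxa):
            csv += t + "," + ",".join(f"{x:.10f}" for x in dm.d[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        dtree = PhyloTree(pdm.nj_tree())
        assert dtree.splits() == ours

    def test_fewer_than_three_taxa(self):
        with pytest.raises(PlastomarkerError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


def _fitch_bruteforce(tree: PhyloTree, column: dict[str, str]) -> int:
    """Minimum changes over all internal-node state assignments."""
    dt = tree.dendropy_tree
    internals = [n for n in dt.preorder_node_iter() if not n.is_leaf()]
    leaf_states = {}
    for leaf in dt.leaf_node_iter():
        c = column[leaf.taxon.label]
        leaf_states[id(leaf)] = "ACGT" if c not in "ACGT" else c
    best = None
    for combo in itertools.product("ACGT", repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        for node in dt.preorder_node_iter():
            if node.parent_node is None:
                continue
            ps = assign[id(node.parent_node)]
            if node.is_leaf():
                cost += ps not in leaf_states[id(node)]
            else:
                cost += assign[id(node)] != ps
        best = cost if best is None else min(best, cost)
    return best


class TestFitch:
    def test_textbook_cases(self):
        good = PhyloTree.from_newick("((A1,A2),(C1,C2));")
        bad = PhyloTree.from_newick("((A1,C1),(A2,C2));")
        aln = Alignment(["A1", "A2", "C1", "C2"], ["A", "A", "C", "C"])
        assert fitch_length(good, aln) == 1
        assert fitch_length(bad, aln) == 2

    def test_constant_and_missing_columns_cost_nothing(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        aln = Alignment(["A", "B", "C", "D"], ["AN?", "AA-", "AAA", "A?A"])
        assert fitch_length(tree, aln) == 0

    def test_matches_bruteforce_on_five_leaf_trees(self, rng):
        labels = list("ABCDE")
        trees = enumerate_topologies(labels)[:4]
        cols = rng.integers(0, 6, size=(30, 5))  # 4 bases + gap + missing
        charset = "ACGT-?"
        for tree in trees:
            for col in cols:
                column = {l: charset[c] for l, c in zip(labels, col)}
                aln = Alignment(labels, [column[l] for l in labels])
                assert fitch_length(tree, aln) == _fitch_bruteforce(tree, column)

    def test_invariant_under_rerooting_and_row_order(self, rng):
        labels = [f"t{i:02d}" for i in range(6)]
        _, newick = random_tree_adjacency(rng, labels)
        tree = PhyloTree.from_newick(newick)
        aln = random_alignment(rng, 6, 50, missing_fraction=0.1)
        base = fitch_length(tree, aln)

        dt = tree.dendropy_tree.clone(depth=1)
        leaf = dt.find_node_with_taxon_label("t03")
        dt.reroot_at_edge(leaf.edge, update_bipartitions=False)
        assert fitch_length(PhyloTree(dt), aln) == base

        shuffled = aln.subset_taxa(list(reversed(aln.taxa)))
        assert fitch_length(tree, shuffled) == base

    def test_column_cost_bounds(self, rng):
        """k-1 <= per-tree cost <= taxa carrying a non-modal state."""
        labels = list("ABCDE")
        for tree in enumerate_topologies(labels)[:5]:
            for _ in range(20):
                col = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5)])
                aln = Alignment(labels, list(col))
                cost = fitch_length(tree, aln)
                counts = {c: col.count(c) for c in set(col)}
                assert cost >= len(counts) - 1
                assert cost <= len(col) - max(counts.values())

    def test_label_mismatch(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        aln = Alignment(["A", "B", "C", "X"], ["A", "A", "C", "C"])
        with pytest.raises(LabelError):
            fitch_length(tree, aln)


class TestBootstrap:
    def test_seeded_runs_identical(self, rng):
        aln = divergent_alignment(rng, 6, 150)
        t1 = bootstrap_trees(aln, 10, seed=5)
        t2 = bootstrap_trees(aln, 10, seed=5)
        assert [t.to_newick() for t in t1] == [t.to_newick() for t in t2]

    def test_overwhelming_signal_gives_full_support(self):
        # 50 concatenated copies of a pattern set built on ((A,B),(C,D),(E,F)):
        # one column per split (AB, CD, EF) plus singleton columns.
        patterns = {
            "A": "AAACAAA",
            "B": "AAAAGAA",
            "C": "CAGAAAA",
            "D": "CAGAATA",
            "E": "CTAAAAA",
            "F": "CTAAAAC",
        }
        taxa = list(patterns)
        aln = Alignment(taxa, [patterns[t] * 50 for t in taxa])
        trees = bootstrap_trees(aln, 100, seed=0)
        truth = PhyloTree.from_newick("((A,B),(C,D),(E,F));")
        ref_splits = nj_tree(jc_matrix(p_distance(aln))).splits()
        assert ref_splits == truth.splits()
        counts = {s: 0 for s in ref_splits}
        for t in trees:
            for s in t.splits() & ref_splits:
                counts[s] += 1
        assert all(c >= 99 for c in counts.values())

    def test_zero_replicates_rejected(self, rng):
        aln = random_alignment(rng, 4, 20)
        with pytest.raises(ConfigError):
            bootstrap_trees(aln, 0, seed=1)


class TestConsensus:
    def test_identical_inputs_full_support(self):
        t = PhyloTree.from_newick("((A,B),(C,D),(E,F));")
        cons = majority_consensus([t] * 7)
        assert cons.splits() == t.splits()
        assert all(v == 100.0 for v in cons.split_supports().values())

    def test_maximally_conflicting_pair_gives_star(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,C),(B,D));")
        cons = majority_consensus([t1, t2])
        assert cons.splits() == frozenset()

    def test_split_at_exact_threshold_excluded(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,C),(B,D));")
        t3 = PhyloTree.from_newick("((A,B),(C,D));")
        t4 = PhyloTree.from_newick("((A,D),(B,C));")
        # AB|CD occurs in exactly 2/4 = threshold: excluded
        assert majority_consensus([t1, t2, t3, t4]).splits() == frozenset()
        # in 2/3 it is included
        cons = majority_consensus([t1, t2, t3])
        assert cons.splits() == t1.splits()
        (sup,) = cons.split_supports().values()
        assert sup == pytest.approx(100 * 2 / 3)

    def test_percentages_match_naive_counting(self, rng):
        labels = [f"t{i}" for i in range(6)]
        trees = []
        for k in range(20):
            _, newick = random_tree_adjacency(
                np.random.default_rng(k), labels
            )
            trees.append(PhyloTree.from_newick(newick))
        cons = majority_consensus(trees)
        for split, sup in cons.split_supports().items():
            naive = sum(split in t.splits() for t in trees)
            assert naive / 20 > 0.5
            assert sup == pytest.approx(100 * naive / 20)

    def test_inconsistent_leaf_sets(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(LabelError):
            majority_consensus([t1, t2])


class TestRobinsonFoulds:
    def test_identity(self, rng):
        _, newick = random_tree_adjacency(rng, [f"t{i}" for i in range(8)])
        t = PhyloTree.from_newick(newick)
        assert rf_distance(t, t) == 0

    def test_four_leaf_distance_two(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t2, t1) == 2

    def test_agrees_with_dendropy(self):
        taxa = dendropy.TaxonNamespace()
        labels = [f"t{i}" for i in range(10)]
        for k in range(5):
            _, nwk1 = random_tree_adjacency(np.random.default_rng(2 * k), labels)
            _, nwk2 = random_tree_adjacency(np.random.default_rng(2 * k + 1), labels)
            d1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=taxa)
            d2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=taxa)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            ours = rf_distance(
                PhyloTree.from_newick(nwk1), PhyloTree.from_newick(nwk2)
            )
            assert ours == expected

    def test_leaf_set_mismatch(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(LabelError):
            rf_distance(t1, t2)


class TestSupportThresholds:
    @pytest.mark.parametrize(
        "value, thresholds, expected",
        [
            (85, SupportThresholds(), "well_supported"),
            (70, SupportThresholds(), "moderate"),
            (84.9, SupportThresholds(), "moderate"),
            (0, SupportThresholds(), "unsupported"),
            (92, SupportThresholds.posterior_defaults(), "moderate"),
            (95, SupportThresholds.posterior_defaults(), "well_supported"),
        ],
    )
    def test_classification(self, value, thresholds, expected):
        assert classify_support(value, thresholds) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(PlastomarkerError):
            classify_support(101, SupportThresholds())
        with pytest.raises(ConfigError):
            SupportThresholds(moderate=90, well=85)


class TestEnumerateTopologies:
    @pytest.mark.parametrize("n, count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_counts_and_distinctness(self, n, count):
        trees = enumerate_topologies([f"t{i}" for i in range(n)])
        assert len(trees) == count
        assert len({t.splits() for t in trees}) == count
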