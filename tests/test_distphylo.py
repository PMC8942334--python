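"""Distance transforms, tree inference, consensus, and Newick round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skbio.tree
from structphylo.distphylo import (
    DistanceMatrix,
    SimilarityMatrix,
    cap_scores,
    consensus,
    fitch_margoliash,
    mean_similarity,
    midpoint_root,
    neighbor_joining,
    parse_newick,
    read_matrix,
    read_phylip_lower,
    robinson_foulds,
    sim_to_dist_matrix,
    similarity_to_distance,
    tree_splits,
    upgma,
    write_matrix,
    write_newick,
)
from structphylo.synthetic_data import random_guide_tree


def additive_matrix(tree) -> DistanceMatrix:
    tips = sorted(x.name for x in tree.tips())
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.find(tips[i]).distance(tree.find(tips[j]))
    scale = max(1.0, d.max() * 1.01)
    return DistanceMatrix(tips, d / scale)


class TestTransforms:
    @pytest.mark.parametrize("score, expected", [(1000, 0.0), (0, 1.0), (486, 0.514),
                                                 (1500, 0.0), (250, 0.75)])
    def test_similarity_to_distance(self, score, expected):
        assert similarity_to_distance(score) == pytest.approx(expected)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            similarity_to_distance(-1.0)

    def test_cap(self):
        m = SimilarityMatrix(["a", "b"], np.array([[1500.0, 486.0], [486.0, 1200.0]]))
        capped = cap_scores(m)
        assert capped.values[0, 0] == 1000.0
        assert capped.values[0, 1] == 486.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matrix_transform_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        half = rng.uniform(0, 1500, size=(n, n))
        vals = (half + half.T) / 2
        m = SimilarityMatrix([f"s{i}" for i in range(n)], vals)
        d = sim_to_dist_matrix(cap_scores(m))
        assert d.values.min() >= 0 and d.values.max() <= 1
        assert np.allclose(np.diag(d.values), 0)
        assert np.allclose(d.values, d.values.T)

    def test_mean_similarity(self):
        m = SimilarityMatrix(["a", "b"], np.array([[10.0, 4.0], [4.0, 10.0]]))
        m3 = SimilarityMatrix(["a", "b"], 3 * m.values)
        assert np.allclose(mean_similarity([m, m3]).values, 2 * m.values)
        assert np.allclose(mean_similarity([m, m, m]).values, m.values)
        with pytest.raises(ValueError, match="label"):
            mean_similarity([m, SimilarityMatrix(["a", "c"], m.values)])


class TestUPGMA:
    def test_two_leaves(self):
        t = upgma(DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]])))
        assert {tip.length for tip in t.tips()} == {0.2}

    def test_four_leaf_hand_agglomeration(self):
        d = DistanceMatrix(list("ABCD"), np.array([
            [0, .2, .6, .6], [.2, 0, .6, .6], [.6, .6, 0, .2], [.6, .6, .2, 0]]))
        t = upgma(d)
        depths = {tip.name: t.distance(tip) for tip in t.tips()}
        assert all(abs(v - 0.3) < 1e-12 for v in depths.values())
        assert tree_splits(t) == {frozenset({"C", "D"})}

    def test_equal_matrix_caterpillar_by_tiebreak(self):
        n = 4
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 0.0)
        t = upgma(DistanceMatrix(list("ABCD"), vals))
        # first merge is (A, B) by the lowest-index rule
        assert frozenset({"C", "D"}) in tree_splits(t) or \
            {frozenset({"A", "B"})} == {s if "A" in s else frozenset("AB") for s in tree_splits(t)}

    def test_ultrametric_output_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            half = rng.uniform(0.05, 1.0, size=(n, n))
            vals = (half + half.T) / 2
            np.fill_diagonal(vals, 0.0)
            t = upgma(DistanceMatrix([f"x{i}" for i in range(n)], vals))
            depths = [t.distance(tip) for tip in t.tips()]
            assert max(depths) - min(depths) < 1e-9

    def test_size_error(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        dab, dac, dbc = 0.3, 0.5, 0.6
        d = DistanceMatrix(list("ABC"), np.array([
            [0, dab, dac], [dab, 0, dbc], [dac, 0.6, 0]]))
        t = neighbor_joining(d)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["A"] == pytest.approx((dab + dac - dbc) / 2)
        assert lengths["B"] == pytest.approx((dab + dbc - dac) / 2)
        assert lengths["C"] == pytest.approx((dac + dbc - dab) / 2)

    def test_additive_recovery_and_branch_lengths(self):
        gt = parse_newick("((A:0.10,B:0.20):0.15,(C:0.30,D:0.05):0.10,E:0.40);")
        t = neighbor_joining(additive_matrix(gt))
        assert robinson_foulds(t, gt) == 0

    def test_atteson_perturbation_tolerance(self):
        gt = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,E:0.3);")
        dm = additive_matrix(gt)
        rng = np.random.default_rng(5)
        # perturb strictly less than half the smallest internal edge (0.1 scaled)
        eps = 0.04 * dm.values.max()
        noise = rng.uniform(-eps / 2, eps / 2, size=dm.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        vals = np.clip(dm.values + noise, 0, 1)
        t = neighbor_joining(DistanceMatrix(dm.labels, vals))
        assert robinson_foulds(t, gt) == 0

    def test_size_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, .1], [.1, 0]])))


class TestFitchMargoliash:
    def test_additive_zero_objective_exact_lengths(self):
        gt = parse_newick("((A:0.10,B:0.20):0.15,(C:0.30,D:0.05):0.10,E:0.40);")
        dm = additive_matrix(gt)
        t = fitch_margoliash(dm)
        assert t.fm_objective < 1e-12
        assert robinson_foulds(t, gt) == 0
        # pairwise path lengths reproduce the input distances
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert t.find(a).distance(t.find(b)) == pytest.approx(dm.values[i, j], abs=1e-9)

    def test_perturbed_quartet_matches_least_squares_oracle(self):
        labels = list("ABCD")
        vals = np.array([
            [0.00, 0.30, 0.50, 0.52],
            [0.30, 0.00, 0.52, 0.50],
            [0.50, 0.52, 0.00, 0.26],
            [0.52, 0.50, 0.26, 0.00],
        ])
        vals[0, 1] = vals[1, 0] = 0.36  # one perturbed entry
        dm = DistanceMatrix(labels, vals)
        t = fitch_margoliash(dm)
        assert t.fm_objective > 0
        # independent oracle: weighted least squares on the ((A,B),(C,D))
        # quartet via scipy least_squares with non-negative bounds
        from scipy.optimize import least_squares

        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        # edges: eA, eB, eC, eD, internal
        paths = {
            (0, 1): [0, 1], (2, 3): [2, 3],
            (0, 2): [0, 2, 4], (0, 3): [0, 3, 4],
            (1, 2): [1, 2, 4], (1, 3): [1, 3, 4],
        }
        w = np.array([1.0 / vals[i, j] ** 2 for i, j in pairs])

        def resid(x):
            return np.sqrt(w) * np.array(
                [sum(x[e] for e in paths[p]) - vals[p] for p in pairs])

        sol = least_squares(resid, x0=np.full(5, 0.1), bounds=(0, np.inf))
        assert t.fm_objective == pytest.approx(float(np.sum(sol.fun ** 2)), abs=1e-3)

    def test_objective_not_worse_than_nj_start(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            n = 6
            half = rng.uniform(0.1, 0.9, size=(n, n))
            vals = (half + half.T) / 2
            np.fill_diagonal(vals, 0.0)
            dm = DistanceMatrix([f"L{i}" for i in range(n)], vals)
            t = fitch_margoliash(dm)
            from structphylo.distphylo import _tree_to_graph, _wls_lengths
            nj_adj, _ = _tree_to_graph(neighbor_joining(dm))
            _, nj_obj, _, _ = _wls_lengths(nj_adj, dm)
            assert t.fm_objective <= nj_obj + 1e-12


class TestRootingConsensusRF:
    def test_midpoint_three_leaf(self):
        t = midpoint_root(parse_newick("(A:1,B:2,C:3);"))
        dists = {tip.name: t.distance(tip) for tip in t.tips()}
        assert dists["C"] == pytest.approx(2.5)
        assert dists["B"] == pytest.approx(2.5)

    def test_midpoint_symmetric_quartet_and_idempotence(self):
        t = midpoint_root(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        dists = [t.distance(tip) for tip in t.tips()]
        assert max(dists) - min(dists) < 1e-9
        again = midpoint_root(t)
        assert robinson_foulds(again, t) == 0
        assert sorted(x.distance(y) for x in again.tips() for y in again.tips()) == \
            pytest.approx(sorted(x.distance(y) for x in t.tips() for y in t.tips()))

    def test_midpoint_degenerate_error(self):
        with pytest.raises(ValueError):
            midpoint_root(parse_newick("(A:0,B:0,C:0);"))

    def test_consensus_majority_and_supports(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = parse_newick("((A:1,B:1):2,(C:1,D:1):2,E:1);")
        t3 = parse_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        c = consensus([t1, t2, t3])
        splits = tree_splits(c)
        assert frozenset({"C", "D"}) in splits
        sups = sorted(getattr(n, "support", None) for n in c.non_tips())
        assert sups == pytest.approx([2 / 3, 2 / 3])
        # kept split's branch length is the mean over trees containing it
        cd_node = next(n for n in c.non_tips()
                       if {t.name for t in n.tips()} == {"C", "D"})
        assert cd_node.length == pytest.approx(1.5)

    def test_consensus_identical_trees(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        c = consensus([t, t.copy(), t.copy()])
        assert robinson_foulds(c, t) == 0
        assert all(getattr(n, "support", None) == 1.0 for n in c.non_tips())

    def test_consensus_high_threshold_collapses(self):
        t1 = parse_newick("((A,B),(C,D),E);")
        t2 = parse_newick("((A,B),(C,E),D);")
        t3 = parse_newick("((A,C),(B,D),E);")
        c = consensus([t1, t2, t3], threshold=0.99)
        assert tree_splits(c) == set()

    def test_consensus_leafset_mismatch(self):
        with pytest.raises(ValueError):
            consensus([parse_newick("((A,B),C,D);"), parse_newick("((A,B),C,E);")])

    def test_consensus_matches_skbio_majority_rule(self):
        trees = [random_guide_tree(7, seed=s) for s in range(5)]
        ours = consensus(trees)
        ref = skbio.tree.majority_rule([t.copy() for t in trees])[0]
        assert robinson_foulds(ours, ref) == 0

    def test_rf_examples(self):
        q1 = parse_newick("((A,B),(C,D));")
        q2 = parse_newick("((A,C),(B,D));")
        assert robinson_foulds(q1, q2) == 2
        assert robinson_foulds(q1, q1) == 0
        assert robinson_foulds(q2, q1) == robinson_foulds(q1, q2)
        with pytest.raises(ValueError):
            robinson_foulds(q1, parse_newick("((A,B),(C,E));"))


class TestSerialization:
    @pytest.mark.parametrize("seed", range(5))
    def test_newick_roundtrip_random_trees(self, seed):
        t = random_guide_tree(8, seed=seed)
        rt = parse_newick(write_newick(t))
        assert robinson_foulds(rt, t) == 0
        for tip in t.tips():
            assert rt.find(tip.name).length == pytest.approx(tip.length, abs=1e-6)

    def test_two_leaf_and_quoted_labels(self):
        t = parse_newick("(A:1,B:1);")
        assert sorted(x.name for x in t.tips()) == ["A", "B"]
        t2 = parse_newick(write_newick(parse_newick("('sp one':1,'sp two':2);")))
        assert sorted(x.name for x in t2.tips()) == ["sp one", "sp two"]

    def test_unbalanced_parentheses_position(self):
        with pytest.raises(ValueError, match="position|left open"):
            parse_newick("((A,B),C;")
        with pytest.raises(ValueError, match="position|left open"):
            parse_newick("(A,B)),C;")

    def test_support_roundtrip(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t3 = parse_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        c = consensus([t1, t1.copy(), t3])
        rt = parse_newick(write_newick(c))
        sups = sorted(getattr(n, "support", None) for n in rt.non_tips()
                      if getattr(n, "support", None) is not None)
        assert sups == pytest.approx([2 / 3, 2 / 3])

    def test_matrix_roundtrip_and_phylip(self):
        m = DistanceMatrix(["a", "b", "c"], np.array([
            [0, .25, .5], [.25, 0, .75], [.5, .75, 0]]))
        rt = read_matrix(write_matrix(m))
        assert rt.labels == m.labels
        assert np.allclose(rt.values, m.values)
        phylip = "3\na 0.0\nb 0.25 0.0\nc 0.5 0.75 0.0\n"
        pm = read_phylip_lower(phylip)
        assert np.allclose(pm.values, m.values)
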