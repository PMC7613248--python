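"""Lineage statistics: contraction, compositions, weighted correlation
(checked against a direct-summation oracle), clustering, stability and
conditional probabilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import annotation_frame, manual_tree
from scartree.lineage import (
    NodeComposition,
    cluster_cell_types,
    conditional_probability,
    contract_vertical_branches,
    downsample_stability,
    node_composition,
    weighted_correlation,
)


def brute_force_weighted_corr(ratios: np.ndarray, weights: np.ndarray, a: int, b: int) -> float:
    """Direct summation of the frequency-weighted Pearson formula."""
    wsum = sum(weights)
    ma = sum(w * r for w, r in zip(weights, ratios[:, a])) / wsum
    mb = sum(w * r for w, r in zip(weights, ratios[:, b])) / wsum
    cab = sum(w * (ra - ma) * (rb - mb)
              for w, ra, rb in zip(weights, ratios[:, a], ratios[:, b])) / wsum
    caa = sum(w * (ra - ma) ** 2 for w, ra in zip(weights, ratios[:, a])) / wsum
    cbb = sum(w * (rb - mb) ** 2 for w, rb in zip(weights, ratios[:, b])) / wsum
    return cab / np.sqrt(caa * cbb)


def composition_from_counts(counts: np.ndarray, types=None) -> NodeComposition:
    types = types or [f"t{i}" for i in range(counts.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [("R1", i) for i in range(len(counts))], names=["replicate", "node"]
    )
    df = pd.DataFrame(counts, index=idx, columns=types, dtype=int)
    return NodeComposition(
        counts=df,
        node_size=df.sum(axis=1),
        is_leaf=pd.Series(True, index=idx),
    )


class TestContraction:
    def test_single_child_node_merges_into_child(self):
        tree = manual_tree({
            "root": (None, None, []),
            "a": ("root", "sa", ["x"]),
            "b": ("a", "sb", ["y"]),
            "c": ("b", "sc", []),
            "d": ("b", "sd", []),
        })
        out = contract_vertical_branches(tree)
        scars = {n.scar for n in out.nodes.values()}
        assert scars == {"sb", "sc", "sd"}
        b = next(n for n in out.nodes.values() if n.scar == "sb")
        assert sorted(b.cells) == ["x", "y"] and b.parent is None

    def test_branching_tree_unchanged(self):
        tree = manual_tree({
            "root": (None, None, ["r"]),
            "a": ("root", "sa", ["x"]),
            "b": ("root", "sb", ["y"]),
        })
        out = contract_vertical_branches(tree)
        assert {n.scar for n in out.nodes.values()} == {None, "sa", "sb"}
        assert out.n_cells() == 3

    def test_pure_chain_collapses_to_single_node(self):
        tree = manual_tree({
            "root": (None, None, []),
            "a": ("root", "sa", ["x"]),
            "b": ("a", "sb", ["y", "z"]),
        })
        out = contract_vertical_branches(tree)
        assert len(out.nodes) == 1
        assert sorted(out.nodes[out.root].cells) == ["x", "y", "z"]

    def test_root_with_cells_is_exempt(self):
        tree = manual_tree({
            "root": (None, None, ["r"]),
            "a": ("root", "sa", ["x"]),
        })
        out = contract_vertical_branches(tree)
        assert len(out.nodes) == 2 and out.nodes[out.root].cells == ["r"]


class TestComposition:
    def test_ratios_follow_definition(self):
        tree = manual_tree({"root": (None, None, ["a1", "a2", "b1"])})
        ann = annotation_frame({"a1": "A", "a2": "A", "b1": "B"})
        comp = node_composition([tree], ann)
        assert comp.node_size.iloc[0] == 3
        assert comp.ratios().iloc[0].to_dict() == {"A": 2 / 3, "B": 1 / 3}

    def test_subtree_inclusive_pools_descendants(self):
        tree = manual_tree({
            "root": (None, None, ["a1"]),
            "c": ("root", "s", ["b1"]),
        })
        ann = annotation_frame({"a1": "A", "b1": "B"})
        comp = node_composition([tree], ann, subtree_inclusive=True)
        root_row = comp.counts.xs(0, level="node").iloc[0]
        assert root_row.to_dict() == {"A": 1, "B": 1}
        local = node_composition([tree], ann, subtree_inclusive=False)
        root_row = local.counts.xs(0, level="node").iloc[0]
        assert root_row.to_dict() == {"A": 1, "B": 0}

    def test_replicate_trees_pool_with_tags(self):
        t1 = manual_tree({"root": (None, None, ["x"])}, replicate="R1")
        t2 = manual_tree({"root": (None, None, ["y"])}, replicate="R2")
        ann = annotation_frame({"x": "A", "y": "A"})
        comp = node_composition([t1, t2], ann)
        assert set(comp.counts.index.get_level_values("replicate")) == {"R1", "R2"}

    def test_unannotated_cells_excluded(self):
        tree = manual_tree({"root": (None, None, ["known", "mystery"])})
        comp = node_composition([tree], annotation_frame({"known": "A"}))
        assert comp.node_size.iloc[0] == 1


class TestWeightedCorrelation:
    def test_equal_weights_match_plain_pearson(self):
        rng = np.random.default_rng(1)
        counts = rng.multinomial(50, [0.3, 0.3, 0.2, 0.2], size=12)  # equal node sizes
        comp = composition_from_counts(counts)
        ratios = comp.ratios().to_numpy()
        got = weighted_correlation(comp).to_numpy()
        want = np.corrcoef(ratios.T)
        assert np.nanmax(np.abs(got - want)) < 1e-12

    def test_identical_ratio_vectors_correlate_to_one(self):
        counts = np.array([[2, 2, 6], [5, 5, 10], [1, 1, 1]])
        corr = weighted_correlation(composition_from_counts(counts))
        assert corr.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_fixture_matches_direct_summation(self):
        sizes = np.array([10, 10, 20])
        r_a = np.array([0.5, 0.2, 0.1])
        r_b = np.array([0.4, 0.3, 0.0])
        counts = np.stack(
            [(r_a * sizes), (r_b * sizes), sizes - r_a * sizes - r_b * sizes]
        ).T.astype(int)
        comp = composition_from_counts(counts)
        got = weighted_correlation(comp).iloc[0, 1]
        ratios = comp.ratios().to_numpy()
        want = brute_force_weighted_corr(ratios, comp.node_size.to_numpy(), 0, 1)
        assert got == pytest.approx(want, abs=1e-12)

    def test_types_in_fewer_than_two_nodes_are_missing(self):
        counts = np.array([[3, 0, 2], [4, 0, 1], [2, 5, 0]])
        corr = weighted_correlation(composition_from_counts(counts))
        assert corr.iloc[1].isna().all()  # t1 present in one node only
        assert corr.iloc[0, 0] == 1.0

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_unit_diagonal_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n, t = rng.integers(3, 20), rng.integers(2, 8)
        counts = rng.integers(0, 6, size=(n, t))
        counts[:, 0] += 1  # keep node sizes positive
        comp = composition_from_counts(counts)
        corr = weighted_correlation(comp).to_numpy()
        assert np.allclose(corr, corr.T, equal_nan=True, atol=1e-12)
        defined = ~np.isnan(np.diag(corr))
        assert np.all(np.diag(corr)[defined] == 1.0)
        ratios = comp.ratios().to_numpy()
        w = comp.node_size.to_numpy()
        for a in range(t):
            for b in range(a + 1, t):
                if not (defined[a] and defined[b]) or np.isnan(corr[a, b]):
                    continue
                assert corr[a, b] == pytest.approx(
                    brute_force_weighted_corr(ratios, w, a, b), abs=1e-10
                )


class TestClustering:
    def test_block_diagonal_recovers_blocks(self):
        corr = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        labels = cluster_cell_types(corr, n_clusters=2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_all_correlated_types_form_one_cluster(self):
        corr = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        labels = cluster_cell_types(corr, distance_threshold=1.9)
        assert labels.nunique() == 1

    def test_too_many_clusters_requested_fails(self):
        corr = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="fewer"):
            cluster_cell_types(corr, n_clusters=3)


class TestConditionalProbability:
    def leaves_tree(self):
        return manual_tree({
            "root": (None, None, []),
            "l1": ("root", "s1", ["a1", "b1"]),
            "l2": ("root", "s2", ["a2"]),
            "l3": ("root", "s3", ["a3", "b2"]),
        })

    def test_enumerated_leaves(self):
        ann = annotation_frame({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"})
        prob, n_leaves = conditional_probability([self.leaves_tree()], ann)
        assert prob.loc["A", "B"] == 1.0
        assert prob.loc["B", "A"] == pytest.approx(2 / 3)
        assert n_leaves["A"] == 3 and n_leaves["B"] == 2

    def test_self_probability_is_one_and_bounds_hold(self):
        ann = annotation_frame({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"})
        prob, _ = conditional_probability([self.leaves_tree()], ann)
        assert prob.loc["A", "A"] == 1.0 and prob.loc["B", "B"] == 1.0
        vals = prob.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_absent_target_reported_missing(self):
        ann = annotation_frame({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"})
        prob, n_leaves = conditional_probability(
            [self.leaves_tree()], ann, targets=["A", "ghost"]
        )
        assert prob["ghost"].isna().all() and n_leaves["ghost"] == 0


class TestStability:
    def two_trees(self):
        t1 = manual_tree({
            "root": (None, None, []),
            "l1": ("root", "s1", ["a1", "a2", "b1"]),
            "l2": ("root", "s2", ["a3", "b2", "b3"]),
            "l3": ("root", "s3", ["c1", "c2"]),
        }, replicate="R1")
        t2 = manual_tree({
            "root": (None, None, []),
            "l1": ("root", "s4", ["a4", "b4"]),
            "l2": ("root", "s5", ["c3", "c4", "a5"]),
        }, replicate="R2")
        ann = annotation_frame(
            {f"a{i}": "A" for i in range(1, 6)}
            | {f"b{i}": "B" for i in range(1, 5)}
            | {f"c{i}": "C" for i in range(1, 5)}
        )
        return [t1, t2], ann

    def test_full_fraction_reproduces_reference_clustering(self):
        trees, ann = self.two_trees()
        rep = downsample_stability(
            trees, ann, mode="nodes", fraction=1.0, reps=10, seed=3,
            distance_threshold=0.6,
        )
        vals = rep.frequency.to_numpy()
        assert set(np.unique(vals[~np.isnan(vals)])) <= {0.0, 1.0}
        ref = rep.reference_labels
        for a in ref.index:
            for b in ref.index:
                expected = 1.0 if ref[a] == ref[b] else 0.0
                assert rep.frequency.loc[a, b] == expected

    def test_cell_mode_runs_and_bounds_hold(self):
        trees, ann = self.two_trees()
        rep = downsample_stability(
            trees, ann, mode="cells", fraction=0.5, reps=25, seed=9,
            distance_threshold=0.6,
        )
        vals = rep.frequency.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
        assert np.all(np.diag(vals)[~np.isnan(np.diag(vals))] == 1.0)
        assert 0 <= rep.exact_match_rate() <= 1

    def test_same_seed_is_reproducible(self):
        trees, ann = self.two_trees()
        r1 = downsample_stability(trees, ann, mode="cells", reps=15, seed=4,
                                  distance_threshold=0.6)
        r2 = downsample_stability(trees, ann, mode="cells", reps=15, seed=4,
                                  distance_threshold=0.6)
        pd.testing.assert_frame_equal(r1.frequency, r2.frequency)
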