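"""Composite similarity, complete linkage, partition cuts, ARI, residuals."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from metaboatlas.atlas import (
    AtlasError,
    Dendrogram,
    adjusted_rand_index,
    complete_linkage,
    composite_similarity,
    cut_partition,
    jaccard,
    spearman_rescaled,
    statin_residualize,
)
from metaboatlas.profiling import DiseaseProfile
from oracles import (
    ari_paircount,
    complete_linkage_bruteforce,
    cut_bruteforce,
    partition_to_labels,
    set_partitions,
    spearman_distinct,
)


class TestJaccard:
    def test_half_overlap(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_identity(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_both_empty_counts_as_identical(self):
        assert jaccard(set(), set()) == 1.0

    def test_monotone_in_overlap(self):
        """Adding a shared feature never lowers the overlap."""
        assert jaccard({"a", "c"}, {"b", "c"}) >= jaccard({"a"}, {"b"})


class TestSpearmanRescaled:
    def test_reversed_is_zero(self):
        assert spearman_rescaled([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_self_is_one(self):
        assert spearman_rescaled([1, 5, 2, 9], [1, 5, 2, 9]) == pytest.approx(1.0)

    def test_worked_example_rank_formula(self):
        """(1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/60 = 0.6, R' = 0.8."""
        a, b = [1, 2, 3, 4], [2, 1, 4, 3]
        assert spearman_distinct(a, b) == pytest.approx(0.6)
        assert spearman_rescaled(a, b) == pytest.approx(0.8)

    def test_zero_variance_midpoint(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert spearman_rescaled([1, 1, 1], [1, 2, 3]) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(AtlasError, match="mismatch"):
            spearman_rescaled([1, 2, 3], [1, 2])


def _profiles_from_matrix(mat: np.ndarray, tau=0.5) -> dict:
    feats = [f"f{j}" for j in range(mat.shape[1])]
    return {
        f"D{i:02d}": DiseaseProfile(
            f"D{i:02d}", pd.Series(mat[i], index=feats), tau=tau,
            n_cases=10, n_controls=10,
        )
        for i in range(mat.shape[0])
    }


class TestCompositeSimilarity:
    def test_weighted_sum_identity(self):
        rng = np.random.default_rng(0)
        profiles = _profiles_from_matrix(rng.normal(size=(4, 12)))
        atl = composite_similarity(profiles, omega=0.5)
        np.testing.assert_allclose(
            atl.S.to_numpy(), 0.5 * atl.J.to_numpy() + 0.5 * atl.R_rescaled.to_numpy()
        )
        # example arithmetic: J=0.5, R'=0.7 -> S=0.6
        assert 0.5 * 0.5 + 0.5 * 0.7 == pytest.approx(0.6)

    @pytest.mark.parametrize("omega,attr", [(1.0, "J"), (0.0, "R_rescaled")])
    def test_omega_limits(self, omega, attr):
        rng = np.random.default_rng(1)
        profiles = _profiles_from_matrix(rng.normal(size=(5, 10)))
        atl = composite_similarity(profiles, omega=omega)
        pd.testing.assert_frame_equal(atl.S, getattr(atl, attr))

    def test_identical_profiles_similarity_one(self):
        row = np.linspace(-1, 1, 8)
        profiles = _profiles_from_matrix(np.vstack([row, row]))
        atl = composite_similarity(profiles)
        assert atl.S.iloc[0, 1] == pytest.approx(1.0)

    def test_matrices_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(2)
        profiles = _profiles_from_matrix(rng.normal(size=(6, 15)))
        atl = composite_similarity(profiles)
        for m in (atl.J, atl.R_rescaled, atl.S):
            a = m.to_numpy()
            np.testing.assert_allclose(a, a.T)
            np.testing.assert_allclose(np.diag(a), 1.0)
            assert ((a >= 0) & (a <= 1 + 1e-12)).all()
        d = atl.D.to_numpy()
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(5, 10))
        profiles = _profiles_from_matrix(mat)
        reordered = dict(reversed(list(profiles.items())))
        a = composite_similarity(profiles)
        b = composite_similarity(reordered)
        pd.testing.assert_frame_equal(a.S, b.S)
        assert a.dendrogram.merges == b.dendrogram.merges


class TestCompleteLinkage:
    def test_three_leaf_oracle(self):
        D = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]],
            index=list("abc"), columns=list("abc"),
        )
        dend = complete_linkage(D)
        assert dend.merges[0] == (("a",), ("b",), 0.1)
        assert dend.merges[1] == (("a", "b"), ("c",), 0.9)
        part = cut_partition(dend, 2)
        groups = {frozenset(g) for g in part.as_groups()}
        assert groups == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_two_leaves(self):
        D = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["x", "y"], columns=["x", "y"])
        dend = complete_linkage(D)
        assert dend.merges == [(("x",), ("y",), 0.3)]

    def test_duplicate_points_merge_first_at_zero(self):
        D = pd.DataFrame(
            [[0, 0.0, 0.5], [0.0, 0, 0.5], [0.5, 0.5, 0]],
            index=list("abc"), columns=list("abc"),
        )
        dend = complete_linkage(D)
        assert dend.merges[0] == (("a",), ("b",), 0.0)

    def test_asymmetric_rejected(self):
        D = pd.DataFrame([[0, 0.2], [0.3, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(AtlasError, match="symmetric"):
            complete_linkage(D)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_bruteforce_and_scipy(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 8))
        dist = np.round(rng.random((n, n)), 6)
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = [f"L{i}" for i in range(n)]
        D = pd.DataFrame(dist, index=labels, columns=labels)
        dend = complete_linkage(D)
        oracle = complete_linkage_bruteforce(dist, labels)
        for (left, right, h), (oa, ob, oh) in zip(dend.merges, oracle):
            assert {frozenset(left), frozenset(right)} == {oa, ob}
            assert h == pytest.approx(oh)
        # heights also agree with scipy's condensed-form implementation
        scipy_heights = np.sort(
            scipy_hierarchy.complete(squareform(dist, checks=False))[:, 2]
        )
        np.testing.assert_allclose(
            np.sort([m[2] for m in dend.merges]), scipy_heights, atol=1e-9
        )

    def test_leaf_order_smaller_subtree_first(self):
        D = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]],
            index=list("cab"), columns=list("cab"),
        )
        order = complete_linkage(D).leaf_order()
        assert set(order) == {"a", "b", "c"}
        assert order[0] == min(order[:2])

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(5)
        dist = rng.random((5, 5))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0)
        labels = [f"T{i}" for i in range(5)]
        dend = complete_linkage(pd.DataFrame(dist, index=labels, columns=labels))
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == labels
        # root-to-leaf path length equals the root merge height for every leaf
        root_h = dend.merges[-1][2]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_h, abs=1e-5)

    def test_nondecreasing_heights_enforced(self):
        with pytest.raises(AtlasError, match="non-decreasing"):
            Dendrogram(
                leaves=["a", "b", "c"],
                merges=[(("a",), ("b",), 0.5), (("a", "b"), ("c",), 0.1)],
            )


class TestCutPartition:
    def test_extremes(self):
        rng = np.random.default_rng(6)
        dist = rng.random((4, 4))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0)
        labels = list("abcd")
        dend = complete_linkage(pd.DataFrame(dist, index=labels, columns=labels))
        assert cut_partition(dend, 4).as_groups() == [
            frozenset({lab}) for lab in labels
        ]
        assert cut_partition(dend, 1).as_groups() == [frozenset(labels)]

    def test_k_out_of_range(self):
        dend = Dendrogram(leaves=["a", "b"], merges=[(("a",), ("b",), 0.1)])
        with pytest.raises(AtlasError):
            cut_partition(dend, 3)

    def test_tie_at_cut_height_flagged(self):
        dend = Dendrogram(
            leaves=["a", "b", "c", "d"],
            merges=[
                (("a",), ("b",), 0.2),
                (("c",), ("d",), 0.2),
                (("a", "b"), ("c", "d"), 0.9),
            ],
        )
        with pytest.warns(UserWarning, match="tie"):
            part = cut_partition(dend, 3)
        assert part.tied_cut

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_cut(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 8))
        dist = rng.random((n, n))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0)
        labels = [f"L{i}" for i in range(n)]
        dend = complete_linkage(pd.DataFrame(dist, index=labels, columns=labels))
        oracle_merges = complete_linkage_bruteforce(dist, labels)
        for k in range(1, n + 1):
            got = sorted(
                (frozenset(g) for g in cut_partition(dend, k).as_groups()), key=min
            )
            assert got == cut_bruteforce(oracle_merges, labels, k)


class TestARI:
    def test_identical_partitions(self):
        a = {"x": 0, "y": 0, "z": 1}
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)

    def test_worked_negative_half(self):
        a = {1: 0, 2: 0, 3: 1, 4: 1}
        b = {1: 0, 2: 1, 3: 0, 4: 1}
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_singletons_vs_one_cluster(self):
        a = {i: i for i in range(4)}
        b = {i: 0 for i in range(4)}
        assert adjusted_rand_index(a, b) == pytest.approx(0.0)

    def test_different_universes_rejected(self):
        with pytest.raises(AtlasError):
            adjusted_rand_index({"a": 0}, {"b": 0})

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exhaustive_against_paircount_oracle(self, n):
        partitions = [partition_to_labels(p) for p in set_partitions(range(n))]
        for la in partitions:
            for lb in partitions:
                assert adjusted_rand_index(la, lb) == pytest.approx(
                    ari_paircount(la, lb)
                )

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_sklearn(self, trial):
        rng = np.random.default_rng(trial)
        n = 12
        la = {i: int(v) for i, v in enumerate(rng.integers(0, 4, n))}
        lb = {i: int(v) for i, v in enumerate(rng.integers(0, 4, n))}
        order = sorted(la)
        ref = adjusted_rand_score([la[i] for i in order], [lb[i] for i in order])
        assert adjusted_rand_index(la, lb) == pytest.approx(ref)


class TestStatinResidualize:
    def test_group_means_exactly_balanced(self):
        rng = np.random.default_rng(7)
        flags = rng.random(400) < 0.3
        m = pd.DataFrame(rng.lognormal(size=(400, 5)))
        m.loc[flags, :] -= 2.0  # constant medication offset
        resid = statin_residualize(m, flags)
        gap = resid[flags].mean() - resid[~flags].mean()
        np.testing.assert_allclose(gap, 0.0, atol=1e-8)

    def test_null_effect_residuals_near_centered_original(self):
        rng = np.random.default_rng(8)
        n = 20_000
        flags = rng.random(n) < 0.3
        m = pd.DataFrame(rng.normal(size=(n, 3)))
        resid = statin_residualize(m, flags)
        centered = (m - m.mean()) / m.std(ddof=0)
        assert np.abs(resid.to_numpy() - centered.to_numpy()).max() < 0.05

    def test_single_level_flag_rejected(self):
        m = pd.DataFrame(np.ones((5, 2)))
        with pytest.raises(AtlasError, match="both levels"):
            statin_residualize(m, np.zeros(5, dtype=bool))

    def test_covariates_accepted(self):
        rng = np.random.default_rng(9)
        n = 500
        flags = rng.random(n) < 0.4
        age = rng.normal(55, 8, n)
        m = pd.DataFrame({"f": rng.normal(size=n) + 0.1 * age - flags})
        resid = statin_residualize(m, flags, covariates=pd.DataFrame({"age": age}))
        assert abs(np.corrcoef(resid["f"], age)[0, 1]) < 0.02
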