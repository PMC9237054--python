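"""Richness, MCC trees, Faith's PD, trait-space PCA, FRic and SES nulls."""

import random

import dendropy
import numpy as np
import pandas as pd
import pytest

import oracles
from ecosens import biodiversity as bio
from ecosens import trees as treemod
from ecosens.exceptions import InputError
from ecosens.trees import TreeIndex


def _presence(data, species=None):
    df = pd.DataFrame(data)
    if species is not None:
        df.index = species
    return df


class TestRichness:
    def test_counts_column_sums(self):
        p = _presence({0: [1, 0, 1, 1], 1: [0, 0, 0, 0]})
        rich = bio.species_richness(p)
        assert rich[0] == 3 and rich[1] == 0

    def test_saturated_matrix(self):
        p = _presence(np.ones((5, 4), dtype=int))
        assert (bio.species_richness(p) == 5).all()

    def test_non_binary_entry_raises(self):
        with pytest.raises(InputError, match="not binary"):
            bio.species_richness(_presence({0: [1, 2]}))


def _trees_from_newick(*newicks):
    ns = dendropy.TaxonNamespace()
    return [dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns)
            for nwk in newicks]


class TestMCC:
    def test_majority_topology_wins(self):
        t1a, t1b, t2 = _trees_from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,C:1):1,(B:1,D:1):1);")
        assert bio.mcc_tree([t1a, t1b, t2]) is t1a

    def test_singleton_set_returns_itself(self):
        (t,) = _trees_from_newick("((A:1,B:1):1,C:2);")
        assert bio.mcc_tree([t]) is t

    def test_mismatched_tip_sets_raise(self):
        ns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick",
                               taxon_namespace=ns)
        t2 = dendropy.Tree.get(data="((A:1,B:1):1,D:2);", schema="newick",
                               taxon_namespace=ns)
        with pytest.raises(InputError):
            bio.mcc_tree([t1, t2])

    def test_base_beats_nni_perturbations_and_matches_oracle(self):
        base = treemod.yule_tree(20, seed=31)
        pyrng = random.Random(13)
        tree_set = [base.clone(depth=1) for _ in range(10)]
        tree_set += [treemod.nni_perturb(base, 2, pyrng) for _ in range(8)]
        got = bio.mcc_tree(tree_set)
        assert set(treemod.clade_sets(got)) == set(treemod.clade_sets(base))
        assert oracles.mcc_bruteforce(tree_set) == tree_set.index(got)


class TestFaithPD:
    def test_hand_tree_pair(self, hand_tree):
        assert bio.faith_pd(hand_tree, {"A", "B"}) == pytest.approx(3.0)

    def test_full_set_equals_total_branch_length(self, hand_tree):
        assert bio.faith_pd(hand_tree, {"A", "B", "C"}) == pytest.approx(5.0)

    def test_unknown_label_raises(self, hand_tree):
        with pytest.raises(InputError):
            bio.faith_pd(hand_tree, {"A", "Z"})

    def test_empty_subset_warns_and_returns_zero(self, hand_tree):
        with pytest.warns(UserWarning):
            assert bio.faith_pd(hand_tree, set()) == 0.0

    def test_matches_bruteforce_oracle_on_random_trees(self):
        rng = np.random.default_rng(8)
        for seed in range(10):
            tree = treemod.yule_tree(25, seed=seed)
            index = TreeIndex.from_dendropy(tree)
            for _ in range(5):
                k = int(rng.integers(1, 20))
                subset = rng.choice(index.labels, size=k, replace=False)
                assert bio.faith_pd(index, subset) == pytest.approx(
                    oracles.pd_bruteforce(tree, subset), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_under_species_addition(self, seed):
        tree = treemod.yule_tree(15, seed=seed)
        index = TreeIndex.from_dendropy(tree)
        rng = np.random.default_rng(seed)
        order = rng.permutation(index.labels)
        prev = 0.0
        for k in range(1, len(order) + 1):
            cur = bio.faith_pd(index, order[:k])
            assert cur >= prev - 1e-12
            prev = cur


class TestTraitSpacePCA:
    def test_perfectly_correlated_pair_retains_minimum_two_axes(self, rng):
        t1 = rng.normal(size=30)
        traits = pd.DataFrame({"t1": t1, "t2": 2 * t1},
                              index=[f"s{i}" for i in range(30)])
        space = bio.trait_space_pca(traits)
        assert space.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)
        assert space.n_retained == 2

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(3)
        traits = pd.DataFrame(rng.normal(size=(1000, 3)),
                              columns=list("abc"))
        space = bio.trait_space_pca(traits)
        assert space.n_retained == 3
        assert space.variance_fractions == pytest.approx([1 / 3] * 3, abs=0.05)

    def test_retained_variance_meets_target(self, rng):
        traits = pd.DataFrame(rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6)))
        space = bio.trait_space_pca(traits)
        assert space.retained_variance >= 0.80

    def test_missing_values_rejected(self):
        traits = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(InputError, match="impute"):
            bio.trait_space_pca(traits)


def _space(points, labels=None):
    pts = np.asarray(points, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(pts))]
    d = pts.shape[1]
    return bio.TraitSpace(
        coordinates=pd.DataFrame(pts, index=labels,
                                 columns=[f"pc{j+1}" for j in range(d)]),
        variance_fractions=np.full(d, 1.0 / d), n_retained=d)


class TestFunctionalRichness:
    def test_unit_square_area(self):
        space = _space([(0, 0), (1, 0), (0, 1), (1, 1)])
        vol, degen = bio.functional_richness(space, space.coordinates.index)
        assert vol == pytest.approx(1.0) and not degen

    def test_unit_simplex_volume(self):
        space = _space([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        vol, degen = bio.functional_richness(space, space.coordinates.index)
        assert vol == pytest.approx(1 / 6) and not degen

    def test_collinear_points_degenerate(self):
        space = _space([(0, 0), (1, 1), (2, 2)])
        vol, degen = bio.functional_richness(space, space.coordinates.index)
        assert vol == 0.0 and degen

    def test_matches_delaunay_volume_oracle(self, rng):
        import oracles as orc
        for d in (2, 3):
            for _ in range(10):
                pts = rng.normal(size=(int(rng.integers(d + 2, 30)), d))
                vol, degen = bio.hull_volume(pts)
                assert not degen
                assert vol == pytest.approx(orc.hull_volume_delaunay(pts), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_under_species_addition(self, seed):
        rng = np.random.default_rng(seed)
        space = _space(rng.normal(size=(25, 3)))
        order = rng.permutation(space.coordinates.index)
        prev = 0.0
        for k in range(1, 26):
            cur, _ = bio.functional_richness(space, order[:k])
            assert cur >= prev - 1e-12
            prev = cur


class TestSES:
    def test_hand_formula(self):
        # null distribution with mean 3 and sample sd 1
        assert bio.ses_value(5.0, [2.0, 3.0, 4.0]) == pytest.approx(2.0)

    def test_zero_variance_is_nan(self):
        assert np.isnan(bio.ses_value(5.0, [3.0, 3.0, 3.0]))

    def test_richness_equal_to_pool_reports_reason(self):
        tree = treemod.yule_tree(5, seed=1)
        labels = sorted(treemod.tip_label_set(tree))
        presence = _presence(np.ones((5, 3), dtype=int), species=labels)
        out = bio.ses_null_model("pd", presence, tree, n_reps=9, seed=0)
        assert (out["reason"] == "zero null variance").all()
        assert out["ses"].isna().all()

    def test_deterministic_under_seed(self):
        tree = treemod.yule_tree(12, seed=2)
        labels = sorted(treemod.tip_label_set(tree))
        rng = np.random.default_rng(0)
        pres = (rng.random((12, 6)) < 0.4).astype(int)
        presence = _presence(pres, species=labels)
        a = bio.ses_null_model("pd", presence, tree, n_reps=49, seed=7)
        b = bio.ses_null_model("pd", presence, tree, n_reps=49, seed=7)
        c = bio.ses_null_model("pd", presence, tree, n_reps=49, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["ses"].fillna(0), c["ses"].fillna(0))

    def test_ses_removes_richness_dependence(self):
        """Raw PD rises with richness on neutral assemblages; SES-PD does
        not (the motivation for null-model standardization)."""
        tree = treemod.yule_tree(40, seed=5)
        labels = np.array(sorted(treemod.tip_label_set(tree)))
        rng = np.random.default_rng(21)
        n_cells = 120
        pres = np.zeros((40, n_cells), dtype=int)
        for c in range(n_cells):
            r = int(rng.integers(3, 31))
            pres[rng.choice(40, size=r, replace=False), c] = 1
        presence = _presence(pres, species=labels)
        out = bio.ses_null_model("pd", presence, tree, n_reps=99, seed=3)
        rich = bio.species_richness(presence).to_numpy()
        raw_corr = np.corrcoef(rich, out["observed"])[0, 1]
        ses_corr = np.corrcoef(rich, out["ses"])[0, 1]
        assert raw_corr > 0.5
        assert abs(ses_corr) < 0.3
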