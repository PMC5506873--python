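import math

import numpy as np
import pytest

from biaslens.core_io import Alignment, SequenceRecord, parse_newick
from biaslens.phylosignal import (
    blomberg_k,
    fallback_tree,
    k_pvalue,
    nj_tree,
    p_distance,
    phylo_covariance,
    profile_signal,
)
from biaslens.conserve import conservation_profile
from biaslens.synthetic import MsaColumnSpec, gen_bm_trait, gen_msa, gen_tree

from _oracles import blomberg_k_oracle, mrca_depth_covariance, patristic_distances


class TestPhyloCovariance:
    def test_star_tree_is_identity(self, star5):
        cov, labels = phylo_covariance(star5)
        assert np.array_equal(cov, np.eye(5))

    def test_three_tip_path_arithmetic(self, basic_tree):
        cov, labels = phylo_covariance(basic_tree)
        idx = {l: i for i, l in enumerate(labels)}
        assert cov[idx["A"], idx["B"]] == 1.0
        assert cov[idx["A"], idx["A"]] == 2.0
        assert cov[idx["B"], idx["B"]] == 2.0
        assert cov[idx["C"], idx["C"]] == 2.0
        assert cov[idx["A"], idx["C"]] == 0.0

    def test_yule16_matches_mrca_oracle(self, yule16):
        cov, labels = phylo_covariance(yule16)
        oracle, olabels = mrca_depth_covariance(yule16)
        order = [olabels.index(l) for l in labels]
        assert np.allclose(cov, oracle[np.ix_(order, order)], atol=1e-12)

    def test_unrooted_errors(self):
        unrooted = parse_newick("(a:1,b:1,c:1,d:1);")
        with pytest.raises(ValueError, match="root"):
            phylo_covariance(unrooted)


class TestBlombergK:
    def test_star_tree_k_is_one_exactly(self, star5):
        trait = dict(zip("abcde", [3.0, 1.0, 4.0, 1.0, 5.0]))
        assert blomberg_k(star5, trait) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_four_tip_value(self, balanced4):
        # independent matrix-algebra oracle gives 1.8 for this configuration
        trait = dict(zip("ABCD", [0.0, 0.0, 1.0, 1.0]))
        assert blomberg_k(balanced4, trait) == pytest.approx(1.8, abs=1e-12)

    def test_matches_oracle_on_fixture_trees(self, fixture_trees):
        for i, tree in enumerate(fixture_trees):
            cov, labels = phylo_covariance(tree)
            trait = gen_bm_trait(tree, sigma=1.0, seed=100 + i)
            y = np.array([trait[l] for l in labels])
            expected = blomberg_k_oracle(cov, y)
            assert blomberg_k(tree, trait) == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self, yule16):
        trait = gen_bm_trait(yule16, seed=5)
        k0 = blomberg_k(yule16, trait)
        for a, b in [(2.5, 0.0), (-1.0, 7.0), (0.001, -3.0)]:
            scaled = {l: a * v + b for l, v in trait.items()}
            assert blomberg_k(yule16, scaled) == pytest.approx(k0, rel=1e-9)

    def test_constant_trait_undefined(self, yule16):
        trait = {l: 1.0 for l in yule16.tip_labels}
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(blomberg_k(yule16, trait))

    def test_too_few_tips(self, basic_tree):
        with pytest.raises(ValueError, match="at least 4"):
            blomberg_k(basic_tree, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_trait_label_mismatch(self, yule16):
        with pytest.raises(ValueError, match="missing"):
            blomberg_k(yule16, {"nope": 1.0})

    def test_bm_calibration_mean_near_one(self):
        tree = gen_tree(64, seed=42)
        ks = [blomberg_k(tree, gen_bm_trait(tree, 1.0, seed=s)) for s in range(1, 101)]
        assert 0.85 <= float(np.mean(ks)) <= 1.15

    def test_shuffled_traits_have_lower_mean_k(self):
        tree = gen_tree(32, seed=6)
        rng = np.random.default_rng(0)
        labels = tree.tip_labels
        bm_ks, shuf_ks = [], []
        for s in range(40):
            trait = gen_bm_trait(tree, 1.0, seed=s)
            bm_ks.append(blomberg_k(tree, trait))
            values = rng.permutation(list(trait.values()))
            shuf_ks.append(blomberg_k(tree, dict(zip(labels, values))))
        assert np.mean(shuf_ks) < np.mean(bm_ks)


class TestKPvalue:
    @pytest.fixture
    def ladder(self):
        # non-ultrametric pectinate tree: tip depth varies strongly
        return parse_newick(
            "((((((a:0.1,b:3.0):0.1,c:2.5):0.1,d:2.0):0.1,e:1.5):0.1,f:1.0):0.1,g:0.2);",
            rooted=True,
        )

    def test_strong_signal_small_p(self):
        # a deep-clade indicator trait is maximally phylogenetically clustered
        tree = gen_tree(32, seed=8)
        clade = {n.label for n in tree.root.children[0].preorder() if n.is_leaf}
        trait = {l: (1.0 if l in clade else 0.0) for l in tree.tip_labels}
        result = k_pvalue(tree, trait, n_perm=999, seed=4)
        assert result.p <= 0.05

    def test_depth_trait_on_nonultrametric_tree(self, ladder):
        depths = ladder.tip_depths()
        result = k_pvalue(ladder, depths, n_perm=999, seed=4)
        assert result.k > 0

    def test_seed_determinism(self, yule16):
        trait = gen_bm_trait(yule16, seed=9)
        r1 = k_pvalue(yule16, trait, n_perm=199, seed=7)
        r2 = k_pvalue(yule16, trait, n_perm=199, seed=7)
        assert r1.p == r2.p and r1.k == r2.k

    def test_p_bounds(self, yule16):
        trait = gen_bm_trait(yule16, seed=9)
        result = k_pvalue(yule16, trait, n_perm=99, seed=1)
        assert 1 / 100 <= result.p <= 1.0

    def test_null_calibration_mean_p_near_half(self, yule16):
        rng = np.random.default_rng(3)
        labels = yule16.tip_labels
        ps = []
        for i in range(40):
            values = rng.normal(size=len(labels))
            result = k_pvalue(yule16, dict(zip(labels, values)), n_perm=99, seed=i)
            ps.append(result.p)
        assert 0.3 <= float(np.mean(ps)) <= 0.7

    def test_min_permutations_enforced(self, yule16):
        trait = gen_bm_trait(yule16, seed=9)
        with pytest.raises(ValueError, match="99"):
            k_pvalue(yule16, trait, n_perm=10, seed=0)


class TestDistanceFallback:
    def test_additive_matrix_recovered(self):
        # unrooted quartet AB|CD: terminal edges 2,3,4,5; internal edge 1
        labels = ["A", "B", "C", "D"]
        dist = np.array(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 0.0, 0.0],
            ]
        )
        dist[3, 2] = dist[2, 3] = 9.0
        dist[3, 3] = 0.0
        tree = nj_tree(dist, labels)
        pat = patristic_distances(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert pat[(a, b)] == pytest.approx(dist[i, j], abs=1e-9)

    def test_identical_sequences_zero_distance(self):
        aln = Alignment(
            [SequenceRecord(f"s{i}", "ACDEFG") for i in range(3)]
        )
        dist, labels = p_distance(aln)
        assert np.array_equal(dist, np.zeros((3, 3)))

    def test_p_distance_ignores_gapped_columns(self):
        aln = Alignment(
            [
                SequenceRecord("x", "AC-DEF"),
                SequenceRecord("y", "ACQD-F"),
                SequenceRecord("z", "GCQDEF"),
            ]
        )
        dist, labels = p_distance(aln)
        idx = {l: i for i, l in enumerate(labels)}
        # x vs y: comparable columns 1,2,4,6 -> 0 mismatches
        assert dist[idx["x"], idx["y"]] == 0.0
        # x vs z: comparable 1,2,4,5,6 -> 1 mismatch (col 1)
        assert dist[idx["x"], idx["z"]] == pytest.approx(1 / 5)

    def test_known_divergence_within_binomial_error(self):
        msa, _ = gen_msa(
            2, 400,
            {c: MsaColumnSpec("A", "S", 1.0, 0.0) for c in range(1, 81)},
            seed=30,
        )
        # focalA and focalB differ at exactly the 80 planted columns
        sub = Alignment([msa["focalA"], msa["focalB"]])
        dist, labels = p_distance(sub)
        assert dist[0, 1] == pytest.approx(80 / 400)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_bad_matrix(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0.0, 1.0, 2.0], [9.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),
                    ["a", "b", "c"])

    def test_fallback_tree_from_alignment(self):
        msa, _ = gen_msa(6, 120, {5: MsaColumnSpec("A", "S", 0.5, 0.5)}, seed=12)
        tree = fallback_tree(msa)
        assert sorted(tree.tip_labels) == sorted(msa.ids())


class TestProfileSignal:
    def test_appends_k_and_p_columns(self, bundle):
        msa = bundle["msa"]
        profile = conservation_profile(msa, "focalA", "focalB").head(2)
        out = profile_signal(
            profile, bundle["tree"], msa, "focalA", "focalB", n_perm=99, seed=5
        )
        for col in ("k_a", "p_a", "k_b", "p_b"):
            assert col in out.columns
        assert len(out) == 2
        assert ((out["p_a"].dropna() >= 0.01) & (out["p_a"].dropna() <= 1.0)).all()
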