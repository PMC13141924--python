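import itertools

import numpy as np
import pandas as pd
import pytest

from pairedmicro.diversity import (
    DistanceMatrix,
    alpha_group_test,
    alpha_indices,
    alpha_table,
    beta_distance,
    pcoa,
    permanova,
    rarefy,
)
from pairedmicro.tables import CohortMetadata

from conftest import counts_table


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        t = counts_table([[3, 5, 2]])
        out = rarefy(t, depth=10, seed=0)
        pd.testing.assert_frame_equal(out.data, t.data, check_dtype=False)

    def test_all_totals_equal_depth(self):
        rng = np.random.default_rng(0)
        t = counts_table(rng.integers(5, 100, (4, 6)))
        out = rarefy(t, depth=20, seed=1)
        assert (out.data.sum(axis=1) == 20).all()
        assert (out.data.to_numpy() <= t.data.to_numpy()).all()

    def test_matches_hypergeometric_expectation(self):
        # E[count] = depth * x / N for sampling without replacement
        t = counts_table([[40, 30, 20, 10]])
        draws = np.array([
            rarefy(t, depth=50, seed=s).data.to_numpy()[0] for s in range(1000)
        ])
        expected = 50 * np.array([40, 30, 20, 10]) / 100
        assert np.allclose(draws.mean(axis=0), expected, rtol=0.02)

    def test_depth_above_sample_total_names_sample(self):
        t = counts_table([[3, 3], [50, 50]], sample_ids=["shallow", "deep"])
        with pytest.raises(ValueError, match="shallow"):
            rarefy(t, depth=10, seed=0)

    def test_deterministic_under_seed(self):
        t = counts_table([[40, 30, 20, 10]])
        a = rarefy(t, depth=30, seed=9).data
        b = rarefy(t, depth=30, seed=9).data
        pd.testing.assert_frame_equal(a, b)


class TestAlphaIndices:
    def test_chao1_closed_form(self):
        # S=4, F1=2, F2=1: chao1 = 4 + 2*1/(2*2) = 4.5
        assert alpha_indices([5, 1, 1, 2])["chao1"] == pytest.approx(4.5)

    def test_shannon_uniform(self):
        assert alpha_indices([1, 1, 1, 1])["shannon"] == pytest.approx(np.log(4))

    def test_single_taxon_extremes(self):
        out = alpha_indices([10])
        assert out["simpson"] == pytest.approx(1.0)
        assert out["shannon"] == pytest.approx(0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            alpha_indices([0, 0])

    def test_estimators_bound_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.integers(0, 30, size=12)
            if v.sum() == 0:
                continue
            out = alpha_indices(v)
            assert out["chao1"] >= out["sobs"]
            assert out["ace"] >= out["sobs"] - 1e-9

    def test_matches_reference_implementation(self):
        # scikit-bio computes the same bias-corrected Chao1 and ACE variants
        from skbio.diversity.alpha import ace as sk_ace
        from skbio.diversity.alpha import chao1 as sk_chao1

        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.integers(0, 25, size=15)
            if (v > 0).sum() < 2 or not (v == 1).any() or (v[(v > 0)] > 10).sum() == 0:
                continue
            out = alpha_indices(v)
            assert out["chao1"] == pytest.approx(sk_chao1(v, bias_corrected=True))
            assert out["ace"] == pytest.approx(sk_ace(v), rel=1e-9)


class TestAlphaGroupTest:
    def test_single_index_fdr_equals_p(self, tiny_meta):
        rng = np.random.default_rng(0)
        alpha = pd.DataFrame(
            {"shannon": rng.normal(2, 0.3, len(tiny_meta.sample_ids))},
            index=tiny_meta.sample_ids,
        )
        out = alpha_group_test(alpha, tiny_meta)
        assert out.loc[0, "fdr"] == pytest.approx(out.loc[0, "p"])

    def test_richness_expansion_detected_but_not_evenness(self):
        # LUAD gains many rare taxa: richness indices should move, Shannon and
        # Simpson (evenness-driven here) much less
        from pairedmicro.simulate import (
            SimulationConfig,
            simulate_cohort_design,
            simulate_genus_asv_tables,
        )

        cfg = SimulationConfig(
            n_patients=40, p_both_tissues=0.8, n_genera=60, n_planted_diff=0,
            n_rare_expansion=30, rare_presence_nc=0.05, rare_presence_luad=0.7,
            sigma_patient=0.2, seed=5,
        )
        meta = simulate_cohort_design(cfg)
        genus, _, _, _ = simulate_genus_asv_tables(cfg, meta)
        rare = rarefy(genus, seed=0)
        out = alpha_group_test(alpha_table(rare), meta).set_index("index")
        assert out.loc["sobs", "fdr"] < 0.05
        assert out.loc["chao1", "fdr"] < 0.05
        assert out.loc["sobs", "beta"] > 0


class TestBetaDistance:
    def test_disjoint_samples_are_maximally_distant(self):
        t = counts_table([[2, 0], [0, 2]])
        assert beta_distance(t, "bray_curtis").matrix[0, 1] == pytest.approx(1.0)
        assert beta_distance(t, "binary_hamming").matrix[0, 1] == pytest.approx(1.0)

    def test_identical_samples_distance_zero(self, tmp_path):
        t = counts_table([[3, 1, 4], [3, 1, 4]])
        for metric in ("bray_curtis", "binary_hamming"):
            assert beta_distance(t, metric).matrix[0, 1] == pytest.approx(0.0)

    def test_binary_hamming_fraction(self):
        t = counts_table([[1, 0, 1], [1, 1, 0]])
        assert beta_distance(t, "binary_hamming").matrix[0, 1] == pytest.approx(2 / 3)

    def test_binary_metric_ignores_abundance_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, (4, 7))
        a = beta_distance(counts_table(x), "binary_hamming").matrix
        b = beta_distance(counts_table(x * 13), "binary_hamming").matrix
        assert np.allclose(a, b)

    def test_unweighted_unifrac_hand_derived(self, tmp_path):
        # tree ((A:1,B:2):0.5,(C:1,D:1):0.5); s1={A,C}, s2={B,D}
        # shared branch length = 0.5+0.5, union = 6 -> distance 5/6
        from pairedmicro.tables import read_tree

        p = tmp_path / "t.nwk"
        p.write_text("((A:1.0,B:2.0):0.5,(C:1.0,D:1.0):0.5);\n")
        tree = read_tree(p)
        t = counts_table([[1, 0, 2, 0], [0, 3, 0, 1]], feature_ids=list("ABCD"))
        d = beta_distance(t, "unweighted_unifrac", tree=tree)
        assert d.matrix[0, 1] == pytest.approx(5 / 6)

    def test_unifrac_requires_tree(self):
        with pytest.raises(ValueError, match="tree"):
            beta_distance(counts_table([[1, 2], [2, 1]]), "weighted_unifrac")


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(8)], "bray_curtis")
        coords, _, _ = pcoa(d)
        rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rec, d.matrix, atol=1e-8)

    def test_equilateral_triangle_has_equal_leading_eigenvalues(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
                           ["a", "b", "c"], "bray_curtis")
        _, eigvals, _ = pcoa(d)
        assert eigvals[0] == pytest.approx(eigvals[1])
        assert eigvals[0] > 0

    def test_duplicate_samples_coincide(self):
        m = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        d = DistanceMatrix(m, ["a", "a2", "b"], "bray_curtis")
        coords, _, _ = pcoa(d)
        assert np.allclose(coords.loc["a"], coords.loc["a2"], atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0, 1.0], [0.5, 0]]), ["a", "b"], "bray_curtis")


class TestPermanova:
    def two_cluster_distance(self, per_group=8):
        pts = np.vstack([np.zeros((per_group, 2)), np.ones((per_group, 2)) * 10])
        pts = pts + np.random.default_rng(0).normal(0, 0.01, pts.shape)
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(squareform(pdist(pts)),
                              [f"s{i}" for i in range(2 * per_group)], "bray_curtis")

    def test_complete_separation_gives_minimal_p(self):
        d = self.two_cluster_distance()
        res = permanova(d, [0] * 8 + [1] * 8, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.r_squared > 0.9

    def test_statistic_matches_independent_implementation(self):
        import skbio

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(12)]
        d = DistanceMatrix(squareform(pdist(pts)), ids, "bray_curtis")
        labels = np.array([0] * 6 + [1] * 6)
        ours = permanova(d, labels, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.matrix, ids), labels.astype(str), permutations=99
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"])

    def test_p_close_to_exhaustive_enumeration(self):
        # n=6: enumerate all 6!/(3!3!) relabelings exactly
        from pairedmicro.diversity import _permanova_f

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(6)],
                           "bray_curtis")
        labels = np.array([0, 0, 0, 1, 1, 1])
        dsq = d.matrix**2
        f_obs, _ = _permanova_f(dsq, labels)
        fs = [_permanova_f(dsq, np.array(perm))[0]
              for perm in set(itertools.permutations(labels))]
        p_exact = float(np.mean([f >= f_obs - 1e-12 for f in fs]))
        res = permanova(d, labels, n_permutations=999, seed=4)
        assert abs(res.p_value - p_exact) < 0.06

    def test_r_squared_invariant_to_distance_scaling(self):
        d = self.two_cluster_distance()
        labels = [0] * 8 + [1] * 8
        a = permanova(d, labels, n_permutations=49, seed=0)
        d2 = DistanceMatrix(d.matrix * 3.7, d.ids, d.metric)
        b = permanova(d2, labels, n_permutations=49, seed=0)
        assert a.r_squared == pytest.approx(b.r_squared)
        assert a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_singleton_group_rejected(self):
        d = self.two_cluster_distance()
        with pytest.raises(ValueError):
            permanova(d, [0] + [1] * 15, n_permutations=9, seed=0)

    def test_membership_metric_more_sensitive_on_rare_expansion(self):
        # planted presence/absence shift: binary metric separates groups at
        # least as strongly as the abundance-weighted one
        from pairedmicro.simulate import (
            SimulationConfig,
            simulate_cohort_design,
            simulate_genus_asv_tables,
        )

        cfg = SimulationConfig(
            n_patients=30, p_both_tissues=0.8, n_genera=50, n_planted_diff=0,
            n_rare_expansion=25, rare_presence_nc=0.05, rare_presence_luad=0.65,
            sigma_patient=0.2, seed=2,
        )
        meta = simulate_cohort_design(cfg)
        genus, _, _, _ = simulate_genus_asv_tables(cfg, meta)
        groups = meta.tissue_indicator(genus.sample_ids)
        p_binary = permanova(beta_distance(genus, "binary_hamming"), groups,
                             n_permutations=199, seed=0).p_value
        p_bray = permanova(beta_distance(genus, "bray_curtis"), groups,
                           n_permutations=199, seed=0).p_value
        assert p_binary <= p_bray
        assert p_binary < 0.05
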