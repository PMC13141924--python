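import numpy as np
import pandas as pd
import pytest

from pairedmicro.functions import (
    RetentionThresholds,
    ko_lopo_screen,
    module_score_test,
    module_scores,
    normalize_and_clr,
    pathway_level_test,
    retain_and_partition,
)
from pairedmicro.tables import CohortMetadata, FeatureTable

from conftest import counts_table


def paired_meta(n_patients, paired_frac=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        rows.append(dict(sample_id=f"{pid}_LUAD", patient_id=pid, tissue="LUAD"))
        if rng.random() < paired_frac:
            rows.append(dict(sample_id=f"{pid}_NC", patient_id=pid, tissue="NC"))
    return CohortMetadata(pd.DataFrame(rows))


def module_map_for(ko_ids, module="biofilm_QS"):
    return pd.DataFrame({"module": [module] * len(ko_ids), "ko_id": list(ko_ids)})


def homogeneous_cohort(beta=1.5, n_patients=12, noise=0.1, seed=4):
    """Every patient shows the same LUAD shift in KO_sig; KO_null is noise."""
    meta = paired_meta(n_patients, seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in meta.frame.iterrows():
        u = 0.3 * rng.normal()
        shift = beta if r["tissue"] == "LUAD" else 0.0
        sig = np.exp(2 + u + shift + noise * rng.normal())
        null = np.exp(2 + u + noise * rng.normal())
        ref = np.exp(3 + noise * rng.normal())
        rows.append([sig, null, ref])
    table = FeatureTable(
        pd.DataFrame(rows, index=meta.sample_ids, columns=["KO_sig", "KO_null", "KO_ref"]),
        scale="score",
    )
    return table, meta


class TestKoLopoScreen:
    def test_homogeneous_effect_fully_sign_consistent(self):
        table, meta = homogeneous_cohort()
        rec = ko_lopo_screen(table, meta, module_map_for(table.feature_ids))
        rec = rec.set_index("ko_id")
        assert rec.loc["KO_sig", "sign_consistency"] == 1.0
        assert rec.loc["KO_sig", "beta_median"] > 0.3

    def test_one_lopo_fit_per_patient(self):
        table, meta = homogeneous_cohort(n_patients=8)
        rec = ko_lopo_screen(table, meta, module_map_for(table.feature_ids))
        assert (rec["n_lopo"] + rec["n_lopo_failures"] == 8).all()

    def test_beta_median_within_lopo_range(self):
        # direct property check via a manual LOPO recomputation
        from pairedmicro.stats import fit_random_intercept_lmm

        table, meta = homogeneous_cohort(beta=0.8, noise=0.4, seed=9)
        clr = normalize_and_clr(table)
        y = clr.data["KO_sig"].to_numpy()
        betas = []
        patients = meta.patients_of(clr.sample_ids)
        for pid in np.unique(patients):
            mask = patients != pid
            sub = [s for s, k in zip(clr.sample_ids, mask) if k]
            betas.append(fit_random_intercept_lmm(y[mask], meta, sample_ids=sub).beta)
        rec = ko_lopo_screen(table, meta, module_map_for(table.feature_ids))
        bm = rec.set_index("ko_id").loc["KO_sig", "beta_median"]
        assert min(betas) - 1e-9 <= bm <= max(betas) + 1e-9

    def test_single_driver_patient_fails_consistency_gate(self):
        # effect exists only in one extreme patient: LOPO flips when removed
        meta = paired_meta(8, seed=1)
        rng = np.random.default_rng(1)
        rows = []
        for _, r in meta.frame.iterrows():
            driver = r["patient_id"] == "P000"
            shift = 6.0 if (driver and r["tissue"] == "LUAD") else 0.0
            jitter = rng.normal(0, 0.4)
            # small alternating anti-signal in the other patients
            anti = -0.25 if (not driver and r["tissue"] == "LUAD") else 0.0
            rows.append([np.exp(2 + shift + anti + jitter), np.exp(3 + jitter * 0.5)])
        table = FeatureTable(
            pd.DataFrame(rows, index=meta.sample_ids, columns=["KO_driver", "KO_ref"]),
            scale="score",
        )
        rec = ko_lopo_screen(table, meta, module_map_for(table.feature_ids))
        rec = retain_and_partition(rec).set_index("ko_id")
        assert rec.loc["KO_driver", "sign_consistency"] < 0.90
        assert not rec.loc["KO_driver", "retained"]

    def test_missing_module_assignment_rejected(self):
        table, meta = homogeneous_cohort(n_patients=6)
        with pytest.raises(Exception, match="module"):
            ko_lopo_screen(table, meta, module_map_for(["KO_sig"]))


class TestRetainAndPartition:
    def record(self, prev, bm, sc):
        return pd.DataFrame([dict(ko_id="K1", module="m", beta_full=bm,
                                  beta_median=bm, sign_consistency=sc,
                                  prevalence=prev)])

    @pytest.mark.parametrize(
        "prev, bm, sc, retained, direction",
        [
            (0.50, 0.31, 0.95, True, "up"),
            (0.19, 2.00, 1.00, False, ""),      # prevalence just below gate
            (0.50, -0.31, 0.90, True, "down"),  # boundaries are inclusive
            (0.20, 0.30, 0.90, True, "up"),     # all three exactly at gate
            (0.50, 0.29, 1.00, False, ""),
            (0.50, 0.31, 0.89, False, ""),
        ],
    )
    def test_conjunctive_inclusive_gates(self, prev, bm, sc, retained, direction):
        out = retain_and_partition(self.record(prev, bm, sc))
        assert bool(out.loc[0, "retained"]) is retained
        assert out.loc[0, "direction"] == direction

    def test_raising_any_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        recs = pd.DataFrame({
            "ko_id": [f"K{i}" for i in range(50)],
            "module": "m",
            "beta_full": rng.normal(0, 1, 50),
            "beta_median": rng.normal(0, 1, 50),
            "sign_consistency": rng.random(50),
            "prevalence": rng.random(50),
        })
        base = retain_and_partition(recs)["retained"]
        for thr in (RetentionThresholds(prevalence=0.5),
                    RetentionThresholds(beta_min=0.8),
                    RetentionThresholds(consistency_min=0.99)):
            stricter = retain_and_partition(recs, thr)["retained"]
            assert not (stricter & ~base).any()


class TestModuleScores:
    def clr_and_records(self):
        t = counts_table([[10, 20, 5], [4, 2, 9], [7, 7, 7], [1, 30, 2]],
                         feature_ids=["K1", "K2", "K3"])
        clr = normalize_and_clr(t, pseudocount=0.01)
        recs = pd.DataFrame({
            "ko_id": ["K1", "K2", "K3"],
            "module": ["mA", "mA", "mB"],
            "beta_median": [0.5, 0.7, -0.6],
            "retained": [True, True, True],
            "direction": ["up", "up", "down"],
        })
        return clr, recs

    def test_singleton_subset_score_is_the_clr_value(self):
        clr, recs = self.clr_and_records()
        scores = module_scores(clr, recs)
        pd.testing.assert_series_equal(
            scores[("mB", "down")], clr.data["K3"], check_names=False
        )

    def test_mean_of_member_kos(self):
        clr, recs = self.clr_and_records()
        scores = module_scores(clr, recs)
        expected = clr.data[["K1", "K2"]].mean(axis=1)
        pd.testing.assert_series_equal(scores[("mA", "up")], expected,
                                       check_names=False)

    def test_direction_subsets_are_disjoint(self):
        clr, recs = self.clr_and_records()
        recs.loc[2, "module"] = "mA"  # K3 down in same module as K1/K2 up
        scores = module_scores(clr, recs)
        assert ("mA", "up") in scores and ("mA", "down") in scores
        # no KO contributes to both subsets
        assert set(["K1", "K2"]).isdisjoint({"K3"})

    def test_unretained_kos_are_excluded(self):
        clr, recs = self.clr_and_records()
        recs.loc[1, "retained"] = False
        scores = module_scores(clr, recs)
        pd.testing.assert_series_equal(
            scores[("mA", "up")], clr.data["K1"], check_names=False
        )


class TestModuleScoreTest:
    def test_planted_module_subset_detected(self):
        table, meta = homogeneous_cohort(beta=2.0, n_patients=20, seed=6)
        rec = retain_and_partition(
            ko_lopo_screen(table, meta, module_map_for(table.feature_ids))
        )
        clr = normalize_and_clr(table)
        tests = module_score_test(module_scores(clr, rec), meta)
        up = tests[(tests["module"] == "biofilm_QS") & (tests["direction"] == "up")]
        assert len(up) == 1
        assert up["beta"].iloc[0] > 0
        assert up["fdr"].iloc[0] < 0.05

    def test_fdr_within_direction_single_module_equals_p(self):
        table, meta = homogeneous_cohort(beta=1.0, n_patients=10, seed=2)
        rec = retain_and_partition(
            ko_lopo_screen(table, meta, module_map_for(table.feature_ids))
        )
        clr = normalize_and_clr(table)
        tests = module_score_test(module_scores(clr, rec), meta)
        for direction in tests["direction"].unique():
            sub = tests[tests["direction"] == direction]
            if len(sub) == 1:
                assert sub["fdr"].iloc[0] == pytest.approx(sub["p"].iloc[0])


class TestPathwayLevelTest:
    def test_single_pathway_fdr_equals_p(self):
        table, meta = homogeneous_cohort(n_patients=8, seed=8)
        single = FeatureTable(table.data[["KO_ref"]].copy() + 0.5, scale="score")
        out = pathway_level_test(single, meta)
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])

    def test_planted_pathway_detected_null_not(self):
        table, meta = homogeneous_cohort(beta=2.0, n_patients=20, seed=10)
        out = pathway_level_test(table, meta).set_index("pathway")
        assert out.loc["KO_sig", "q"] < 0.05
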