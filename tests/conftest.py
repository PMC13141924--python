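import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pairedmicro.simulate import (
    SimulationConfig,
    simulate_bundle,
    simulate_cohort_design,
    simulate_genus_asv_tables,
)
from pairedmicro.tables import CohortMetadata, FeatureTable

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_meta() -> CohortMetadata:
    """Six patients, four of them paired: the smallest realistic design."""
    rows = []
    for i in range(1, 7):
        pid = f"P{i:03d}"
        rows.append(dict(sample_id=f"{pid}_LUAD", patient_id=pid, tissue="LUAD"))
        if i <= 4:
            rows.append(dict(sample_id=f"{pid}_NC", patient_id=pid, tissue="NC"))
    return CohortMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_bundle():
    cfg = SimulationConfig(
        n_patients=20, p_both_tissues=0.6, n_genera=30, n_planted_diff=3,
        effect_logfc=2.0, n_rare_expansion=5, n_kos=24, n_planted_kos=6,
        n_pathways=6, seed=7,
    )
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with two strongly planted genera, for marker-selection tests."""
    cfg = SimulationConfig(
        n_patients=30, p_both_tissues=0.6, n_genera=25, n_planted_diff=2,
        effect_logfc=3.0, n_rare_expansion=0, sigma_patient=0.3, seed=11,
    )
    meta = simulate_cohort_design(cfg)
    genus, _, _, truth = simulate_genus_asv_tables(cfg, meta)
    return genus, meta, truth


def counts_table(matrix, sample_ids=None, feature_ids=None) -> FeatureTable:
    matrix = np.asarray(matrix)
    sample_ids = sample_ids or [f"s{i+1}" for i in range(matrix.shape[0])]
    feature_ids = feature_ids or [f"f{j+1}" for j in range(matrix.shape[1])]
    return FeatureTable(
        pd.DataFrame(matrix, index=sample_ids, columns=feature_ids), scale="counts"
    )
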