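"""Synthetic partially paired lung-tissue cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: every patient contributes a tumor (LUAD) sample and a Bernoulli
subset also contributes a distal noncancerous (NC) sample; genus abundances
follow a logistic-normal-multinomial model (log-scale Gaussian structure
with a patient random intercept and planted tissue effects, softmax
composition, multinomial read counts with log-normal library sizes); a set
of low-prevalence taxa is presence/absence-modulated with elevated presence
probability in tumors, so membership-based community metrics separate the
groups while abundance-weighted ones need not; ASVs partition each genus's
counts exactly; KO abundances arise from a nonnegative genus-to-KO loading
matrix with planted direction-specific tissue effects, and pathways are
grouped KO sums.  All distributional choices are stand-ins with no
biological claim; they exist so the pipeline is testable without external
data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    CohortMetadata,
    FeatureTable,
    TaxonomyMap,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)

MODULE_NAMES = (
    "LPS_lipidA",
    "peptidoglycan",
    "secretion_systems",
    "biofilm_QS",
    "fatty_acid_metabolism",
    "beta_lactam_resistance",
    "SCFA_metabolism",
    "tryptophan_indole_metabolism",
    "redox_stress_response",
    "nitrogen_sulfur_metabolism",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.  Defaults mirror the study design:
    34 tumor patients of whom 14/34 contribute a matched NC sample."""

    n_patients: int = 34
    p_both_tissues: float = 14 / 34
    n_genera: int = 80
    n_planted_diff: int = 7
    effect_logfc: float = 1.5          # magnitude; signs alternate (+,-,+,...)
    n_rare_expansion: int = 15
    rare_presence_nc: float = 0.10     # Bernoulli presence probability in NC
    rare_presence_luad: float = 0.50   # ... and in LUAD
    sigma_patient: float = 0.5         # SD of the patient random intercept (log scale)
    sigma_noise: float = 0.6           # residual per-sample log-scale SD
    library_size_logmean: float = 9.2  # ln-scale; exp(9.2) ~ 1e4 reads
    library_size_logsd: float = 0.4
    asv_per_genus_range: tuple[int, int] = (1, 5)
    n_kos: int = 60
    n_planted_kos: int = 10
    ko_effect: float = 1.0
    ko_noise_sd: float = 0.3
    n_pathways: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("invalid design: need at least 2 patients")
        for name in ("n_genera", "n_kos", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_both_tissues", "rare_presence_nc", "rare_presence_luad"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("sigma_patient", "sigma_noise", "library_size_logsd", "ko_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.asv_per_genus_range
        if lo < 1 or hi < lo:
            raise ValueError("asv_per_genus_range must be an interval with low >= 1")
        if self.n_planted_diff + self.n_rare_expansion > self.n_genera:
            raise ValueError("planted + rare-expansion genera exceed n_genera")
        if self.n_planted_kos > self.n_kos:
            raise ValueError("n_planted_kos exceeds n_kos")


@dataclass
class GroundTruth:
    planted_diff_genera: list[tuple[str, float]] = field(default_factory=list)
    rare_expansion_taxa: list[str] = field(default_factory=list)
    planted_kos: list[tuple[str, str]] = field(default_factory=list)  # (ko, up|down)
    patient_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    metadata: CohortMetadata
    genus_table: FeatureTable
    asv_table: FeatureTable
    taxonomy: TaxonomyMap
    tree_newick: str
    ko_table: FeatureTable
    pathway_table: FeatureTable
    module_map: pd.DataFrame
    ground_truth: GroundTruth


def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Stage-keyed substream so each component is independently reproducible."""
    key = int.from_bytes(stage.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def simulate_cohort_design(config: SimulationConfig) -> CohortMetadata:
    """Every patient contributes a LUAD sample; a Bernoulli(p_both_tissues)
    subset also contributes an NC sample."""
    config.validate()
    rng = _rng_for(config, "design")
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rows.append(dict(sample_id=f"{pid}_LUAD", patient_id=pid, tissue="LUAD"))
        if rng.random() < config.p_both_tissues:
            rows.append(dict(sample_id=f"{pid}_NC", patient_id=pid, tissue="NC"))
    return CohortMetadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genus / ASV tables
# ---------------------------------------------------------------------------

def _genus_names(config: SimulationConfig) -> list[str]:
    names = [f"Genus_{i + 1:03d}" for i in range(config.n_genera)]
    # a few genus-level units carry the field's unclassified/norank naming
    if config.n_genera >= 3:
        names[-1] = "unclassified_f__Family_X"
        names[-2] = "norank_c__Class_Y"
    return names


def simulate_genus_asv_tables(
    config: SimulationConfig, metadata: CohortMetadata
) -> tuple[FeatureTable, FeatureTable, TaxonomyMap, GroundTruth]:
    """Logistic-normal-multinomial genus counts, partitioned into ASVs."""
    config.validate()
    rng = _rng_for(config, "tables")
    genera = _genus_names(config)
    n_g = config.n_genera

    baseline = rng.normal(0.0, 2.0, size=n_g)
    order = rng.permutation(n_g)
    planted_idx = order[: config.n_planted_diff]
    rare_idx = order[config.n_planted_diff: config.n_planted_diff + config.n_rare_expansion]
    # planted differential genera get mid-range baselines so they are
    # detectable (pass prevalence filtering) in both tissues
    baseline[planted_idx] = rng.normal(0.5, 0.75, size=len(planted_idx))
    baseline[rare_idx] = rng.normal(-3.5, 0.5, size=len(rare_idx))

    effects = np.zeros(n_g)
    truth = GroundTruth()
    for k, gi in enumerate(planted_idx):
        signed = config.effect_logfc * (1.0 if k % 2 == 0 else -1.0)
        effects[gi] = signed
        truth.planted_diff_genera.append((genera[gi], signed))
    truth.rare_expansion_taxa = [genera[gi] for gi in rare_idx]

    patient_u = {
        pid: rng.normal(0.0, config.sigma_patient) for pid in metadata.patient_ids
    }
    truth.patient_effects = patient_u

    sample_ids = metadata.sample_ids
    is_luad = metadata.tissue_indicator(sample_ids)
    patients = metadata.patients_of(sample_ids)

    # ASV structure per genus, fixed across samples
    asv_counts_per_genus = rng.integers(
        config.asv_per_genus_range[0], config.asv_per_genus_range[1] + 1, size=n_g
    )
    asv_ids, asv_genus, asv_props = [], [], []
    lineages: dict[str, str] = {}
    for gi, g in enumerate(genera):
        k = int(asv_counts_per_genus[gi])
        props = rng.dirichlet(np.full(k, 2.0))
        for j in range(k):
            aid = f"ASV_{len(asv_ids) + 1:04d}"
            asv_ids.append(aid)
            asv_genus.append(gi)
            asv_props.append(props[j])
            gtoken = g if not g.startswith("Genus_") else f"g__{g}"
            lineages[aid] = (
                f"d__Bacteria;p__Phylum_{gi % 6 + 1};c__Class_{gi % 6 + 1};"
                f"o__Order_{gi % 6 + 1};f__Family_{gi % 10 + 1};{gtoken}"
            )
    asv_genus = np.asarray(asv_genus)
    asv_props = np.asarray(asv_props)

    rare_mask = np.zeros(n_g, dtype=bool)
    rare_mask[rare_idx] = True
    genus_counts = np.zeros((len(sample_ids), n_g), dtype=np.int64)
    asv_counts = np.zeros((len(sample_ids), len(asv_ids)), dtype=np.int64)
    for si, sid in enumerate(sample_ids):
        eta = (
            baseline
            + patient_u[patients[si]]
            + effects * is_luad[si]
            + rng.normal(0.0, config.sigma_noise, size=n_g)
        )
        p_present = (
            config.rare_presence_luad if is_luad[si] > 0 else config.rare_presence_nc
        )
        present = np.ones(n_g, dtype=bool)
        present[rare_mask] = rng.random(int(rare_mask.sum())) < p_present
        w = np.exp(eta - eta.max())
        w[~present] = 0.0
        probs = w / w.sum()
        depth = max(int(np.round(rng.lognormal(
            config.library_size_logmean, config.library_size_logsd))), 100)
        gcounts = rng.multinomial(depth, probs)
        genus_counts[si] = gcounts
        for gi in np.flatnonzero(gcounts):
            members = np.flatnonzero(asv_genus == gi)
            split = rng.multinomial(gcounts[gi], asv_props[members] / asv_props[members].sum())
            asv_counts[si, members] = split

    genus_table = FeatureTable(
        pd.DataFrame(genus_counts, index=sample_ids, columns=genera), scale="counts"
    )
    asv_table = FeatureTable(
        pd.DataFrame(asv_counts, index=sample_ids, columns=asv_ids), scale="counts"
    )
    return genus_table, asv_table, TaxonomyMap(lineages), truth


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(asv_ids, seed: int = 0) -> str:
    """Rooted binary tree over the ASV ids by random coalescent-style joins
    with exponential branch lengths.  Returns a Newick string."""
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 tips")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tip ids")
    rng = np.random.default_rng(seed)
    nodes = [f"{tid}:{rng.exponential(1.0) + 0.01:.6f}" for tid in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        length = rng.exponential(1.0) + 0.01
        nodes.append(f"({a},{b}):{length:.6f}")
        if len(nodes) == 1:
            inner = nodes[0].rsplit(":", 1)[0]
            return f"{inner};"
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# KO / pathway tables
# ---------------------------------------------------------------------------

def simulate_function_tables(
    config: SimulationConfig,
    genus_table: FeatureTable,
    metadata: CohortMetadata,
    truth: GroundTruth,
    loading: np.ndarray | None = None,
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame]:
    """KO abundances from a nonnegative genus-to-KO loading matrix, with
    planted direction-specific tissue effects; pathways are grouped sums."""
    config.validate()
    rng = _rng_for(config, "functions")
    n_k = config.n_kos
    ko_ids = [f"K{i + 1:05d}" for i in range(n_k)]
    rel = genus_table.data.div(genus_table.data.sum(axis=1), axis=0).to_numpy()

    if loading is None:
        loading = np.zeros((config.n_genera, n_k))
        for k in range(n_k):
            donors = rng.choice(config.n_genera, size=min(5, config.n_genera), replace=False)
            loading[donors, k] = rng.gamma(2.0, 1.0, size=len(donors))
    loading = np.asarray(loading, dtype=float)
    if (loading < 0).any():
        raise ValueError("loading matrix must be nonnegative")

    ko = rel @ loading
    if config.ko_noise_sd > 0:
        ko = ko * np.exp(rng.normal(0.0, config.ko_noise_sd, size=ko.shape))

    planted = rng.choice(n_k, size=config.n_planted_kos, replace=False)
    is_luad = metadata.tissue_indicator(genus_table.sample_ids)
    truth.planted_kos = []
    for m, kidx in enumerate(planted):
        direction = "up" if m % 2 == 0 else "down"
        sign = 1.0 if direction == "up" else -1.0
        ko[:, kidx] = ko[:, kidx] * np.exp(config.ko_effect * sign * is_luad)
        truth.planted_kos.append((ko_ids[kidx], direction))

    ko_table = FeatureTable(
        pd.DataFrame(ko, index=genus_table.sample_ids, columns=ko_ids), scale="score"
    )

    pathway_of = rng.integers(0, config.n_pathways, size=n_k)
    pw_ids = [f"PW{j + 1:03d}" for j in range(config.n_pathways)]
    pw = np.zeros((ko.shape[0], config.n_pathways))
    for k in range(n_k):
        pw[:, pathway_of[k]] += ko[:, k]
    keep = pw.sum(axis=0) > 0
    pathway_table = FeatureTable(
        pd.DataFrame(pw[:, keep], index=genus_table.sample_ids,
                     columns=[p for p, k in zip(pw_ids, keep) if k]),
        scale="score",
    )

    module_of = rng.integers(0, len(MODULE_NAMES), size=n_k)
    module_map = pd.DataFrame(
        {"module": [MODULE_NAMES[m] for m in module_of], "ko_id": ko_ids}
    )[["module", "ko_id"]]
    return ko_table, pathway_table, module_map


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full cohort: design, tables, tree, functions, truth."""
    config.validate()
    metadata = simulate_cohort_design(config)
    genus, asv, taxonomy, truth = simulate_genus_asv_tables(config, metadata)
    tree_newick = simulate_tree(asv.feature_ids, seed=config.seed)
    ko, pathway, module_map = simulate_function_tables(config, genus, metadata, truth)
    return SyntheticBundle(
        config=config, metadata=metadata, genus_table=genus, asv_table=asv,
        taxonomy=taxonomy, tree_newick=tree_newick, ko_table=ko,
        pathway_table=pathway, module_map=module_map, ground_truth=truth,
    )


def emit_fixture_bundle(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the whole bundle to ``out_dir``; same config => identical bytes."""
    bundle = simulate_bundle(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genus_table": out / "genus_table.tsv",
        "asv_table": out / "asv_table.tsv",
        "ko_table": out / "ko_table.tsv",
        "pathway_table": out / "pathway_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "tree": out / "tree.nwk",
        "module_map": out / "module_map.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.json",
    }
    write_feature_table(bundle.genus_table, paths["genus_table"])
    write_feature_table(bundle.asv_table, paths["asv_table"])
    write_feature_table(bundle.ko_table, paths["ko_table"])
    write_feature_table(bundle.pathway_table, paths["pathway_table"])
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    write_metadata(bundle.metadata, paths["metadata"])
    paths["tree"].write_text(bundle.tree_newick + "\n")
    bundle.module_map.to_csv(paths["module_map"], sep="\t", index=False)
    gt = bundle.ground_truth
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "planted_diff_genera": gt.planted_diff_genera,
                "rare_expansion_taxa": gt.rare_expansion_taxa,
                "planted_kos": gt.planted_kos,
                "patient_effects": gt.patient_effects,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    cfg = asdict(config)
    cfg["asv_per_genus_range"] = list(cfg["asv_per_genus_range"])
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return paths
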