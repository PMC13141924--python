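"""End-to-end orchestration of the analysis stages on a fixture bundle.

Stages run in a fixed order (filters -> diversity -> diffab -> markers ->
network -> functions), each reading only declared input files and writing
its own TSVs, so runs are re-entrant and stages are individually skippable.
A single global seed deterministically derives per-stage seeds, so skipping
one stage never changes another stage's stream.  All deterministic outputs
(result TSVs and report.json) are byte-identical across runs with the same
config; wall-clock timings go to a separate run_log.txt, the one
intentionally non-deterministic artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffab as diffab_mod
from . import diversity as div_mod
from . import functions as fn_mod
from . import markers as mk_mod
from . import network as net_mod
from . import tables as tio
from .diffab import ENGINE_NOTE

logger = logging.getLogger(__name__)

STAGES = ("filters", "diversity", "diffab", "markers", "network", "functions")

DEVIATIONS = [
    f"differential abundance engine: {ENGINE_NOTE}",
    "AUC confidence intervals: DeLong analytic method",
    "binary-Hamming denominator: all table features",
    "weighted UniFrac: normalized variant",
    "network node filters: prevalence >= 0.2 within group (values not externally fixed)",
    "module scores: unweighted mean of CLR abundances",
]

_KNOWN_KEYS = {
    "inputs", "out_dir", "seed", "skip",
    "filters", "diversity", "diffab", "markers", "network", "functions",
}


@dataclass
class RunConfig:
    inputs: dict[str, str]
    out_dir: str
    seed: int = 0
    skip: list[str] = field(default_factory=list)
    filters: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    diffab: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    functions: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def for_bundle(cls, bundle_dir, out_dir, seed: int = 0, **stage_params) -> "RunConfig":
        b = Path(bundle_dir)
        inputs = {
            "asv_table": str(b / "asv_table.tsv"),
            "taxonomy": str(b / "taxonomy.tsv"),
            "metadata": str(b / "metadata.tsv"),
            "tree": str(b / "tree.nwk"),
            "ko_table": str(b / "ko_table.tsv"),
            "pathway_table": str(b / "pathway_table.tsv"),
            "module_map": str(b / "module_map.tsv"),
        }
        return cls(inputs=inputs, out_dir=str(out_dir), seed=seed, **stage_params)

    def effective(self) -> dict:
        """Default-resolved config echo, written to the run report."""
        return {
            "inputs": self.inputs,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "skip": list(self.skip),
            "filters": {"min_samples": 2, "min_total_reads": 10, **self.filters},
            "diversity": {"depth": None, "n_permutations": 999, **self.diversity},
            "diffab": {"min_prevalence": 0.15, "pseudocount": 1.0, **self.diffab},
            "markers": {"n_bootstrap": 500, "threshold": 0.60, **self.markers},
            "network": {"rho_min": 0.7, "p_max": 0.05, "n_bootstrap": 500,
                        "top_k": 10, "stability_min": 0.6, **self.network},
            "functions": {"pseudocount": None, **self.functions},
        }


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed, independent of which stages run."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the run report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eff = config.effective()
    timings: dict[str, float] = {}
    report: dict = {"config": eff, "deviations": DEVIATIONS, "stages_run": []}

    asv = tio.read_feature_table(config.inputs["asv_table"], scale="counts")
    taxonomy = tio.read_taxonomy(config.inputs["taxonomy"])
    metadata = tio.read_metadata(config.inputs["metadata"])
    metadata.check_covers(asv)

    def active(stage: str) -> bool:
        return stage not in config.skip

    # -- filters ------------------------------------------------------------
    t0 = time.perf_counter()
    fcfg = eff["filters"]
    filtered = tio.basic_asv_filter(
        asv, min_samples=fcfg["min_samples"], min_total_reads=fcfg["min_total_reads"]
    )
    filtered = tio.organelle_filter(filtered, taxonomy)
    genus = tio.aggregate_to_genus(filtered, taxonomy)
    if active("filters"):
        tio.write_feature_table(filtered, out / "filtered_asv_table.tsv")
        tio.write_feature_table(genus, out / "genus_table.tsv")
        report["stages_run"].append("filters")
    timings["filters"] = time.perf_counter() - t0

    # -- diversity ----------------------------------------------------------
    if active("diversity"):
        t0 = time.perf_counter()
        dcfg = eff["diversity"]
        seed = stage_seed(config.seed, "diversity")
        rare_genus = div_mod.rarefy(genus, depth=dcfg["depth"], seed=seed)
        alpha = div_mod.alpha_table(rare_genus)
        alpha.index.name = "sample_id"
        alpha.reset_index().to_csv(out / "alpha_genus.tsv", sep="\t", index=False,
                                   float_format="%.10g")
        atest = div_mod.alpha_group_test(alpha, metadata)
        atest.to_csv(out / "alpha_genus_tests.tsv", sep="\t", index=False,
                     float_format="%.10g")
        tree = tio.read_tree(config.inputs["tree"])
        rare_asv = div_mod.rarefy(filtered, depth=dcfg["depth"], seed=seed + 1)
        perm_rows = []
        for metric, tbl, tr in (
            ("bray_curtis", rare_genus, None),
            ("binary_hamming", rare_genus, None),
            ("unweighted_unifrac", rare_asv, tree),
            ("weighted_unifrac", rare_asv, tree),
        ):
            d = div_mod.beta_distance(tbl, metric, tree=tr)
            coords, eigvals, explained = div_mod.pcoa(d)
            coords.index.name = "sample_id"
            coords.iloc[:, :2].reset_index().to_csv(
                out / f"pcoa_{metric}.tsv", sep="\t", index=False, float_format="%.10g"
            )
            res = div_mod.permanova(
                d, metadata.tissue_indicator(d.ids),
                n_permutations=dcfg["n_permutations"], seed=seed + 2,
            )
            perm_rows.append(dict(metric=metric, r_squared=res.r_squared,
                                  pseudo_f=res.pseudo_f, p=res.p_value,
                                  n_permutations=res.n_permutations))
        pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t", index=False,
                                       float_format="%.10g")
        report["stages_run"].append("diversity")
        timings["diversity"] = time.perf_counter() - t0

    # -- differential abundance ---------------------------------------------
    prev_genus = diffab_mod.prevalence_filter(
        genus, min_prevalence=eff["diffab"]["min_prevalence"]
    )
    if active("diffab"):
        t0 = time.perf_counter()
        res = diffab_mod.differential_abundance(
            prev_genus, metadata, pseudocount=eff["diffab"]["pseudocount"]
        )
        res.to_csv(out / "differential_abundance.tsv", sep="\t", index=False,
                   float_format="%.10g")
        report["stages_run"].append("diffab")
        timings["diffab"] = time.perf_counter() - t0

    # -- marker stability selection ------------------------------------------
    if active("markers"):
        t0 = time.perf_counter()
        mcfg = eff["markers"]
        params = mk_mod.StabilityParams(
            n_bootstrap=mcfg["n_bootstrap"], threshold=mcfg["threshold"],
            seed=stage_seed(config.seed, "markers"),
            **{k: v for k, v in mcfg.items()
               if k in ("alpha_mixing", "cv_folds", "pseudocount", "oob_aggregate")},
        )
        sel = mk_mod.stability_select(prev_genus, metadata, params)
        sel.selection_frequency.rename_axis("genus").reset_index().to_csv(
            out / "selection_frequencies.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(
            {"sample_id": sel.oob_scores.index, "oob_score": sel.oob_scores.values,
             "oob_count": sel.oob_counts.values, "luad": sel.labels.values}
        ).to_csv(out / "oob_scores.tsv", sep="\t", index=False, float_format="%.10g")
        roc_rows = [dict(kind="oob", auc=sel.oob_roc.auc, ci_low=sel.oob_roc.ci_low,
                         ci_high=sel.oob_roc.ci_high)]
        if sel.apparent_roc is not None:
            roc_rows.append(dict(kind="apparent", auc=sel.apparent_roc.auc,
                                 ci_low=sel.apparent_roc.ci_low,
                                 ci_high=sel.apparent_roc.ci_high))
        pd.DataFrame(roc_rows).to_csv(out / "roc_summary.tsv", sep="\t", index=False,
                                      float_format="%.10g")
        panel = sel.refit_coefficients
        if panel is not None:
            panel.rename_axis("genus").reset_index().to_csv(
                out / "panel_log_odds.tsv", sep="\t", index=False, float_format="%.10g"
            )
        report["stages_run"].append("markers")
        timings["markers"] = time.perf_counter() - t0

    # -- co-occurrence network ------------------------------------------------
    if active("network"):
        t0 = time.perf_counter()
        ncfg = eff["network"]
        topo_rows = []
        for group in ("LUAD", "NC"):
            net = net_mod.build_network(
                genus, metadata, group, rho_min=ncfg["rho_min"], p_max=ncfg["p_max"]
            )
            net.edges.to_csv(out / f"network_edges_{group}.tsv", sep="\t", index=False,
                             float_format="%.10g")
            net_mod.centralities(net).to_csv(
                out / f"network_centrality_{group}.tsv", sep="\t", index=False,
                float_format="%.10g"
            )
            topo = net_mod.topology_metrics(net)
            topo_rows.append(dict(group=group, **topo))
            stable, stability = net_mod.bootstrap_stable_nodes(
                genus, metadata, group,
                net_mod.BootstrapStabilityParams(
                    n_bootstrap=ncfg["n_bootstrap"], top_k=ncfg["top_k"],
                    stability_min=ncfg["stability_min"],
                    seed=stage_seed(config.seed, "network"),
                ),
                rho_min=ncfg["rho_min"], p_max=ncfg["p_max"],
            )
            stability.rename_axis("genus").reset_index().assign(
                stable=lambda df: df["genus"].isin(stable)
            ).to_csv(out / f"network_stability_{group}.tsv", sep="\t", index=False,
                     float_format="%.10g")
        pd.DataFrame(topo_rows).to_csv(out / "network_topology.tsv", sep="\t",
                                       index=False, float_format="%.10g")
        report["stages_run"].append("network")
        timings["network"] = time.perf_counter() - t0

    # -- KO / module functions -------------------------------------------------
    if active("functions"):
        t0 = time.perf_counter()
        ko = tio.read_feature_table(config.inputs["ko_table"], scale="score")
        pathway = tio.read_feature_table(config.inputs["pathway_table"], scale="score")
        module_map = tio.read_module_map(config.inputs["module_map"])
        pc = eff["functions"]["pseudocount"]
        records = fn_mod.ko_lopo_screen(ko, metadata, module_map, pseudocount=pc)
        records = fn_mod.retain_and_partition(records)
        records.to_csv(out / "ko_lopo.tsv", sep="\t", index=False, float_format="%.10g")
        ko_clr = fn_mod.normalize_and_clr(ko, pseudocount=pc)
        scores = fn_mod.module_scores(ko_clr, records)
        tests = fn_mod.module_score_test(scores, metadata)
        tests.to_csv(out / "module_tests.tsv", sep="\t", index=False,
                     float_format="%.10g")
        pres = fn_mod.pathway_level_test(pathway, metadata, pseudocount=pc)
        pres.to_csv(out / "pathway_tests.tsv", sep="\t", index=False,
                    float_format="%.10g")
        report["stages_run"].append("functions")
        timings["functions"] = time.perf_counter() - t0

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "run_log.txt").write_text(
        "".join(f"{k}\t{v:.3f}s\n" for k, v in timings.items())
    )
    return report
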