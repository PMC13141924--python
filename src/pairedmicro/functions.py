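"""KO-level functional screening with leave-one-patient-out (LOPO) stability.

Each KO's tissue effect is estimated by the random-intercept LMM on
normalized, CLR-transformed abundances; robustness is probed by refitting
with each patient held out in turn.  A KO is retained when prevalence
>= 0.20, |median LOPO effect| >= 0.30 and sign consistency >= 0.90 (all
inclusive), then partitioned by the sign of the median LOPO effect into
LUAD-upregulated and LUAD-downregulated subsets.  Direction-specific module
scores (mean CLR over a subset's KOs) are tested with the same LMM, with BH
correction applied within each direction separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, clr_transform, default_pseudocount, fit_random_intercept_lmm
from .tables import CohortMetadata, FeatureTable, TableValidationError

logger = logging.getLogger(__name__)


@dataclass
class RetentionThresholds:
    prevalence: float = 0.20
    beta_min: float = 0.30
    consistency_min: float = 0.90


def normalize_and_clr(table: FeatureTable, pseudocount: float | None = None) -> FeatureTable:
    """Per-sample relative abundance, then CLR with a small pseudocount
    (default: half the smallest nonzero relative abundance).

    Accepts counts or nonnegative float abundances (e.g. inferred KO tables).
    """
    if table.scale == "clr":
        raise TableValidationError("table is already CLR-scale")
    arr = table.data.to_numpy(dtype=float)
    if (arr < 0).any():
        raise TableValidationError("abundances must be nonnegative")
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        bad = table.data.index[totals <= 0][0]
        raise TableValidationError(f"sample {bad!r} has zero total")
    rel = FeatureTable(
        pd.DataFrame(arr / totals[:, None], index=table.data.index,
                     columns=table.data.columns),
        scale="relative",
    )
    if pseudocount is None:
        pseudocount = default_pseudocount(rel)
    return clr_transform(rel, pseudocount=pseudocount)


def ko_lopo_screen(
    ko_table: FeatureTable,
    metadata: CohortMetadata,
    module_map: pd.DataFrame,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Full-data and leave-one-patient-out LMM effects per KO.

    Returns one row per KO: module, beta_full, beta_median, sign_consistency,
    prevalence, n_lopo_failures.  Sign consistency is the fraction of LOPO
    effects sharing the sign of the median (0 when the median is exactly 0).
    """
    ko_to_module = dict(zip(module_map["ko_id"], module_map["module"]))
    missing = set(ko_table.feature_ids) - set(ko_to_module)
    if missing:
        raise TableValidationError(f"KOs absent from module map: {sorted(missing)[:5]}")
    prevalence = ko_table.prevalence()
    clr = normalize_and_clr(ko_table, pseudocount=pseudocount)
    metadata.check_covers(clr)
    sample_ids = clr.sample_ids
    patients = metadata.patients_of(sample_ids)
    uniq_patients = np.unique(patients)

    lopo_masks = []
    for pid in uniq_patients:
        mask = patients != pid
        sub = [s for s, keep in zip(sample_ids, mask) if keep]
        lopo_masks.append((pid, mask, sub))

    rows = []
    for ko in clr.feature_ids:
        y = clr.data[ko].to_numpy()
        full = fit_random_intercept_lmm(y, metadata, sample_ids=sample_ids)
        betas = []
        failures = 0
        for _, mask, sub in lopo_masks:
            try:
                fit = fit_random_intercept_lmm(y[mask], metadata, sample_ids=sub)
                betas.append(fit.beta)
            except ValueError:
                failures += 1
        betas = np.asarray(betas)
        beta_median = float(np.median(betas)) if len(betas) else float("nan")
        if len(betas) == 0 or beta_median == 0.0:
            consistency = 0.0
        else:
            consistency = float(np.mean(np.sign(betas) == np.sign(beta_median)))
        rows.append(
            dict(ko_id=ko, module=ko_to_module[ko], beta_full=full.beta,
                 beta_median=beta_median, sign_consistency=consistency,
                 prevalence=float(prevalence[ko]), p_full=full.p_value,
                 n_lopo=len(betas), n_lopo_failures=failures)
        )
    if any(r["n_lopo_failures"] for r in rows):
        logger.warning("ko_lopo_screen: some LOPO refits failed (reported per KO)")
    return pd.DataFrame(rows)


def retain_and_partition(
    records: pd.DataFrame, thresholds: RetentionThresholds | None = None
) -> pd.DataFrame:
    """Apply the conjunctive, boundary-inclusive retention rule and assign
    direction (up/down) by the sign of the median LOPO effect."""
    thr = thresholds or RetentionThresholds()
    out = records.copy()
    out["retained"] = (
        (out["prevalence"] >= thr.prevalence)
        & (out["beta_median"].abs() >= thr.beta_min)
        & (out["sign_consistency"] >= thr.consistency_min)
    )
    out["direction"] = np.where(
        out["retained"], np.where(out["beta_median"] > 0, "up", "down"), ""
    )
    return out


def module_scores(
    ko_clr: FeatureTable, records: pd.DataFrame
) -> dict[tuple[str, str], pd.Series]:
    """Per-sample score for each (module, direction): unweighted mean CLR
    abundance over that subset's retained KOs.  Empty subsets are skipped."""
    scores: dict[tuple[str, str], pd.Series] = {}
    retained = records.loc[records["retained"]]
    for (module, direction), grp in retained.groupby(["module", "direction"]):
        kos = [k for k in grp["ko_id"] if k in ko_clr.data.columns]
        if not kos:
            logger.info("module_scores: (%s, %s) has no scored KOs, skipped",
                        module, direction)
            continue
        scores[(module, direction)] = ko_clr.data[kos].mean(axis=1)
    return scores


def module_score_test(
    scores: dict[tuple[str, str], pd.Series], metadata: CohortMetadata
) -> pd.DataFrame:
    """LMM per (module, direction); BH within each direction separately."""
    rows = []
    for (module, direction), s in scores.items():
        res = fit_random_intercept_lmm(
            s.to_numpy(), metadata, sample_ids=list(s.index)
        )
        rows.append(dict(module=module, direction=direction, beta=res.beta,
                         se=res.se, p=res.p_value, converged=res.converged))
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    out["fdr"] = np.nan
    for direction in out["direction"].unique():
        mask = out["direction"] == direction
        out.loc[mask, "fdr"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["fdr"] < 0.05
    return out.sort_values(["direction", "fdr"], kind="stable").reset_index(drop=True)


def pathway_level_test(
    pathway_table: FeatureTable,
    metadata: CohortMetadata,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """CLR + per-pathway LMM screen with BH across pathways."""
    from .stats import lmm_screen

    clr = normalize_and_clr(pathway_table, pseudocount=pseudocount)
    out = lmm_screen(clr, metadata).rename(columns={"feature_id": "pathway"})
    out["significant"] = out["q"] < 0.05
    return out
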