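"""Patient-level cluster-bootstrap stability selection of genus markers.

Each bootstrap iteration resamples whole patients with replacement, so
paired samples always travel together and out-of-bag (OOB) predictions are
leakage-free.  Within an iteration, features are CLR-transformed (the CLR
is a per-sample operation, so it is computed once up front) and Z-score
standardized using training-set statistics only, then an elastic-net
logistic model is fitted with its penalty strength chosen by patient-grouped
cross-validation on the training patients.  A feature is "selected" when its
coefficient is nonzero; selection frequencies over iterations define the
marker panel (frequency > threshold), and per-sample OOB scores are the mean
predicted probability over iterations in which the sample's patient was out
of bag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .stats import RocResult, clr_transform, roc_auc_ci
from .tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class StabilityParams:
    pseudocount: float = 1.0
    alpha_mixing: float = 0.5          # elastic-net l1_ratio
    n_bootstrap: int = 500
    threshold: float = 0.60            # selection-frequency cutoff for the panel
    c_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-2, 2, 20)
    )                                  # inverse penalty strengths searched per iteration
    cv_folds: int = 3
    oob_aggregate: str = "mean"        # or "median"
    seed: int = 0
    max_redraws: int = 50


@dataclass
class StabilitySelectionResult:
    selection_frequency: pd.Series
    panel: list[str]
    threshold: float
    n_bootstrap: int
    oob_scores: pd.Series              # per-sample aggregated OOB probability
    oob_counts: pd.Series              # times each sample was out of bag
    labels: pd.Series                  # 1 = LUAD
    coefficients: pd.DataFrame         # iterations x features
    apparent_roc: RocResult | None = None
    oob_roc: RocResult | None = None
    refit_coefficients: pd.Series | None = None
    n_redraws: int = 0


def cluster_bootstrap(patients, n_bootstrap: int, seed: int = 0) -> list[np.ndarray]:
    """Draw ``n_bootstrap`` patient-level resamples (with replacement, original size)."""
    patients = np.asarray(patients)
    if len(patients) < 5:
        raise ValueError("need at least 5 patients for the cluster bootstrap")
    rng = np.random.default_rng(seed)
    return [rng.choice(patients, size=len(patients), replace=True) for _ in range(n_bootstrap)]


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    """Z-score with training statistics; zero-variance features map to 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    zt = np.where(sd > 0, (train - mu) / safe, 0.0)
    zo = None if other is None else np.where(sd > 0, (other - mu) / safe, 0.0)
    return zt, zo


def _fit_enet(X, y, C: float, l1_ratio: float) -> LogisticRegression:
    model = LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, C=C, max_iter=5000, tol=1e-4,
        random_state=0,
    )
    model.fit(X, y)
    return model


def _grouped_cv_auc(X, y, groups, C, l1_ratio, n_folds, rng) -> tuple[float, float]:
    """Mean validation AUC (and its standard error) of an elastic-net fit
    over patient-grouped folds."""
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    folds = np.array_split(perm, n_folds)
    aucs = []
    for fold in folds:
        val = np.isin(groups, fold)
        if val.all() or (~val).all():
            continue
        ytr, yva = y[~val], y[val]
        if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
            continue
        ztr, zva = _standardize(X[~val], X[val])
        model = _fit_enet(ztr, ytr, C, l1_ratio)
        scores = model.predict_proba(zva)[:, 1]
        aucs.append(roc_auc_ci(yva, scores).auc)
    if not aucs:
        return float("nan"), float("nan")
    se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
    return float(np.mean(aucs)), se


def stability_select(
    table: FeatureTable,
    metadata: CohortMetadata,
    params: StabilityParams | None = None,
) -> StabilitySelectionResult:
    """Run the full cluster-bootstrap elastic-net stability selection."""
    params = params or StabilityParams()
    metadata.check_covers(table)
    clr = clr_transform(table, pseudocount=params.pseudocount)
    X_all = clr.data.to_numpy()
    sample_ids = clr.sample_ids
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    y_all = metadata.tissue_indicator(sample_ids)
    if len(np.unique(y_all)) < 2:
        raise ValueError("both tissue classes must be present")
    patients_of_sample = metadata.patients_of(sample_ids)
    patients = np.unique(patients_of_sample)

    rng = np.random.default_rng(params.seed)
    n_feat = table.n_features
    sel_counts = np.zeros(n_feat)
    coef_rows = []
    oob_sum = np.zeros(len(sample_ids))
    oob_n = np.zeros(len(sample_ids), dtype=int)
    oob_lists: list[list[float]] | None = None
    if params.oob_aggregate == "median":
        oob_lists = [[] for _ in sample_ids]
    n_redraws = 0

    it = 0
    while it < params.n_bootstrap:
        bag = rng.choice(patients, size=len(patients), replace=True)
        bag_set = set(bag)
        train_samples = metadata.samples_of_patients(bag)
        tr_idx = np.array([sample_pos[s] for s in train_samples])
        ytr = y_all[tr_idx]
        if len(np.unique(ytr)) < 2:
            n_redraws += 1
            if n_redraws > params.max_redraws * params.n_bootstrap:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        it += 1
        Xtr = X_all[tr_idx]
        gtr = patients_of_sample[tr_idx]
        # penalty by patient-grouped CV: one-SE rule, i.e. the strongest
        # penalty (smallest C) whose mean AUC is within one standard error
        # of the best, favouring sparse, stable selections
        cv_rng = np.random.default_rng(rng.integers(2**31))
        grid = np.sort(np.asarray(params.c_grid, dtype=float))
        means, ses = np.full(len(grid), np.nan), np.full(len(grid), np.nan)
        for ci, C in enumerate(grid):
            means[ci], ses[ci] = _grouped_cv_auc(
                Xtr, ytr, gtr, C, params.alpha_mixing, params.cv_folds, cv_rng
            )
        if np.isnan(means).all():
            best_c = grid[0]
        else:
            best_i = int(np.nanargmax(means))
            cutoff = means[best_i] - ses[best_i]
            ok = np.flatnonzero(np.nan_to_num(means, nan=-np.inf) >= cutoff)
            best_c = grid[ok[0]]
        ztr, _ = _standardize(Xtr)
        model = _fit_enet(ztr, ytr, best_c, params.alpha_mixing)
        coefs = model.coef_.ravel()
        sel_counts += (np.abs(coefs) > 1e-10)
        coef_rows.append(coefs)
        # OOB predictions: all samples of undrawn patients
        oob_mask = ~np.isin(patients_of_sample, list(bag_set))
        if oob_mask.any():
            _, zoob = _standardize(Xtr, X_all[oob_mask])
            probs = model.predict_proba(zoob)[:, 1]
            oob_sum[oob_mask] += probs
            oob_n[oob_mask] += 1
            if oob_lists is not None:
                for pos, pr in zip(np.flatnonzero(oob_mask), probs):
                    oob_lists[pos].append(pr)

    if n_redraws:
        logger.info("stability_select: redrew %d degenerate resamples", n_redraws)
    freq = pd.Series(sel_counts / params.n_bootstrap, index=table.feature_ids,
                     name="selection_frequency")
    panel = list(freq.index[freq > params.threshold])
    if oob_lists is not None:
        oob_scores = np.array(
            [np.median(v) if v else np.nan for v in oob_lists], dtype=float
        )
    else:
        with np.errstate(invalid="ignore"):
            oob_scores = np.where(oob_n > 0, oob_sum / np.maximum(oob_n, 1), np.nan)
    result = StabilitySelectionResult(
        selection_frequency=freq,
        panel=panel,
        threshold=params.threshold,
        n_bootstrap=params.n_bootstrap,
        oob_scores=pd.Series(oob_scores, index=sample_ids, name="oob_score"),
        oob_counts=pd.Series(oob_n, index=sample_ids, name="oob_count"),
        labels=pd.Series(y_all.astype(int), index=sample_ids, name="luad"),
        coefficients=pd.DataFrame(coef_rows, columns=table.feature_ids),
        n_redraws=n_redraws,
    )
    result.oob_roc = oob_roc(result)
    if panel:
        coefs, roc = refit_panel(table, metadata, panel, pseudocount=params.pseudocount)
        result.refit_coefficients = coefs
        result.apparent_roc = roc
    return result


def oob_roc(result: StabilitySelectionResult) -> RocResult:
    """ROC on aggregated out-of-bag scores; never-OOB samples are excluded."""
    scored = result.oob_scores.notna()
    n_excluded = int((~scored).sum())
    if n_excluded:
        logger.info("oob_roc: %d samples never out-of-bag, excluded", n_excluded)
    labels = result.labels[scored].to_numpy()
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValueError("need >= 2 scored samples per class for the OOB ROC")
    return roc_auc_ci(labels, result.oob_scores[scored].to_numpy())


def refit_panel(
    table: FeatureTable,
    metadata: CohortMetadata,
    panel: list[str],
    pseudocount: float = 1.0,
    ridge_c: float = 100.0,
) -> tuple[pd.Series, RocResult]:
    """Single multivariable logistic refit of the panel over all samples.

    A light ridge penalty (large C) guarantees a finite fit under complete
    separation; coefficients are log-odds per standardized CLR unit.
    """
    if not panel:
        raise ValueError("panel is empty")
    missing = set(panel) - set(table.feature_ids)
    if missing:
        raise ValueError(f"panel features absent from table: {sorted(missing)}")
    # CLR on the full composition first; the panel is a view of it
    clr = clr_transform(table, pseudocount=pseudocount).subset_features(panel)
    X = clr.data.to_numpy()
    y = metadata.tissue_indicator(clr.sample_ids)
    z, _ = _standardize(X)
    model = LogisticRegression(C=ridge_c, max_iter=5000)
    model.fit(z, y)
    scores = model.predict_proba(z)[:, 1]
    coefs = pd.Series(model.coef_.ravel(), index=panel, name="log_odds")
    return coefs, roc_auc_ci(y.astype(int), scores)
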