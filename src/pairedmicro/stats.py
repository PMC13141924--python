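"""Shared statistical primitives.

CLR transform, Gaussian random-intercept mixed model for the partially
paired tissue design, Benjamini-Hochberg adjustment, Spearman association
and ROC/AUC with a DeLong confidence interval.  LMM inference is a Wald
t test with residual degrees of freedom (n - 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .tables import CohortMetadata, FeatureTable, TableValidationError

__all__ = [
    "LmmResult",
    "RocResult",
    "clr_transform",
    "default_pseudocount",
    "fit_random_intercept_lmm",
    "lmm_screen",
    "bh_adjust",
    "spearman_assoc",
    "roc_auc_ci",
]


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def default_pseudocount(table: FeatureTable) -> float:
    """Half the smallest nonzero entry of the table (the 'small pseudocount'
    used for KO/pathway abundances, where unit counts have no meaning)."""
    arr = table.data.to_numpy(dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise TableValidationError("table is all zeros; no pseudocount can be derived")
    return float(nonzero.min()) / 2.0


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> FeatureTable:
    """Centered log-ratio transform: ln(x + pc) minus its per-sample mean.

    Each output row sums to zero; the transform is invariant to per-sample
    rescaling of the input.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if table.scale in ("clr", "score"):
        raise TableValidationError(f"cannot CLR-transform a {table.scale}-scale table")
    logx = np.log(table.data.to_numpy(dtype=float) + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return FeatureTable(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns), scale="clr"
    )


# ---------------------------------------------------------------------------
# Random-intercept LMM
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    """Tissue fixed effect (LUAD vs NC) from a patient random-intercept model."""

    beta: float
    se: float
    p_value: float
    n_samples: int
    n_patients: int
    converged: bool
    boundary: bool = False  # random-effect variance estimated at 0 (OLS equivalent)
    fdr: float = np.nan
    feature_id: str = ""


def _ols_fallback(y: np.ndarray, x: np.ndarray, n_patients: int, converged: bool) -> LmmResult:
    X = np.column_stack([np.ones_like(x), x])
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    dof = max(len(y) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    beta = float(beta_hat[1])
    if se == 0.0:
        p = 1.0 if abs(beta) < 1e-12 else 0.0
    else:
        p = float(2.0 * sps.t.sf(abs(beta / se), df=dof))
    return LmmResult(
        beta=beta, se=se, p_value=p, n_samples=len(y), n_patients=n_patients,
        converged=converged, boundary=True,
    )


def fit_random_intercept_lmm(
    y, metadata: CohortMetadata, sample_ids=None
) -> LmmResult:
    """Fit ``y = b0 + b*1[LUAD] + u_patient + e`` by REML; Wald t test on b.

    If the random-intercept variance hits the zero boundary the model
    degenerates to OLS; the result is then recomputed by OLS and flagged.
    Non-convergence falls back to OLS with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    if sample_ids is None:
        sample_ids = metadata.sample_ids
    if len(y) != len(sample_ids):
        raise ValueError("response length does not match sample ids")
    x = metadata.tissue_indicator(sample_ids)
    groups = metadata.patients_of(sample_ids)
    n_patients = len(np.unique(groups))
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if len(np.unique(x)) < 2:
        raise ValueError("both tissue levels must be present")
    if np.ptp(y) < 1e-12:
        return LmmResult(0.0, 0.0, 1.0, len(y), n_patients, True, boundary=True)

    X = np.column_stack([np.ones_like(x), x])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):  # powell is slower but far more robust
            try:
                cand = MixedLM(y, X, groups=groups).fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged:
                fit = cand
                break
    if fit is None:
        return _ols_fallback(y, x, n_patients, converged=False)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    resid_var = float(fit.scale)
    if re_var <= 1e-8 * max(resid_var, 1e-12):
        return _ols_fallback(y, x, n_patients, converged=True)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    # Wald t with residual df (n - 2): a light small-sample correction over
    # the asymptotic z reference
    dof = max(len(y) - 2, 1)
    p = float(2.0 * sps.t.sf(abs(beta / se), df=dof)) if se > 0 else 1.0
    return LmmResult(beta, se, p, len(y), n_patients, True)


def lmm_screen(table: FeatureTable, metadata: CohortMetadata) -> pd.DataFrame:
    """One random-intercept LMM per feature; BH across features.

    Returns a DataFrame (feature_id, beta, se, p, q, n_samples, n_patients,
    converged, boundary) sorted by (q, p).  Failed fits are reported with
    NaN statistics, never silently dropped.
    """
    metadata.check_covers(table)
    rows = []
    for fid in table.feature_ids:
        try:
            res = fit_random_intercept_lmm(
                table.data[fid].to_numpy(), metadata, sample_ids=table.sample_ids
            )
            rows.append(
                dict(feature_id=fid, beta=res.beta, se=res.se, p=res.p_value,
                     n_samples=res.n_samples, n_patients=res.n_patients,
                     converged=res.converged, boundary=res.boundary)
            )
        except ValueError as exc:
            rows.append(
                dict(feature_id=fid, beta=np.nan, se=np.nan, p=np.nan,
                     n_samples=table.n_samples, n_patients=0,
                     converged=False, boundary=False, error=str(exc))
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out.sort_values(["q", "p"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Multiplicity, association, ROC
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; two-sided t-approx p.

    A constant vector makes the correlation undefined: returns (nan, nan)
    with a warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    labels: np.ndarray = field(default_factory=lambda: np.array([]))
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    n_positive: int = 0
    n_negative: int = 0


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via the midrank formulation."""
    m, n = len(pos_scores), len(neg_scores)
    allx = np.concatenate([pos_scores, neg_scores])
    tx = _midrank(allx)
    tpos = _midrank(pos_scores)
    tneg = _midrank(neg_scores)
    auc = (tx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tx[:m] - tpos) / n  # structural components over positives
    v01 = 1.0 - (tx[m:] - tneg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc_ci(labels, scores, alpha: float = 0.05) -> RocResult:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong 95% CI, clipped to [0,1]."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    pos, neg = scores[labels == 1], scores[labels == 0]
    auc, var = _delong_variance(pos, neg)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        labels=labels,
        scores=scores,
        n_positive=int((labels == 1).sum()),
        n_negative=int((labels == 0).sum()),
    )
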