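"""Alpha and beta diversity for the paired tissue design.

Alpha: observed richness, bias-corrected Chao1, ACE (rare cutoff 10),
Shannon (natural log) and the unbiased Simpson dominance, computed on a
rarefied table and tested per index with the patient random-intercept LMM.

Beta: Bray-Curtis, binary-Hamming (presence/absence mismatch fraction over
all table features), and unweighted / normalized weighted UniFrac through
scikit-bio; PCoA by Gower double-centering (negative eigenvalues reported,
not corrected); PERMANOVA with Anderson's pseudo-F and unrestricted label
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, fit_random_intercept_lmm
from .tables import CohortMetadata, FeatureTable, TableValidationError, check_tree_covers

ALPHA_INDICES = ("sobs", "chao1", "ace", "shannon", "simpson")
BETA_METRICS = ("bray_curtis", "binary_hamming", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    ``depth=None`` uses the minimum per-sample total (the study convention of
    rarefying to the minimum sequencing depth).
    """
    if table.scale != "counts":
        raise TableValidationError("rarefy requires a counts-scale table")
    totals = table.data.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    short = totals.index[totals < depth]
    if len(short):
        raise ValueError(f"sample {short[0]!r} has fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.data.to_numpy(dtype=np.int64))
    for i, (_, row) in enumerate(table.data.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(dtype=np.int64), depth)
    return FeatureTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns), scale="counts"
    )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray) -> float:
    s = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    present = counts[counts > 0]
    rare = present[present <= rare_cutoff]
    abund = present[present > rare_cutoff]
    s_rare, s_abund = len(rare), len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == 0:
        return float(s_abund)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare reads are singletons: coverage undefined, use Chao1 instead
        return _chao1(counts)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma = max(
        (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1)) - 1.0, 0.0
    ) if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma


def alpha_indices(sample_counts) -> dict[str, float]:
    """Alpha-diversity indices for one sample's count vector."""
    counts = np.asarray(sample_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("sample has zero total count")
    p = counts[counts > 0] / n
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((counts * (counts - 1.0)).sum() / (n * (n - 1.0))) if n > 1 else 1.0
    return {
        "sobs": int((counts > 0).sum()),
        "chao1": float(_chao1(counts)),
        "ace": float(_ace(counts)),
        "shannon": shannon,
        "simpson": simpson,
    }


def alpha_table(table: FeatureTable) -> pd.DataFrame:
    """Per-sample alpha indices (rows = samples, columns = indices)."""
    recs = {sid: alpha_indices(row.to_numpy()) for sid, row in table.data.iterrows()}
    return pd.DataFrame.from_dict(recs, orient="index")[list(ALPHA_INDICES)]


def alpha_group_test(alpha: pd.DataFrame, metadata: CohortMetadata) -> pd.DataFrame:
    """LMM (tissue fixed, patient random) per index; BH across the indices."""
    rows = []
    for idx in alpha.columns:
        res = fit_random_intercept_lmm(
            alpha[idx].to_numpy(dtype=float), metadata, sample_ids=list(alpha.index)
        )
        rows.append(dict(index=idx, beta=res.beta, se=res.se, p=res.p_value,
                         converged=res.converged, boundary=res.boundary))
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    matrix: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m


def beta_distance(
    table: FeatureTable,
    metric: str,
    tree=None,
    hamming_denominator: str = "all",
) -> DistanceMatrix:
    """Pairwise sample distances under one of the four study metrics."""
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    ids = table.sample_ids
    if metric == "bray_curtis":
        from scipy.spatial.distance import pdist, squareform

        rel = table.to_relative().data.to_numpy()
        mat = squareform(pdist(rel, metric="braycurtis"))
    elif metric == "binary_hamming":
        pres = (table.data.to_numpy() > 0).astype(float)
        n = table.n_samples
        mat = np.zeros((n, n))
        for i in range(n):
            diff = pres != pres[i]
            if hamming_denominator == "all":
                mat[i] = diff.mean(axis=1)
            else:  # pairwise union of present features
                union = (pres > 0) | (pres[i] > 0)
                denom = union.sum(axis=1)
                with np.errstate(invalid="ignore"):
                    mat[i] = np.where(denom > 0, diff.sum(axis=1) / denom, 0.0)
        np.fill_diagonal(mat, 0.0)
    else:
        from skbio.diversity import beta_diversity

        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        check_tree_covers(tree, table.feature_ids)
        kwargs = dict(ids=ids, taxa=table.feature_ids, tree=tree)
        if metric == "weighted_unifrac":
            dm = beta_diversity("weighted_unifrac", table.data.to_numpy(), normalized=True,
                                **kwargs)
        else:
            dm = beta_diversity("unweighted_unifrac", table.data.to_numpy(), **kwargs)
        mat = np.asarray(dm.data, dtype=float)
    return DistanceMatrix(mat, ids, metric)


def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal coordinate analysis by Gower double-centering.

    Returns (coordinates on positive axes, all eigenvalues sorted descending,
    explained-variance fractions over the positive eigenvalues).  Negative
    eigenvalues are reported as-is, never corrected.
    """
    dsq = d.matrix**2
    n = dsq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ dsq @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords, index=d.ids, columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))]
    )
    explained = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return frame, eigvals, explained


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _permanova_f(dsq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = dsq.shape[0]
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = dsq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    d: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """Anderson's distance-based pseudo-F with free (unrestricted) label
    permutations; p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)."""
    labels = np.asarray(groups)
    if len(labels) != len(d.ids):
        raise ValueError("group labels must match distance matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"group {uniq[counts < 2][0]!r} has fewer than 2 samples")
    dsq = d.matrix**2
    f_obs, r2 = _permanova_f(dsq, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_f(dsq, rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(r2), float(f_obs), float(p), n_permutations)
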