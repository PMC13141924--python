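"""Feature tables, cohort metadata and taxonomy: containers, validation, I/O, filters.

Disk convention follows common amplicon practice: feature tables are stored
features x samples (first column = feature id).  In memory everything is
samples x features, which is what the statistical modules expect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("counts", "relative", "clr", "score")

#: lineage tokens that mark host-organelle reads (matched case-insensitively)
ORGANELLE_TOKENS = ("chloroplast", "mitochondria", "mitochondrial")


class TableValidationError(ValueError):
    """Raised when a table, metadata or taxonomy object violates its contract."""


@dataclass
class FeatureTable:
    """Sample x feature abundance matrix with an explicit scale flag.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples as rows, features as columns.
    scale : str
        One of ``counts``, ``relative``, ``clr``, ``score``.
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise TableValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate feature ids: {dups}")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.data.columns[
                [not np.issubdtype(t, np.number) for t in self.data.dtypes]
            ].tolist()
            raise TableValidationError(f"non-numeric columns: {bad}")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise TableValidationError(
                f"missing cell at sample {self.data.index[r]!r}, feature {self.data.columns[c]!r}"
            )
        if self.scale in ("counts", "relative") and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"negative value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.scale == "counts" and not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise TableValidationError(
                f"non-integer count at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.scale == "relative":
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[~np.isclose(sums, 1.0, atol=1e-9)][0]
                raise TableValidationError(f"relative rows must sum to 1; sample {bad!r} does not")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_relative(self) -> "FeatureTable":
        if self.scale not in ("counts", "relative"):
            raise TableValidationError(f"cannot renormalize a {self.scale}-scale table")
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise TableValidationError(f"sample {bad!r} has zero total")
        return FeatureTable(self.data.div(totals, axis=0), scale="relative")

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)].copy(), scale=self.scale)

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data[list(feature_ids)].copy(), scale=self.scale)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each feature has abundance > 0."""
        return (self.data > 0).mean(axis=0)


@dataclass
class CohortMetadata:
    """Per-sample design information: sample id, patient id, tissue label."""

    frame: pd.DataFrame

    TISSUES = ("LUAD", "NC")

    def __post_init__(self) -> None:
        req = {"sample_id", "patient_id", "tissue"}
        missing = req - set(self.frame.columns)
        if missing:
            raise TableValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise TableValidationError("duplicate sample ids in metadata")
        bad = set(self.frame["tissue"]) - set(self.TISSUES)
        if bad:
            raise TableValidationError(f"unknown tissue labels: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def patient_ids(self) -> list[str]:
        return list(pd.unique(self.frame["patient_id"]))

    def for_samples(self, sample_ids) -> "CohortMetadata":
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return CohortMetadata(sub)

    def tissue_indicator(self, sample_ids=None) -> np.ndarray:
        """1 for LUAD, 0 for NC, aligned to ``sample_ids`` (metadata order if None)."""
        frame = self.frame
        if sample_ids is not None:
            frame = frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return (frame["tissue"] == "LUAD").to_numpy(dtype=float)

    def patients_of(self, sample_ids) -> np.ndarray:
        return (
            self.frame.set_index("sample_id").loc[list(sample_ids), "patient_id"].to_numpy()
        )

    def samples_of_patients(self, patient_ids) -> list[str]:
        """All sample ids of the given patients, repeated per patient occurrence."""
        by_patient = self.frame.groupby("patient_id")["sample_id"].apply(list)
        out: list[str] = []
        for pid in patient_ids:
            out.extend(by_patient[pid])
        return out

    def check_covers(self, table: FeatureTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise TableValidationError(f"samples absent from metadata: {sorted(missing)}")


@dataclass
class TaxonomyMap:
    """feature id -> ranked lineage (domain..genus), semicolon-separated.

    ``unclassified_f__X`` / ``norank_c__Y`` genus tokens are legitimate and
    are treated as distinct genus-level units.
    """

    lineages: dict[str, str] = field(default_factory=dict)

    RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")

    def genus_of(self, feature_id: str) -> str:
        lineage = self.lineages[feature_id]
        parts = [p.strip() for p in lineage.split(";")]
        genus = parts[-1] if parts else ""
        return genus.removeprefix("g__") if genus.startswith("g__") else genus

    def check_covers(self, table: FeatureTable) -> None:
        missing = set(table.feature_ids) - set(self.lineages)
        if missing:
            raise TableValidationError(f"features without taxonomy: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, scale: str = "counts") -> FeatureTable:
    """Read a TSV feature table, auto-detecting orientation from the header.

    A header starting with ``sample_id`` is taken as samples x features;
    anything else (conventionally ``feature_id``) as features x samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if str(df.index.name).strip().lower() != "sample_id":
        df = df.T
    df.index.name = "sample_id"
    df.columns.name = None
    return FeatureTable(df, scale=scale)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write features x samples TSV (first column = feature id)."""
    out = table.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path) -> CohortMetadata:
    return CohortMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(metadata: CohortMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "lineage"} <= set(df.columns):
        raise TableValidationError("taxonomy TSV needs columns feature_id, lineage")
    return TaxonomyMap(dict(zip(df["feature_id"], df["lineage"])))


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    pd.DataFrame(
        {"feature_id": list(taxonomy.lineages), "lineage": list(taxonomy.lineages.values())}
    ).to_csv(path, sep="\t", index=False)


def read_tree(path):
    """Read a rooted Newick tree as an ``skbio.TreeNode``."""
    import skbio

    # underscores in tip ids are literal (QIIME/amplicon convention)
    return skbio.TreeNode.read(str(path), convert_underscores=False)


def check_tree_covers(tree, feature_ids) -> None:
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(feature_ids) - tips)
    if missing:
        raise TableValidationError(f"tree is missing tips: {missing[:10]}")


def read_module_map(path) -> pd.DataFrame:
    """Read a KO -> functional-module assignment; each KO exactly one module."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"module", "ko_id"} <= set(df.columns):
        raise TableValidationError("module map TSV needs columns module, ko_id")
    dup = df["ko_id"][df["ko_id"].duplicated()]
    if not dup.empty:
        raise TableValidationError(f"KOs assigned to more than one module: {sorted(set(dup))}")
    return df


def write_results(objects: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each named DataFrame as ``<name>.tsv`` with stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in objects.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def basic_asv_filter(
    table: FeatureTable, min_samples: int = 2, min_total_reads: int = 10
) -> FeatureTable:
    """Retain features detected in >= ``min_samples`` samples with a dataset-wide
    total of >= ``min_total_reads`` reads.  Presence means count > 0."""
    if table.scale != "counts":
        raise TableValidationError("basic_asv_filter requires a counts-scale table")
    n_present = (table.data > 0).sum(axis=0)
    totals = table.data.sum(axis=0)
    keep = table.data.columns[(n_present >= min_samples) & (totals >= min_total_reads)]
    logger.info("basic_asv_filter: kept %d / %d features", len(keep), table.n_features)
    return table.subset_features(keep)


def organelle_filter(table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Drop features whose lineage names a chloroplast or mitochondrial origin."""
    taxonomy.check_covers(table)
    drop = [
        f
        for f in table.feature_ids
        if any(tok in taxonomy.lineages[f].lower() for tok in ORGANELLE_TOKENS)
    ]
    logger.info("organelle_filter: removed %d features", len(drop))
    keep = [f for f in table.feature_ids if f not in set(drop)]
    return table.subset_features(keep)


def aggregate_to_genus(asv_table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Sum ASV counts into genus-level units (full-lineage genus identity)."""
    if asv_table.scale != "counts":
        raise TableValidationError("aggregate_to_genus requires a counts-scale table")
    taxonomy.check_covers(asv_table)
    genus = [taxonomy.genus_of(f) for f in asv_table.feature_ids]
    agg = asv_table.data.T.groupby(pd.Index(genus, name="genus"), sort=True).sum().T
    agg.columns.name = None
    return FeatureTable(agg, scale="counts")
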