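"""Expression matrices: loading, validation, filtering, fold changes, clustering.

The substrate of every statistic in the pipeline is a log2 feature x sample
matrix (genes or miRNAs) with a sample annotation mapping each sample to a
condition (e.g. disease vs. two control tissues) and an optional driver
mutation label.  Two feature filters mirror common pre-processing of
summarized array data: removal of weakly expressed features (lowest fraction
of the per-feature mean distribution) and of poorly variable features
(Shannon entropy of the expression profile below a threshold, in bits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "SampleAnnotation",
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotation",
    "mean_expression_filter",
    "shannon_entropy_bits",
    "entropy_filter",
    "filter_features",
    "log2_fold_change",
    "hcluster_samples",
]


@dataclass(frozen=True)
class SampleAnnotation:
    """Maps samples to condition labels and optional mutation labels."""

    condition: pd.Series  # index: sample_id -> condition string
    mutation: pd.Series | None = None  # index: sample_id -> mutation string

    def __post_init__(self) -> None:
        if self.condition.index.duplicated().any():
            dups = self.condition.index[self.condition.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in annotation: {dups}")
        if self.mutation is not None and not self.mutation.index.equals(
            self.condition.index
        ):
            raise ValueError("mutation labels must cover the same samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.condition.index)

    def conditions(self) -> list[str]:
        return sorted(self.condition.unique())

    def samples_in(self, condition: str, mutation: str | None = None) -> list[str]:
        """Sample ids with the given condition (optionally restricted by mutation)."""
        mask = self.condition == condition
        if mutation is not None:
            if self.mutation is None:
                raise ValueError("annotation carries no mutation column")
            mask &= self.mutation == mutation
        return list(self.condition.index[mask])


@dataclass
class ExpressionMatrix:
    """A log2 feature x sample matrix with sample annotation.

    ``values`` is a pandas DataFrame (rows: features, columns: samples); all
    entries must be finite.  ``feature_kind`` records whether rows are genes
    or miRNAs — downstream stages use it only for bookkeeping.
    """

    values: pd.DataFrame
    feature_kind: str  # "gene" | "mirna"
    annotation: SampleAnnotation = field(repr=False)

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "mirna"):
            raise ValueError(f"feature_kind must be 'gene' or 'mirna', got {self.feature_kind!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.shape[1] == 0:
            raise ValueError("expression matrix must have at least one sample")
        arr = self.values.to_numpy()
        if arr.size and (
            not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all()
        ):
            raise ValueError("expression matrix contains non-numeric or non-finite values")
        missing = set(self.values.columns) - set(self.annotation.condition.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return ExpressionMatrix(self.values.loc[keep], self.feature_kind, self.annotation)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in sample_ids if s in set(self.sample_ids)]
        if not keep:
            raise ValueError("sample subset is empty")
        return ExpressionMatrix(self.values[keep], self.feature_kind, self.annotation)


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Read a TSV with header sample_id<TAB>condition[<TAB>mutation]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}, got {list(df.columns)}")
    cond = pd.Series(df["condition"].values, index=df["sample_id"].values, name="condition")
    mut = None
    if "mutation" in df.columns:
        mut = pd.Series(df["mutation"].values, index=df["sample_id"].values, name="mutation")
    return SampleAnnotation(cond, mut)


def read_expression_matrix(
    matrix_path: str | Path,
    annotation_path: str | Path | SampleAnnotation,
    feature_kind: str,
) -> ExpressionMatrix:
    """Load a TSV expression matrix (first header cell ``feature_id``).

    Sample order is preserved as in the file; the matrix and annotation are
    cross-validated (every sample must be annotated).
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc
    ann = (
        annotation_path
        if isinstance(annotation_path, SampleAnnotation)
        else read_sample_annotation(annotation_path)
    )
    return ExpressionMatrix(df, feature_kind, ann)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV dialect read_expression_matrix consumes.

    Values are written with :func:`repr`-exact float formatting so that a
    write/read round trip reproduces values bit for bit.
    """
    df = mat.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def mean_expression_filter(mat: ExpressionMatrix, drop_fraction: float = 0.25) -> ExpressionMatrix:
    """Remove features whose mean expression falls strictly below the
    ``drop_fraction`` empirical quantile (linear interpolation) of per-feature
    means.  Order of surviving features is preserved."""
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    if mat.n_features == 0:
        raise ValueError("cannot filter an empty matrix")
    means = mat.values.mean(axis=1).to_numpy()
    cutoff = float(np.quantile(means, drop_fraction))  # linear-interpolation quantile
    keep = means >= cutoff
    return ExpressionMatrix(mat.values.loc[keep], mat.feature_kind, mat.annotation)


def shannon_entropy_bits(profile: np.ndarray, n_bins: int = 10) -> float:
    """Shannon entropy of an expression profile, in bits.

    The profile's own range [min, max] is split into ``n_bins`` equal-width
    bins; H = -sum p_b log2 p_b over occupied bins.  A constant profile has
    all mass in one bin and H = 0 by convention.  0 <= H <= log2(n_bins).
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("profile must have at least 2 values")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def entropy_filter(
    mat: ExpressionMatrix, threshold: float = 1.4, n_bins: int = 10
) -> ExpressionMatrix:
    """Remove poorly variable features: Shannon entropy (bits) < threshold."""
    ent = np.array([shannon_entropy_bits(row, n_bins) for row in mat.values.to_numpy()])
    keep = ent >= threshold if mat.n_features else np.zeros(0, dtype=bool)
    return ExpressionMatrix(mat.values.loc[keep], mat.feature_kind, mat.annotation)


def filter_features(
    mat: ExpressionMatrix,
    drop_fraction: float = 0.25,
    entropy_threshold: float = 1.4,
    n_bins: int = 10,
) -> ExpressionMatrix:
    """Union of the two removals ("and/or"): a feature is dropped when weakly
    expressed *or* poorly variable.  Both criteria are evaluated on the
    original matrix, which makes the composition order-insensitive."""
    means = mat.values.mean(axis=1).to_numpy()
    cutoff = float(np.quantile(means, drop_fraction))
    weak = means < cutoff
    low_ent = np.array(
        [shannon_entropy_bits(row, n_bins) < entropy_threshold for row in mat.values.to_numpy()]
    )
    keep = ~(weak | low_ent)
    return ExpressionMatrix(mat.values.loc[keep], mat.feature_kind, mat.annotation)


def log2_fold_change(
    mat: ExpressionMatrix,
    group_a: str,
    group_b: str,
    stratify_by: str | None = None,
) -> pd.Series:
    """Per-feature log2 fold change: mean(group_a) - mean(group_b).

    Data are on the log2 scale already, so the difference of group means is
    the log2 fold change.  ``stratify_by`` restricts group_a to samples
    carrying the given mutation label (group_b is left untouched).
    """
    ann = mat.annotation
    for g in (group_a, group_b):
        if g not in set(ann.condition.values):
            raise ValueError(f"unknown condition {g!r}")
    samples_a = [s for s in ann.samples_in(group_a, stratify_by) if s in set(mat.sample_ids)]
    samples_b = [s for s in ann.samples_in(group_b) if s in set(mat.sample_ids)]
    if not samples_a:
        raise ValueError(f"empty stratum for condition {group_a!r} / mutation {stratify_by!r}")
    if not samples_b:
        raise ValueError(f"no samples for condition {group_b!r}")
    fc = mat.values[samples_a].mean(axis=1) - mat.values[samples_b].mean(axis=1)
    fc.name = f"log2FC[{group_a}-{group_b}]"
    return fc


def hcluster_samples(mat: ExpressionMatrix, feature_subset: Sequence[str]) -> dict:
    """Agglomerative clustering of samples (Euclidean distance, complete
    linkage) on the given feature subset.

    Samples are ordered lexicographically by id before linkage, which makes
    tie-breaking deterministic.  Returns a dict with ``sample_order`` (the
    lexicographic leaf labels) and ``linkage`` (the scipy merge matrix).
    """
    subset = [f for f in feature_subset if f in set(mat.feature_ids)]
    if not subset:
        raise ValueError("feature_subset is empty or disjoint from the matrix")
    if mat.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    order = sorted(mat.sample_ids)
    data = mat.values.loc[subset, order].to_numpy().T  # samples x features
    z = linkage(pdist(data, metric="euclidean"), method="complete")
    return {"sample_order": order, "linkage": z}
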