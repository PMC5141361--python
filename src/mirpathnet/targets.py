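"""Expression-supported miRNA targeting.

Sequence-based target predictions carry many false positives; this module
keeps only the predicted miRNA->gene pairs whose expression profiles are
significantly anticorrelated across the samples of a comparison — the
mechanistic expectation for a repressive interaction.  The selection rule is
Pearson r < -0.5 with Benjamini-Hochberg FDR < 0.1 (both strict), applied
over exactly the family of testable predicted pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = [
    "PredictedTargets",
    "ValidatedTargets",
    "SupportedInteraction",
    "read_predicted_targets",
    "read_validated_targets",
    "pearson_r",
    "correlation_p_value",
    "bh_fdr",
    "select_supported",
    "restrict_to_pathway_genes",
]


@dataclass(frozen=True)
class PredictedTargets:
    """Prediction table: one row per (mirna_id, gene_id) with a confidence
    score in [0, 1] (e.g. a conservation-weighted sequence score)."""

    table: pd.DataFrame  # columns: mirna_id, gene_id, score

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id", "score"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"prediction table needs columns {sorted(required)}")
        if self.table.duplicated(["mirna_id", "gene_id"]).any():
            raise ValueError("duplicate (mirna_id, gene_id) pairs in predictions")
        if not np.isfinite(self.table["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite prediction scores")

    def filter_score(self, score_min: float) -> "PredictedTargets":
        return PredictedTargets(self.table[self.table["score"] >= score_min].reset_index(drop=True))

    def filter_top_fraction(self, fraction: float = 0.25) -> "PredictedTargets":
        """Alternative score mode: keep the top ``fraction`` of the score
        distribution (score >= the (1-fraction) linear-interpolation quantile)."""
        cut = float(np.quantile(self.table["score"], 1 - fraction))
        return PredictedTargets(self.table[self.table["score"] >= cut].reset_index(drop=True))

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna_id"], self.table["gene_id"]))


@dataclass(frozen=True)
class ValidatedTargets:
    """Experimentally validated miRNA->gene pairs (reporter-assay grade)."""

    table: pd.DataFrame  # columns: mirna_id, gene_id, source, assay

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id", "source"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"validated table needs columns {sorted(required)}")

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna_id"], self.table["gene_id"]))


@dataclass(frozen=True)
class SupportedInteraction:
    """A predicted pair with its anticorrelation evidence."""

    mirna_id: str
    gene_id: str
    r: float
    p: float
    q: float
    passed: bool


def read_predicted_targets(path: str | Path) -> PredictedTargets:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    return PredictedTargets(df)


def read_validated_targets(path: str | Path) -> ValidatedTargets:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ValidatedTargets(df)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation from the t distribution.

    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  |r| = 1 returns 0
    by convention.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a correlation p-value")
    if not -1 <= r <= 1:
        raise ValueError("r outside [-1, 1]")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_supported(
    predictions: PredictedTargets,
    mirna_mat: ExpressionMatrix,
    gene_mat: ExpressionMatrix,
    score_min: float = 0.8,
    r_max: float = -0.5,
    q_max: float = 0.1,
    score_mode: str = "threshold",
) -> list[SupportedInteraction]:
    """Select predicted pairs supported by expression anticorrelation.

    Correlations are computed for predicted pairs passing the score filter
    whose members are present in both matrices; the BH family is exactly
    those tested pairs.  A pair passes iff r < r_max AND q < q_max (both
    strict).  Pairs with a constant profile are dropped with a warning.

    ``score_mode`` is "threshold" (score >= score_min) or "top_fraction"
    (upper score_min fraction of the score distribution).
    """
    if mirna_mat.sample_ids != gene_mat.sample_ids:
        raise ValueError("miRNA and gene matrices must share identical sample sets and order")
    if score_mode == "threshold":
        preds = predictions.filter_score(score_min)
    elif score_mode == "top_fraction":
        preds = predictions.filter_top_fraction(score_min)
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")

    mirnas = set(mirna_mat.feature_ids)
    genes = set(gene_mat.feature_ids)
    rows = preds.table[
        preds.table["mirna_id"].isin(mirnas) & preds.table["gene_id"].isin(genes)
    ].sort_values(["mirna_id", "gene_id"])
    if rows.empty:
        warnings.warn("no testable miRNA-target pairs", stacklevel=2)
        return []

    n = mirna_mat.n_samples
    mvals = mirna_mat.values
    gvals = gene_mat.values
    tested: list[tuple[str, str, float, float]] = []
    for m, g in zip(rows["mirna_id"], rows["gene_id"]):
        x = mvals.loc[m].to_numpy()
        y = gvals.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant profile, dropping pair ({m}, {g})", stacklevel=2)
            continue
        r = pearson_r(x, y)
        tested.append((m, g, r, correlation_p_value(r, n)))
    if not tested:
        warnings.warn("no testable miRNA-target pairs", stacklevel=2)
        return []
    q = bh_fdr([t[3] for t in tested])
    return [
        SupportedInteraction(m, g, r, p, float(qi), bool(r < r_max and qi < q_max))
        for (m, g, r, p), qi in zip(tested, q)
    ]


def restrict_to_pathway_genes(
    interactions: list[SupportedInteraction], gene_universe: set[str]
) -> list[SupportedInteraction]:
    """Keep interactions whose target gene is annotated in a pathway."""
    return [i for i in interactions if i.gene_id in gene_universe]
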