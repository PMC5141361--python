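"""Mixed TF-miRNA-gene feed-forward circuit discovery.

Two three-node topologies are considered:

* ``tf_master`` — a transcription factor drives both a miRNA and a gene,
  while the miRNA post-transcriptionally represses that same gene;
* ``mirna_master`` — a miRNA represses both a TF-encoding transcript and a
  second gene which is itself a transcriptional target of that TF.

Candidates are enumerated from regulation catalogs (TF->miRNA, TF->gene)
joined with the target-prediction table, then scored by the three pairwise
Pearson correlations on the comparison's samples; a circuit is retained when
all three |r| >= 0.5 ("at least", non-strict).  Retained circuits are
classified as coherent or incoherent feed-forward loops by sign algebra: TF
edges take the sign of the observed correlation, miRNA->target edges are
always repressive, and the loop is coherent when the direct edge sign equals
the product of signs along the indirect two-step route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .targets import PredictedTargets, pearson_r

__all__ = [
    "TFCatalog",
    "Circuit",
    "read_tf_catalog",
    "enumerate_candidates",
    "score_and_filter",
    "classify_ffl",
    "link_to_network",
    "circuits_to_frame",
]


@dataclass(frozen=True)
class TFCatalog:
    """Validated TF->miRNA and TF->gene regulation tables.  TF ids live in
    the gene identifier namespace (a TF is a gene)."""

    tf_mirna: pd.DataFrame  # columns: tf_id, mirna_id, source
    tf_gene: pd.DataFrame  # columns: tf_id, target_gene_id, source

    def __post_init__(self) -> None:
        if not {"tf_id", "mirna_id"}.issubset(self.tf_mirna.columns):
            raise ValueError("tf_mirna table needs columns tf_id, mirna_id")
        if not {"tf_id", "target_gene_id"}.issubset(self.tf_gene.columns):
            raise ValueError("tf_gene table needs columns tf_id, target_gene_id")
        if self.tf_mirna.duplicated(["tf_id", "mirna_id"]).any():
            raise ValueError("duplicate (tf_id, mirna_id) rows")
        if self.tf_gene.duplicated(["tf_id", "target_gene_id"]).any():
            raise ValueError("duplicate (tf_id, target_gene_id) rows")

    @property
    def tf_ids(self) -> set[str]:
        return set(self.tf_mirna["tf_id"]) | set(self.tf_gene["tf_id"])


@dataclass(frozen=True)
class Circuit:
    """One TF-miRNA-gene triangle with its three correlations."""

    topology: str  # "tf_master" | "mirna_master"
    tf_id: str
    mirna_id: str
    gene_id: str
    r_tf_mirna: float | None = None
    r_tf_gene: float | None = None
    r_mirna_gene: float | None = None
    coherence: str | None = None  # "coherent" | "incoherent"

    def members(self) -> set[str]:
        return {self.tf_id, self.mirna_id, self.gene_id}


def read_tf_catalog(tf_mirna_path: str | Path, tf_gene_path: str | Path) -> TFCatalog:
    return TFCatalog(
        pd.read_csv(tf_mirna_path, sep="\t", dtype=str),
        pd.read_csv(tf_gene_path, sep="\t", dtype=str),
    )


def enumerate_candidates(
    catalog: TFCatalog,
    predictions: PredictedTargets,
    available_genes: set[str],
    available_mirnas: set[str],
) -> list[Circuit]:
    """Enumerate unscored circuit candidates from catalog/prediction joins.

    ``predictions`` must already be filtered to the configured score mode.
    Only triples whose three members are all present in the expression data
    are kept, and the regulated gene is never the TF itself.
    """
    pred_pairs = predictions.pairs()
    tf_mirna = {
        (t, m)
        for t, m in zip(catalog.tf_mirna["tf_id"], catalog.tf_mirna["mirna_id"])
        if t in available_genes and m in available_mirnas
    }
    tf_gene = {
        (t, g)
        for t, g in zip(catalog.tf_gene["tf_id"], catalog.tf_gene["target_gene_id"])
        if t in available_genes and g in available_genes
    }
    preds = {
        (m, g) for m, g in pred_pairs if m in available_mirnas and g in available_genes
    }

    # index predictions by miRNA for the joins
    targets_of: dict[str, set[str]] = {}
    for m, g in preds:
        targets_of.setdefault(m, set()).add(g)
    genes_of_tf: dict[str, set[str]] = {}
    for t, g in tf_gene:
        genes_of_tf.setdefault(t, set()).add(g)

    out: set[tuple[str, str, str, str]] = set()
    # (i) TF drives miRNA and gene; miRNA represses the gene
    for t, m in tf_mirna:
        for g in genes_of_tf.get(t, set()) & targets_of.get(m, set()):
            if g != t:
                out.add(("tf_master", t, m, g))
    # (ii) miRNA represses a TF transcript and a gene; TF drives that gene
    for m, tgts in targets_of.items():
        for t in tgts:
            if t not in genes_of_tf:
                continue
            for g in genes_of_tf[t] & tgts:
                if g != t:
                    out.add(("mirna_master", t, m, g))
    return [
        Circuit(topology, tf, mirna, gene)
        for topology, tf, mirna, gene in sorted(out)
    ]


def score_and_filter(
    candidates: list[Circuit],
    mirna_mat: ExpressionMatrix,
    gene_mat: ExpressionMatrix,
    min_abs_r: float = 0.5,
) -> list[Circuit]:
    """Score candidates with the three pairwise Pearson correlations and keep
    circuits with |r| >= min_abs_r on all three edges (non-strict).  Retained
    circuits are classified coherent/incoherent; candidates with a constant
    member profile are dropped with a warning."""
    if mirna_mat.sample_ids != gene_mat.sample_ids:
        raise ValueError("matrices must be sample-aligned")
    out: list[Circuit] = []
    gvals, mvals = gene_mat.values, mirna_mat.values
    for c in candidates:
        try:
            tf = gvals.loc[c.tf_id].to_numpy()
            g = gvals.loc[c.gene_id].to_numpy()
            m = mvals.loc[c.mirna_id].to_numpy()
        except KeyError as exc:
            raise ValueError(f"circuit member missing from expression data: {exc}") from exc
        if np.ptp(tf) == 0 or np.ptp(g) == 0 or np.ptp(m) == 0:
            warnings.warn(
                f"constant profile in circuit ({c.tf_id},{c.mirna_id},{c.gene_id}); dropped",
                stacklevel=2,
            )
            continue
        scored = replace(
            c,
            r_tf_mirna=pearson_r(tf, m),
            r_tf_gene=pearson_r(tf, g),
            r_mirna_gene=pearson_r(m, g),
        )
        if (
            abs(scored.r_tf_mirna) >= min_abs_r
            and abs(scored.r_tf_gene) >= min_abs_r
            and abs(scored.r_mirna_gene) >= min_abs_r
        ):
            out.append(replace(scored, coherence=classify_ffl(scored)))
    return out


def classify_ffl(c: Circuit) -> str:
    """Coherence of a scored feed-forward loop by sign algebra.

    TF edge signs are sign(r); miRNA->target edges are repressive (-) by
    mechanism regardless of the observed correlation sign.  The loop is
    coherent when the direct edge of the topology's master regulator has the
    same sign as the product of the two indirect edge signs:

    * tf_master: direct TF->gene (sign r_tf_gene) vs TF->miRNA->gene
      (sign r_tf_mirna * (-1));
    * mirna_master: direct miRNA->gene (-1) vs miRNA->TF->gene
      ((-1) * sign r_tf_gene).
    """
    for r in (c.r_tf_mirna, c.r_tf_gene, c.r_mirna_gene):
        if r is None:
            raise ValueError("circuit must be scored before classification")
        if r == 0:
            raise ValueError("zero correlation: coherence undefined")
    if c.topology == "tf_master":
        direct = np.sign(c.r_tf_gene)
        indirect = np.sign(c.r_tf_mirna) * -1.0
    elif c.topology == "mirna_master":
        direct = -1.0
        indirect = -1.0 * np.sign(c.r_tf_gene)
    else:
        raise ValueError(f"unknown topology {c.topology!r}")
    return "coherent" if direct == indirect else "incoherent"


def link_to_network(circuits: list[Circuit], network_node_ids: set[str]) -> list[Circuit]:
    """Keep circuits sharing at least one member (gene, TF or miRNA) with the
    pathway-derived network."""
    return [c for c in circuits if c.members() & network_node_ids]


def circuits_to_frame(circuits: list[Circuit]) -> pd.DataFrame:
    """Tabular export: one row per circuit with all three correlations."""
    return pd.DataFrame(
        [
            {
                "topology": c.topology,
                "tf_id": c.tf_id,
                "mirna_id": c.mirna_id,
                "gene_id": c.gene_id,
                "r_tf_mirna": c.r_tf_mirna,
                "r_tf_gene": c.r_tf_gene,
                "r_mirna_gene": c.r_mirna_gene,
                "coherence": c.coherence,
            }
            for c in circuits
        ]
    )
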