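"""Seeded synthetic input bundles with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
three-class design (one case class, two control classes, mirroring a
disease-vs-two-tissues comparison), log2-normal expression, a mean shift
planted along a designated pathway path in the case class, miRNA-target
pairs planted with a chosen negative correlation, and TF-miRNA-gene circuits
built from a latent driver with chosen sign patterns.  Every bundle is fully
deterministic given its seed and ships the exact TSV dialects the pipeline
consumes, plus a machine-readable truth record for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import Circuit, TFCatalog
from .expression import ExpressionMatrix, SampleAnnotation, write_expression_matrix
from .pathways import PathwayEdge, PathwayGraph, write_pathway_edgelist
from .targets import PredictedTargets, SupportedInteraction, ValidatedTargets

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticBundle", "generate", "evaluate_recovery"]

_MUTATIONS = ("JAK2V617F", "CALR", "MPLW515", "3N")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic bundle.

    Defaults follow the scale of a two-tissue case/control expression study:
    30 samples per class, 300 genes, 40 miRNAs, three 25-node pathways with
    one planted 5-node differential path (shift 1.5 sigma), ten miRNA-target
    pairs planted at correlation -0.8, and two planted circuits per
    feed-forward topology.
    """

    n_case: int = 30
    n_ctrl_a: int = 30
    n_ctrl_b: int = 30
    n_genes: int = 300
    n_mirnas: int = 40
    n_pathways: int = 3
    pathway_size: int = 25
    planted_path_length: int = 5
    delta: float = 1.5  # case mean shift on planted path genes, in sigma units
    rho: float = -0.8  # planted miRNA-target correlation
    n_planted_targets: int = 10
    n_validated_on_path: int = 2
    n_circuits_per_topology: int = 2
    sigma: float = 1.0  # baseline log2-scale noise SD
    n_decoy_predictions: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_case", "n_ctrl_a", "n_ctrl_b", "n_genes", "n_mirnas",
            "n_pathways", "pathway_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.planted_path_length > self.pathway_size:
            raise ValueError("planted path longer than its pathway")
        if self.n_pathways * self.pathway_size > self.n_genes:
            raise ValueError("pathways reference more genes than generated")
        if self.n_planted_targets > self.n_mirnas:
            raise ValueError("more planted targets than miRNAs")


@dataclass
class SyntheticTruth:
    """Ground truth of a bundle: what was planted, keyed by generated ids."""

    planted_path_nodes: dict[str, list[str]]  # pathway_id -> node ids
    planted_pairs: list[tuple[str, str, float]]  # (mirna, gene, rho)
    planted_circuits: list[dict]  # topology, tf, mirna, gene, coherence
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_path_nodes": self.planted_path_nodes,
                "planted_pairs": [list(p) for p in self.planted_pairs],
                "planted_circuits": self.planted_circuits,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticBundle:
    """In-memory bundle of everything the pipeline consumes."""

    gene_mat: ExpressionMatrix
    mirna_mat: ExpressionMatrix
    annotation: SampleAnnotation
    pathways: list[PathwayGraph]
    predictions: PredictedTargets
    validated: ValidatedTargets
    catalog: TFCatalog
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as the pipeline's TSV dialects plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "mirnas": outdir / "mirnas.tsv",
            "annotation": outdir / "samples.tsv",
            "pathways": outdir / "pathways.tsv",
            "predictions": outdir / "predicted_targets.tsv",
            "validated": outdir / "validated_targets.tsv",
            "tf_mirna": outdir / "tf_mirna.tsv",
            "tf_gene": outdir / "tf_gene.tsv",
            "truth": outdir / "truth.json",
        }
        write_expression_matrix(self.gene_mat, paths["genes"])
        write_expression_matrix(self.mirna_mat, paths["mirnas"])
        ann = pd.DataFrame(
            {
                "sample_id": self.annotation.sample_ids,
                "condition": self.annotation.condition.values,
                "mutation": self.annotation.mutation.values,
            }
        )
        ann.to_csv(paths["annotation"], sep="\t", index=False)
        write_pathway_edgelist(self.pathways, paths["pathways"])
        self.predictions.table.to_csv(paths["predictions"], sep="\t", index=False)
        self.validated.table.to_csv(paths["validated"], sep="\t", index=False)
        self.catalog.tf_mirna.to_csv(paths["tf_mirna"], sep="\t", index=False)
        self.catalog.tf_gene.to_csv(paths["tf_gene"], sep="\t", index=False)
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _scaffold_pathway(
    pid: str, genes: list[str], path_genes: list[str], rng: np.random.Generator
) -> PathwayGraph:
    """A pathway graph containing the planted chain plus a random cascade
    scaffold.

    The chain models a terminal signaling cascade: the scaffold tree hangs
    off the chain's middle node only, leaving the chain ends as terminal
    nodes, and the remaining genes attach downstream of random already
    placed scaffold nodes.  A couple of extra cross edges among scaffold
    genes exercise moralization and triangulation."""
    nodes: dict[str, str] = {g: "gene" for g in genes}
    edges: list[PathwayEdge] = []
    etypes = ["activation", "inhibition"]
    for a, b in zip(path_genes, path_genes[1:]):
        edges.append(PathwayEdge(a, b, True, str(rng.choice(etypes)), pid))
    others = [g for g in genes if g not in path_genes]
    anchor = path_genes[len(path_genes) // 2]
    attached = [anchor]
    for g in others:
        parent = attached[int(rng.integers(len(attached)))]
        edges.append(PathwayEdge(parent, g, True, str(rng.choice(etypes)), pid))
        attached.append(g)
    # a few cross links among scaffold genes (co-parents / cycles)
    existing = {(e.src, e.dst) for e in edges}
    n_extra = 2
    tries = 0
    while n_extra > 0 and tries < 100 and len(others) >= 2:
        tries += 1
        a, b = (others[int(i)] for i in rng.integers(len(others), size=2))
        if a == b or (a, b) in existing or (b, a) in existing:
            continue
        edges.append(PathwayEdge(a, b, True, str(rng.choice(etypes)), pid))
        existing.add((a, b))
        n_extra -= 1
    return PathwayGraph(pid, f"synthetic pathway {pid}", nodes, edges)


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a complete input bundle with known ground truth."""
    rng = np.random.default_rng(config.seed)
    c = config

    gene_ids = [f"G{i + 1:04d}" for i in range(c.n_genes)]
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(c.n_mirnas)]
    samples = (
        [f"CASE_{i + 1:02d}" for i in range(c.n_case)]
        + [f"CTA_{i + 1:02d}" for i in range(c.n_ctrl_a)]
        + [f"CTB_{i + 1:02d}" for i in range(c.n_ctrl_b)]
    )
    conditions = (
        ["case"] * c.n_case + ["ctrl_a"] * c.n_ctrl_a + ["ctrl_b"] * c.n_ctrl_b
    )
    mutations = [
        _MUTATIONS[i % len(_MUTATIONS)] if cond == "case" else "none"
        for i, cond in enumerate(conditions)
    ]
    annotation = SampleAnnotation(
        pd.Series(conditions, index=samples, name="condition"),
        pd.Series(mutations, index=samples, name="mutation"),
    )
    n_total = len(samples)
    case_mask = np.array([cond == "case" for cond in conditions])

    # pathways over disjoint gene blocks; planted path in the first pathway
    pathways: list[PathwayGraph] = []
    planted_path_nodes: dict[str, list[str]] = {}
    pathway_gene_sets: list[list[str]] = []
    for j in range(c.n_pathways):
        block = gene_ids[j * c.pathway_size : (j + 1) * c.pathway_size]
        pathway_gene_sets.append(block)
        pid = f"pw{j + 1}"
        if j == 0 and c.delta > 0:
            path_genes = block[: c.planted_path_length]
            planted_path_nodes[pid] = path_genes
        else:
            path_genes = block[:2]  # scaffold chain seed, not a planted effect
            planted_path_nodes.setdefault(pid, [])
        pathways.append(_scaffold_pathway(pid, block, path_genes, rng))
    shifted = set(planted_path_nodes.get("pw1", []))

    # baseline expression
    gene_mu = rng.uniform(4, 12, size=c.n_genes)
    mirna_mu = rng.uniform(4, 12, size=c.n_mirnas)
    gene_z = rng.standard_normal((c.n_genes, n_total))
    mirna_z = rng.standard_normal((c.n_mirnas, n_total))

    # planted anticorrelated miRNA-target pairs: targets are pathway genes
    # off the planted path, one distinct miRNA each
    off_path_pathway_genes = [
        g for block in pathway_gene_sets for g in block if g not in shifted
    ]
    planted_pairs: list[tuple[str, str, float]] = []
    rho = c.rho
    if rho != 0 and c.n_planted_targets > 0:
        tgt_idx = rng.choice(
            len(off_path_pathway_genes), size=c.n_planted_targets, replace=False
        )
        mir_idx = rng.choice(c.n_mirnas, size=c.n_planted_targets, replace=False)
        gidx = {g: i for i, g in enumerate(gene_ids)}
        for ti, mi in zip(tgt_idx, mir_idx):
            g = off_path_pathway_genes[int(ti)]
            m = mirna_ids[int(mi)]
            zg = rng.standard_normal(n_total)
            zm = rho * zg + np.sqrt(1 - rho**2) * rng.standard_normal(n_total)
            gene_z[gidx[g]] = zg
            mirna_z[int(mi)] = zm
            planted_pairs.append((m, g, rho))

    # planted circuits from a latent driver; loading 0.85 -> pairwise |rho|~0.72
    loading = 0.85
    resid = np.sqrt(1 - loading**2)
    free_genes = [g for g in gene_ids[c.n_pathways * c.pathway_size :]]
    free_mirnas = [m for m in mirna_ids if m not in {p[0] for p in planted_pairs}]
    planted_circuits: list[dict] = []
    # sign patterns (s_tf, s_mirna, s_gene) chosen so each topology gets one
    # coherent and one incoherent loop first, then alternating
    patterns = {
        "tf_master": [(1, -1, 1, "coherent"), (1, 1, 1, "incoherent")],
        "mirna_master": [(1, -1, 1, "coherent"), (-1, -1, 1, "incoherent")],
    }
    gidx = {g: i for i, g in enumerate(gene_ids)}
    midx = {m: i for i, m in enumerate(mirna_ids)}
    gi = mi = 0
    for topology in ("tf_master", "mirna_master"):
        for k in range(c.n_circuits_per_topology):
            if gi + 2 > len(free_genes) or mi + 1 > len(free_mirnas):
                raise ValueError("config plants more circuit members than generated features")
            s_tf, s_m, s_g, coherence = patterns[topology][k % 2]
            tf, gene = free_genes[gi], free_genes[gi + 1]
            mirna = free_mirnas[mi]
            gi += 2
            mi += 1
            t = rng.standard_normal(n_total)
            gene_z[gidx[tf]] = s_tf * loading * t + resid * rng.standard_normal(n_total)
            mirna_z[midx[mirna]] = s_m * loading * t + resid * rng.standard_normal(n_total)
            gene_z[gidx[gene]] = s_g * loading * t + resid * rng.standard_normal(n_total)
            planted_circuits.append(
                {
                    "topology": topology,
                    "tf_id": tf,
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "coherence": coherence,
                }
            )

    # database-validated miRNAs targeting planted path genes: validated
    # targeting needs no anticorrelation in a given tissue, and these edges
    # carry miRNA nodes into the deregulated paths via augmentation
    validated_on_path: list[tuple[str, str]] = []
    if shifted and c.n_validated_on_path > 0:
        used = {p[0] for p in planted_pairs} | {
            circ["mirna_id"] for circ in planted_circuits
        }
        avail = [m for m in mirna_ids if m not in used]
        path_list = planted_path_nodes["pw1"]
        for i in range(min(c.n_validated_on_path, len(avail))):
            validated_on_path.append((avail[i], path_list[i % len(path_list)]))

    # planted regulator miRNAs are detectably expressed (upper mean range):
    # an unexpressed miRNA cannot regulate, and QC filters would censor it
    planted_mirna_idx = sorted(
        {midx[m] for m, _, _ in planted_pairs}
        | {midx[circ["mirna_id"]] for circ in planted_circuits}
        | {midx[m] for m, _ in validated_on_path}
    )
    if planted_mirna_idx:
        mirna_mu[planted_mirna_idx] = rng.uniform(8, 12, size=len(planted_mirna_idx))

    gene_values = gene_mu[:, None] + c.sigma * gene_z
    mirna_values = mirna_mu[:, None] + c.sigma * mirna_z
    # case mean shift on the planted path
    for g in shifted:
        gene_values[gidx[g], case_mask] += c.delta * c.sigma

    gene_mat = ExpressionMatrix(
        pd.DataFrame(gene_values, index=gene_ids, columns=samples), "gene", annotation
    )
    mirna_mat = ExpressionMatrix(
        pd.DataFrame(mirna_values, index=mirna_ids, columns=samples), "mirna", annotation
    )

    # prediction table: planted pairs + circuit pairs (high scores) + decoys
    rows: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()

    def _add(m: str, g: str, score: float) -> None:
        if (m, g) not in seen:
            seen.add((m, g))
            rows.append((m, g, round(float(score), 4)))

    for m, g, _ in planted_pairs:
        _add(m, g, rng.uniform(0.8, 1.0))
    for circ in planted_circuits:
        _add(circ["mirna_id"], circ["gene_id"], rng.uniform(0.8, 1.0))
        if circ["topology"] == "mirna_master":
            _add(circ["mirna_id"], circ["tf_id"], rng.uniform(0.8, 1.0))
    decoy_universe_genes = gene_ids
    tries = 0
    added = 0
    while added < c.n_decoy_predictions and tries < 50 * c.n_decoy_predictions:
        tries += 1
        m = mirna_ids[int(rng.integers(c.n_mirnas))]
        g = decoy_universe_genes[int(rng.integers(len(decoy_universe_genes)))]
        if (m, g) in seen:
            continue
        # half the decoys clear the score threshold so the FDR family is
        # exercised with truly null tested pairs
        score = rng.uniform(0.8, 1.0) if added % 2 == 0 else rng.uniform(0.0, 0.8)
        _add(m, g, score)
        added += 1
    predictions = PredictedTargets(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"])
    )

    # every other planted pair is also catalogued as reporter-assay validated
    vrows = [
        (m, g, "miRTarBase", "reporter_assay")
        for i, (m, g, _) in enumerate(planted_pairs)
        if i % 2 == 0
    ]
    vrows.extend((m, g, "miRecords", "reporter_assay") for m, g in validated_on_path)
    validated = ValidatedTargets(
        pd.DataFrame(vrows, columns=["mirna_id", "gene_id", "source", "assay"])
    )

    # TF catalog: circuit relations plus uncorrelated decoy relations
    tf_mirna_rows: list[tuple[str, str, str]] = []
    tf_gene_rows: list[tuple[str, str, str]] = []
    for circ in planted_circuits:
        if circ["topology"] == "tf_master":
            tf_mirna_rows.append((circ["tf_id"], circ["mirna_id"], "synthetic"))
        tf_gene_rows.append((circ["tf_id"], circ["gene_id"], "synthetic"))
    n_decoy_tf = 10
    for _ in range(n_decoy_tf):
        tf = gene_ids[int(rng.integers(c.n_genes))]
        m = mirna_ids[int(rng.integers(c.n_mirnas))]
        g = gene_ids[int(rng.integers(c.n_genes))]
        if (tf, m) not in {(a, b) for a, b, _ in tf_mirna_rows}:
            tf_mirna_rows.append((tf, m, "decoy"))
        if g != tf and (tf, g) not in {(a, b) for a, b, _ in tf_gene_rows}:
            tf_gene_rows.append((tf, g, "decoy"))
    catalog = TFCatalog(
        pd.DataFrame(tf_mirna_rows, columns=["tf_id", "mirna_id", "source"]),
        pd.DataFrame(tf_gene_rows, columns=["tf_id", "target_gene_id", "source"]),
    )

    truth = SyntheticTruth(
        planted_path_nodes=planted_path_nodes,
        planted_pairs=planted_pairs,
        planted_circuits=planted_circuits,
        config=asdict(c),
    )
    return SyntheticBundle(
        gene_mat, mirna_mat, annotation, pathways, predictions, validated, catalog, truth
    )


def _prf(found: set, true: set) -> dict:
    tp = len(found & true)
    precision = tp / len(found) if found else None
    recall = tp / len(true) if true else None
    return {"precision": precision, "recall": recall, "n_found": len(found), "n_true": len(true)}


def evaluate_recovery(
    truth: SyntheticTruth,
    supported: list[SupportedInteraction] | None = None,
    meta_nodes: set[str] | None = None,
    final_path_nodes: set[str] | None = None,
    circuits: list[Circuit] | None = None,
) -> dict:
    """Precision/recall of pipeline outputs against the planted truth.

    Components not handed in are skipped; undefined ratios (empty truth or
    empty output) are reported as None, never as 0/0 artifacts.
    """
    out: dict[str, dict] = {}
    true_path_nodes = {n for nodes in truth.planted_path_nodes.values() for n in nodes}
    if supported is not None:
        found = {(s.mirna_id, s.gene_id) for s in supported if s.passed}
        true = {(m, g) for m, g, _ in truth.planted_pairs}
        out["supported_interactions"] = _prf(found, true)
    if meta_nodes is not None:
        out["meta_pathway_nodes"] = _prf(set(meta_nodes), true_path_nodes)
    if final_path_nodes is not None:
        out["final_path_nodes"] = _prf(set(final_path_nodes), true_path_nodes)
    if circuits is not None:
        found = {(c.topology, c.tf_id, c.mirna_id, c.gene_id) for c in circuits}
        true = {
            (c["topology"], c["tf_id"], c["mirna_id"], c["gene_id"])
            for c in truth.planted_circuits
        }
        out["circuits"] = _prf(found, true)
    return out
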