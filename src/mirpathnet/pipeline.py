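"""End-to-end orchestration: filter -> integrate -> topological analysis per
comparison -> circuits -> link -> merge -> annotate -> export.

The pipeline runs two (or more) case-vs-control comparisons independently —
each produces its own supported interactions, significant pathways,
meta-pathway and final deregulated paths — and merges the per-comparison
networks, with linked feed-forward circuits attached, into one
provenance-tagged regulatory network.  Everything is deterministic given the
configured seed; per-stage seeds are derived from it, so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuits import (
    TFCatalog,
    circuits_to_frame,
    enumerate_candidates,
    link_to_network,
    read_tf_catalog,
    score_and_filter,
)
from .expression import (
    ExpressionMatrix,
    filter_features,
    log2_fold_change,
    read_expression_matrix,
    read_sample_annotation,
)
from .network import (
    RegulatoryNetwork,
    add_circuits,
    annotate_fold_changes,
    export_network,
    merge_networks,
    network_from_pathway,
    network_summary,
)
from .pathways import PathwayGraph, augment_pathway, read_pathway_edgelist
from .targets import (
    PredictedTargets,
    ValidatedTargets,
    read_predicted_targets,
    read_validated_targets,
    restrict_to_pathway_genes,
    select_supported,
)
from .topology import (
    adjust_pathway_qvalues,
    analyze_pathway,
    final_path_selection,
    select_meta_pathway,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_on_bundle"]


@dataclass
class PipelineConfig:
    """All file paths, comparisons and thresholds of one pipeline run.

    ``comparisons`` maps a label (used for provenance and fold-change slots)
    to a (case_condition, control_condition) pair.
    """

    gene_matrix: str
    mirna_matrix: str
    annotation: str
    pathways: str
    predictions: str
    validated: str
    tf_mirna: str
    tf_gene: str
    comparisons: dict[str, tuple[str, str]]
    seed: int = 0
    n_perm: int = 1000
    # feature filtering (applied to the miRNA matrix)
    filter_drop_fraction: float = 0.25
    filter_entropy_bits: float = 1.4
    filter_entropy_bins: int = 10
    # target integration
    score_min: float = 0.8
    score_mode: str = "threshold"
    r_max: float = -0.5
    q_max_targets: float = 0.1
    # topological analysis
    q_max_pathways: float = 0.1
    pathway_significance_mode: str = "either"
    top_k_paths: int = 10
    # circuits
    min_abs_r: float = 0.5
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "comparisons" not in data:
            raise KeyError("config missing required key 'comparisons'")
        data["comparisons"] = {
            label: tuple(pair) for label, pair in data["comparisons"].items()
        }
        return cls(**data)


@dataclass
class ComparisonResult:
    label: str
    classes: tuple[str, str]
    supported: list
    pathway_tests: list
    scored_paths: list
    meta: PathwayGraph | None
    final_paths: list
    network: RegulatoryNetwork
    circuits_all: list
    circuits_linked: list


@dataclass
class PipelineResult:
    config: PipelineConfig
    comparisons: dict[str, ComparisonResult]
    network: RegulatoryNetwork
    summary: dict
    fold_changes: dict

    def to_json_obj(self) -> dict:
        """Stable JSON view of the run (used for the determinism contract)."""
        from .network import _to_json_obj

        obj: dict = {
            "seed": self.config.seed,
            "n_perm": self.config.n_perm,
            "summary": self.summary,
            "network": _to_json_obj(self.network),
            "comparisons": {},
        }
        for label, cr in sorted(self.comparisons.items()):
            obj["comparisons"][label] = {
                "classes": list(cr.classes),
                "n_supported": sum(1 for s in cr.supported if s.passed),
                "supported": sorted(
                    [s.mirna_id, s.gene_id, round(s.r, 10), round(s.q, 10)]
                    for s in cr.supported
                    if s.passed
                ),
                "pathway_tests": [
                    {
                        "pathway_id": t.pathway_id,
                        "p_mean": t.p_mean,
                        "p_var": t.p_var,
                        "q_mean": t.q_mean,
                        "q_var": t.q_var,
                        "significant": t.significant,
                    }
                    for t in cr.pathway_tests
                ],
                "final_paths": [
                    {"label": p.label, "score": round(p.score, 10), "nodes": sorted(p.nodes)}
                    for p in cr.final_paths
                ],
                "circuits_linked": sorted(
                    [c.topology, c.tf_id, c.mirna_id, c.gene_id, c.coherence]
                    for c in cr.circuits_linked
                ),
            }
        return obj


def _derive_seed(base: int, *parts: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(base)] + [int(p) for p in parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _stage(label: str):
    """Context decorating errors with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[stage: {label}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline_on_bundle(
    config: PipelineConfig,
    gene_mat: ExpressionMatrix,
    mirna_mat: ExpressionMatrix,
    pathways: list[PathwayGraph],
    predictions: PredictedTargets,
    validated: ValidatedTargets,
    catalog: TFCatalog,
) -> PipelineResult:
    """Run the pipeline on in-memory inputs (the file-based
    :func:`run_pipeline` is a thin wrapper around this)."""
    if not config.comparisons:
        raise KeyError("config missing required key 'comparisons'")

    with _stage("filter"):
        mirna_f = filter_features(
            mirna_mat,
            drop_fraction=config.filter_drop_fraction,
            entropy_threshold=config.filter_entropy_bits,
            n_bins=config.filter_entropy_bins,
        )

    pathway_gene_universe: set[str] = set()
    for pw in pathways:
        pathway_gene_universe |= pw.gene_ids

    comparison_results: dict[str, ComparisonResult] = {}
    per_comparison_nets: list[RegulatoryNetwork] = []
    fold_changes: dict[str, object] = {}

    for ci, label in enumerate(sorted(config.comparisons)):
        class_a, class_b = config.comparisons[label]
        ann = gene_mat.annotation
        comp_samples = [
            s
            for s in gene_mat.sample_ids
            if ann.condition.get(s) in (class_a, class_b)
        ]
        gene_sub = gene_mat.subset_samples(comp_samples)
        mirna_sub = mirna_f.subset_samples(comp_samples)

        with _stage(f"integrate:{label}"):
            supported = select_supported(
                predictions,
                mirna_sub,
                gene_sub,
                score_min=config.score_min,
                r_max=config.r_max,
                q_max=config.q_max_targets,
                score_mode=config.score_mode,
            )
            supported_pw = restrict_to_pathway_genes(
                [s for s in supported if s.passed], pathway_gene_universe
            )

        with _stage(f"pathways:{label}"):
            augmented = {
                pw.pathway_id: augment_pathway(pw, validated, supported_pw)
                for pw in pathways
            }
            # expression matrix spanning genes and miRNAs for the GGM tests
            combined_values = pd.concat([gene_sub.values, mirna_sub.values])
            combined = ExpressionMatrix(combined_values, "gene", gene_mat.annotation)

            tests = []
            per_pathway_paths = {}
            for pi, pid in enumerate(sorted(augmented)):
                seed = _derive_seed(config.seed, ci, pi)
                test, ct, clique_results, scored = analyze_pathway(
                    combined, augmented[pid], class_a, class_b,
                    n_perm=config.n_perm, seed=seed,
                )
                tests.append(test)
                per_pathway_paths[pid] = scored
            tests = adjust_pathway_qvalues(
                tests, q_max=config.q_max_pathways, mode=config.pathway_significance_mode
            )
            significant = {t.pathway_id for t in tests if t.significant}
            pooled_paths = [
                p for pid in sorted(significant) for p in per_pathway_paths[pid]
            ]

            meta = None
            final_paths = []
            if pooled_paths:
                meta = select_meta_pathway(
                    pooled_paths,
                    {pid: augmented[pid] for pid in sorted(significant)},
                    k=config.top_k_paths,
                    meta_id=f"meta_{label}",
                )
                final_paths = final_path_selection(
                    meta, combined, class_a, class_b,
                    n_perm=config.n_perm, seed=_derive_seed(config.seed, ci, 9999),
                )

        with _stage(f"network:{label}"):
            net = RegulatoryNetwork()
            if final_paths and meta is not None:
                final_nodes = set().union(*(p.nodes for p in final_paths))
                sub_nodes = {n: k for n, k in meta.nodes.items() if n in final_nodes}
                sub_edges = [
                    e for e in meta.edges if e.src in final_nodes and e.dst in final_nodes
                ]
                sub = PathwayGraph(f"final_{label}", f"final paths {label}",
                                   sub_nodes, sub_edges)
                net = network_from_pathway(sub, provenance=label, tf_ids=catalog.tf_ids)

        with _stage(f"circuits:{label}"):
            if config.score_mode == "threshold":
                preds_f = predictions.filter_score(config.score_min)
            else:
                preds_f = predictions.filter_top_fraction(config.score_min)
            candidates = enumerate_candidates(
                catalog,
                preds_f,
                available_genes=set(gene_sub.feature_ids),
                available_mirnas=set(mirna_sub.feature_ids),
            )
            circuits_all = score_and_filter(
                candidates, mirna_sub, gene_sub, min_abs_r=config.min_abs_r
            )
            circuits_linked = link_to_network(circuits_all, net.node_ids)
            net = add_circuits(net, circuits_linked, provenance=f"{label}:circuits")

        with _stage(f"fold_change:{label}"):
            fc_gene = log2_fold_change(gene_mat, class_a, class_b)
            fc_mirna = log2_fold_change(mirna_mat, class_a, class_b)
            fold_changes[label] = pd.concat([fc_gene, fc_mirna])

        comparison_results[label] = ComparisonResult(
            label=label,
            classes=(class_a, class_b),
            supported=supported,
            pathway_tests=tests,
            scored_paths=pooled_paths,
            meta=meta,
            final_paths=final_paths,
            network=net,
            circuits_all=circuits_all,
            circuits_linked=circuits_linked,
        )
        per_comparison_nets.append(net)

    with _stage("merge"):
        merged = merge_networks(per_comparison_nets)
        merged = annotate_fold_changes(merged, fold_changes)
        summary = network_summary(merged)

    result = PipelineResult(
        config=config,
        comparisons=comparison_results,
        network=merged,
        summary=summary,
        fold_changes=fold_changes,
    )

    if config.output_dir:
        with _stage("export"):
            write_outputs(result, config.output_dir)
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load all configured input files and run the pipeline."""
    with _stage("load"):
        annotation = read_sample_annotation(config.annotation)
        gene_mat = read_expression_matrix(config.gene_matrix, annotation, "gene")
        mirna_mat = read_expression_matrix(config.mirna_matrix, annotation, "mirna")
        pathways = read_pathway_edgelist(config.pathways)
        predictions = read_predicted_targets(config.predictions)
        validated = read_validated_targets(config.validated)
        catalog = read_tf_catalog(config.tf_mirna, config.tf_gene)
    return run_pipeline_on_bundle(
        config, gene_mat, mirna_mat, pathways, predictions, validated, catalog
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the result bundle: network exports, circuit table, run JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fmt in ("json", "graphml", "sif"):
        p = outdir / f"network.{fmt}"
        export_network(result.network, fmt, p)
        paths[f"network_{fmt}"] = p
    all_linked = [c for cr in result.comparisons.values() for c in cr.circuits_linked]
    cpath = outdir / "circuits.tsv"
    circuits_to_frame(all_linked).to_csv(cpath, sep="\t", index=False)
    paths["circuits"] = cpath
    rpath = outdir / "run.json"
    rpath.write_text(json.dumps(result.to_json_obj(), indent=2, sort_keys=True) + "\n")
    paths["run"] = rpath
    return paths
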