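"""Typed, signed, partially directed pathway graphs and miRNA augmentation.

A pathway is a graph over genes (and, after augmentation, miRNAs) with typed
edges: activation / inhibition (directed), binding (undirected), and
miRNA-target edges (always miRNA -> gene, repressive in sign semantics,
typed ``mirna_validated`` or ``mirna_predicted`` by evidence class).
Pathways are read from a plain TSV edge-list dialect so the pipeline runs
without database access; SIF export is provided for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .targets import SupportedInteraction, ValidatedTargets

EDGE_TYPES = {"activation", "inhibition", "binding", "mirna_validated", "mirna_predicted"}
NODE_KINDS = {"gene", "mirna"}

__all__ = [
    "PathwayEdge",
    "PathwayGraph",
    "read_pathway_edgelist",
    "write_pathway_edgelist",
    "write_sif",
    "augment_pathway",
    "moral_graph",
]


@dataclass(frozen=True)
class PathwayEdge:
    src: str
    dst: str
    directed: bool
    etype: str
    provenance: str = ""


@dataclass
class PathwayGraph:
    """A pathway topology: nodes with kinds, typed (possibly undirected) edges."""

    pathway_id: str
    name: str
    nodes: dict[str, str] = field(default_factory=dict)  # id -> kind
    edges: list[PathwayEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for nid, kind in self.nodes.items():
            if kind not in NODE_KINDS:
                raise ValueError(f"unknown node kind {kind!r} for {nid}")
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.src == e.dst:
                raise ValueError(f"self-loop on {e.src} in {self.pathway_id}")
            if e.etype not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {e.etype!r} ({e.src}->{e.dst})")
            for endpoint in (e.src, e.dst):
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} not among nodes")
            if e.etype in ("mirna_validated", "mirna_predicted"):
                if self.nodes[e.src] != "mirna" or self.nodes[e.dst] != "gene":
                    raise ValueError(
                        f"{e.etype} edges must run miRNA -> gene ({e.src}->{e.dst})"
                    )
            key = (e.src, e.dst, e.etype)
            if key in seen:
                raise ValueError(f"duplicate edge {key} in {self.pathway_id}")
            seen.add(key)

    @property
    def gene_ids(self) -> set[str]:
        return {n for n, k in self.nodes.items() if k == "gene"}

    @property
    def mirna_ids(self) -> set[str]:
        return {n for n, k in self.nodes.items() if k == "mirna"}

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(self.pathway_id, self.name, dict(self.nodes), list(self.edges))


def read_pathway_edgelist(path: str | Path) -> list[PathwayGraph]:
    """Parse one or more pathway graphs from the TSV edge-list dialect.

    Each graph opens with a header line ``#pathway<TAB>id<TAB>name``; edge
    rows are ``src<TAB>src_kind<TAB>etype<TAB>dst<TAB>dst_kind<TAB>directed``.
    Other ``#`` lines are comments.
    """
    graphs: list[PathwayGraph] = []
    seen_ids: set[str] = set()
    current: PathwayGraph | None = None

    def _close() -> None:
        if current is not None:
            # re-validate as a whole
            graphs.append(PathwayGraph(current.pathway_id, current.name,
                                       dict(current.nodes), list(current.edges)))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#pathway\t"):
                _close()
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed #pathway header")
                pid, pname = parts[1], parts[2]
                if pid in seen_ids:
                    raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
                seen_ids.add(pid)
                current = PathwayGraph(pid, pname)
                continue
            if line.startswith("#"):
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: edge row before any #pathway header")
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            src, src_kind, etype, dst, dst_kind, directed = parts
            if etype not in EDGE_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown edge type {etype!r}")
            for nid, kind in ((src, src_kind), (dst, dst_kind)):
                if kind not in NODE_KINDS:
                    raise ValueError(f"{path}:{lineno}: unknown node kind {kind!r}")
                if current.nodes.setdefault(nid, kind) != kind:
                    raise ValueError(f"{path}:{lineno}: conflicting kind for node {nid!r}")
            current.edges.append(
                PathwayEdge(src, dst, directed == "1", etype, provenance=current.pathway_id)
            )
    _close()
    return graphs


def write_pathway_edgelist(graphs: list[PathwayGraph], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in graphs:
            fh.write(f"#pathway\t{g.pathway_id}\t{g.name}\n")
            for e in g.edges:
                fh.write(
                    "\t".join(
                        [e.src, g.nodes[e.src], e.etype, e.dst, g.nodes[e.dst],
                         "1" if e.directed else "0"]
                    )
                    + "\n"
                )


def write_sif(g: PathwayGraph, path: str | Path) -> None:
    """Cytoscape-loadable SIF: one ``src<TAB>etype<TAB>dst`` line per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in g.edges:
            fh.write(f"{e.src}\t{e.etype}\t{e.dst}\n")


def augment_pathway(
    pw: PathwayGraph,
    validated: ValidatedTargets | None,
    supported: list[SupportedInteraction],
) -> PathwayGraph:
    """Add miRNA nodes and miRNA->gene edges for targets already in the pathway.

    Only miRNAs with at least one target gene annotated in the pathway are
    added; genes are never added.  A pair present in both the validated
    catalog and the supported list gets a single edge typed
    ``mirna_validated`` (validation takes precedence over prediction).
    """
    out = pw.copy()
    pathway_genes = pw.gene_ids
    vpairs = validated.pairs() if validated is not None else set()
    existing = {(e.src, e.dst) for e in out.edges if e.etype.startswith("mirna_")}

    candidate: dict[tuple[str, str], str] = {}
    for mirna, gene in sorted(vpairs):
        if gene in pathway_genes:
            candidate[(mirna, gene)] = "mirna_validated"
    for si in supported:
        if not si.passed or si.gene_id not in pathway_genes:
            continue
        candidate.setdefault((si.mirna_id, si.gene_id), "mirna_predicted")

    for (mirna, gene), etype in sorted(candidate.items()):
        if (mirna, gene) in existing:
            continue
        out.nodes.setdefault(mirna, "mirna")
        out.edges.append(PathwayEdge(mirna, gene, True, etype, provenance="target_integration"))
    return PathwayGraph(out.pathway_id, out.name, out.nodes, out.edges)


def moral_graph(pw: PathwayGraph) -> nx.Graph:
    """Moralize: drop directions, marry every pair of directed co-parents.

    Undirected (binding) edges are kept as plain adjacencies.  miRNA edges
    enter as ordinary adjacencies; the Gaussian graphical model downstream is
    sign-agnostic.
    """
    g = nx.Graph()
    g.add_nodes_from(pw.nodes)
    parents: dict[str, set[str]] = {n: set() for n in pw.nodes}
    for e in pw.edges:
        g.add_edge(e.src, e.dst)
        if e.directed:
            parents[e.dst].add(e.src)
    for node, ps in parents.items():
        for a in ps:
            for b in ps:
                if a < b:
                    g.add_edge(a, b)
    return g
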