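"""Assembly, annotation and export of the merged regulatory network.

The final deliverable of the pipeline is a single provenance-tagged network
merging, for each two-class comparison, the pathway-derived deregulated
paths (gene-gene edges plus miRNA-target edges) with the linked TF-miRNA-
gene circuits.  Nodes carry one log2 fold-change slot per comparison; every
node and edge records the set of comparisons / sources that contributed it.
Exports: GraphML and JSON (lossless round trip) and SIF (topology only, all
Cytoscape-loadable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .circuits import Circuit
from .pathways import PathwayGraph

NODE_KINDS = {"gene", "tf", "mirna"}
EDGE_TYPES = {
    "activation",
    "inhibition",
    "binding",
    "mirna_validated",
    "mirna_predicted",
    "tf_mirna",
    "tf_gene",
}

__all__ = [
    "RegulatoryNetwork",
    "network_from_pathway",
    "add_circuits",
    "merge_networks",
    "annotate_fold_changes",
    "network_summary",
    "export_network",
    "import_network",
]


@dataclass
class RegulatoryNetwork:
    """Merged regulatory network.

    ``nodes``: id -> {"kind": str, "fc": {comparison: float}, "provenance": set}
    ``edges``: (src, dst, etype) -> {"provenance": set}
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], dict] = field(default_factory=dict)

    def add_node(self, node_id: str, kind: str, provenance: str) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        entry = self.nodes.get(node_id)
        if entry is None:
            self.nodes[node_id] = {"kind": kind, "fc": {}, "provenance": {provenance}}
            return
        if entry["kind"] != kind:
            # a gene may be promoted to TF, never across gene/miRNA spaces
            if {entry["kind"], kind} == {"gene", "tf"}:
                entry["kind"] = "tf"
            else:
                raise ValueError(
                    f"conflicting kinds for node {node_id!r}: {entry['kind']} vs {kind}"
                )
        entry["provenance"].add(provenance)

    def add_edge(self, src: str, dst: str, etype: str, provenance: str) -> None:
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        for endpoint in (src, dst):
            if endpoint not in self.nodes:
                raise ValueError(f"edge endpoint {endpoint!r} not in network")
        self.edges.setdefault((src, dst, etype), {"provenance": set()})[
            "provenance"
        ].add(provenance)

    @property
    def node_ids(self) -> set[str]:
        return set(self.nodes)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[tuple[str, str, str]]:
        return sorted(self.edges)


def network_from_pathway(
    pw: PathwayGraph, provenance: str, tf_ids: set[str] | None = None
) -> RegulatoryNetwork:
    """Convert a (meta-)pathway graph into a regulatory network; genes found
    in the TF catalog are typed ``tf``."""
    tf_ids = tf_ids or set()
    net = RegulatoryNetwork()
    for n, kind in sorted(pw.nodes.items()):
        out_kind = "tf" if (kind == "gene" and n in tf_ids) else kind
        net.add_node(n, out_kind, provenance)
    for e in pw.edges:
        net.add_edge(e.src, e.dst, e.etype, provenance)
    return net


def add_circuits(
    net: RegulatoryNetwork, circuits: list[Circuit], provenance: str
) -> RegulatoryNetwork:
    """Add linked circuits: TF->miRNA, TF->gene and miRNA->gene edges."""
    out = merge_networks([net])
    for c in circuits:
        out.add_node(c.tf_id, "tf", provenance)
        out.add_node(c.mirna_id, "mirna", provenance)
        if c.gene_id not in out.nodes:
            out.add_node(c.gene_id, "gene", provenance)
        else:
            out.nodes[c.gene_id]["provenance"].add(provenance)
        if c.topology == "tf_master":
            out.add_edge(c.tf_id, c.mirna_id, "tf_mirna", provenance)
        out.add_edge(c.tf_id, c.gene_id, "tf_gene", provenance)
        out.add_edge(c.mirna_id, c.gene_id, "mirna_predicted", provenance)
        if c.topology == "mirna_master":
            out.add_edge(c.mirna_id, c.tf_id, "mirna_predicted", provenance)
    return out


def merge_networks(nets: list[RegulatoryNetwork]) -> RegulatoryNetwork:
    """Union of networks on node id and (src, dst, etype); provenance sets
    and fold-change slots are unioned.  Node kind conflicts (other than the
    gene/tf promotion) are errors."""
    out = RegulatoryNetwork()
    for net in nets:
        for nid in net.sorted_nodes():
            entry = net.nodes[nid]
            for prov in sorted(entry["provenance"]):
                out.add_node(nid, entry["kind"], prov)
            out.nodes[nid]["fc"].update(entry["fc"])
        for key in net.sorted_edges():
            src, dst, etype = key
            for prov in sorted(net.edges[key]["provenance"]):
                out.add_edge(src, dst, etype, prov)
    return out


def annotate_fold_changes(
    net: RegulatoryNetwork, fc_tables: dict[str, pd.Series]
) -> RegulatoryNetwork:
    """Attach one fold-change slot per comparison label; nodes absent from a
    table keep that slot absent (never imputed as zero)."""
    out = merge_networks([net])
    for comparison, table in sorted(fc_tables.items()):
        for nid in out.sorted_nodes():
            if nid in table.index:
                out.nodes[nid]["fc"][comparison] = float(table.loc[nid])
    return out


def network_summary(net: RegulatoryNetwork) -> dict:
    """Exact counts over stored elements."""
    per_etype: dict[str, int] = {}
    for (_, _, etype) in net.edges:
        per_etype[etype] = per_etype.get(etype, 0) + 1
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_mirnas": sum(1 for v in net.nodes.values() if v["kind"] == "mirna"),
        "n_tfs": sum(1 for v in net.nodes.values() if v["kind"] == "tf"),
        "n_genes": sum(1 for v in net.nodes.values() if v["kind"] == "gene"),
        "edges_by_type": dict(sorted(per_etype.items())),
    }


# ---------------------------------------------------------------------------
# serialization


def _to_json_obj(net: RegulatoryNetwork) -> dict:
    return {
        "nodes": [
            {
                "id": nid,
                "kind": net.nodes[nid]["kind"],
                "fc": {k: net.nodes[nid]["fc"][k] for k in sorted(net.nodes[nid]["fc"])},
                "provenance": sorted(net.nodes[nid]["provenance"]),
            }
            for nid in net.sorted_nodes()
        ],
        "edges": [
            {
                "src": src,
                "dst": dst,
                "etype": etype,
                "provenance": sorted(net.edges[(src, dst, etype)]["provenance"]),
            }
            for src, dst, etype in net.sorted_edges()
        ],
    }


def _from_json_obj(obj: dict) -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    for n in obj["nodes"]:
        for prov in n["provenance"]:
            net.add_node(n["id"], n["kind"], prov)
        net.nodes[n["id"]]["fc"] = {k: float(v) for k, v in n.get("fc", {}).items()}
    for e in obj["edges"]:
        for prov in e["provenance"]:
            net.add_edge(e["src"], e["dst"], e["etype"], prov)
    return net


def export_network(net: RegulatoryNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as ``graphml``, ``sif`` or ``json``.

    GraphML and JSON are lossless (import(export(net)) == net); SIF carries
    topology only with the edge type as the relation.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(_to_json_obj(net), indent=2, sort_keys=True) + "\n")
    elif fmt == "sif":
        path.write_text(
            "\n".join(f"{src}\t{etype}\t{dst}" for src, dst, etype in net.sorted_edges())
            + ("\n" if net.edges else "")
        )
    elif fmt == "graphml":
        # MultiDiGraph so parallel edges of different types survive
        mg = nx.MultiDiGraph()
        for nid in net.sorted_nodes():
            entry = net.nodes[nid]
            attrs = {"kind": entry["kind"], "provenance": "|".join(sorted(entry["provenance"]))}
            for comp, val in sorted(entry["fc"].items()):
                attrs[f"fc_{comp}"] = float(val)
            mg.add_node(nid, **attrs)
        for src, dst, etype in net.sorted_edges():
            mg.add_edge(
                src,
                dst,
                key=etype,
                etype=etype,
                provenance="|".join(sorted(net.edges[(src, dst, etype)]["provenance"])),
            )
        nx.write_graphml(mg, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path: str | Path, fmt: str | None = None) -> RegulatoryNetwork:
    """Read a network written by :func:`export_network` (json or graphml)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "graphml"
    if fmt == "json":
        return _from_json_obj(json.loads(path.read_text()))
    if fmt == "graphml":
        mg = nx.read_graphml(path, force_multigraph=True)
        net = RegulatoryNetwork()
        for nid, data in sorted(mg.nodes(data=True)):
            for prov in data.get("provenance", "").split("|"):
                if prov:
                    net.add_node(nid, data["kind"], prov)
            fc = {
                k[len("fc_"):]: float(v)
                for k, v in data.items()
                if k.startswith("fc_")
            }
            net.nodes[nid]["fc"] = fc
        for src, dst, _key, data in sorted(mg.edges(keys=True, data=True)):
            for prov in data.get("provenance", "").split("|"):
                if prov:
                    net.add_edge(src, dst, data["etype"], prov)
        return net
    raise ValueError(f"unknown format {fmt!r}")
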