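"""Chordal graph machinery: min-fill triangulation and clique trees.

The topological pathway tests fit Gaussian graphical models whose structure
is the moralized pathway graph.  Likelihood evaluation and path extraction
both rest on a chordal (triangulated) cover of that graph and a junction
(clique) tree over its maximal cliques satisfying the running intersection
property (RIP).  All tie-breaks are lexicographic so results are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = ["CliqueTree", "triangulate", "build_clique_tree", "is_chordal_peo"]


@dataclass
class CliqueTree:
    """Junction tree: maximal cliques of a chordal graph, spanning-tree edges
    and the separator (clique intersection) on each tree edge.

    For a disconnected input the structure is a forest joined into a tree by
    zero-weight edges whose separators are empty; path enumeration treats
    empty-separator edges as component boundaries.
    """

    cliques: list[frozenset] = field(default_factory=list)
    tree_edges: list[tuple[int, int]] = field(default_factory=list)
    separators: list[frozenset] = field(default_factory=list)

    @property
    def n_cliques(self) -> int:
        return len(self.cliques)

    def nodes(self) -> set:
        out: set = set()
        for c in self.cliques:
            out |= c
        return out

    def component_edges(self) -> list[tuple[int, int]]:
        """Tree edges with nonempty separators (edges within one connected
        component of the underlying graph)."""
        return [e for e, s in zip(self.tree_edges, self.separators) if s]

    def check_rip(self) -> bool:
        """Running intersection property: for every pair of cliques, their
        intersection is contained in every clique on the tree path between
        them.  Exhaustive check, O(k^3)."""
        g = nx.Graph(self.tree_edges)
        g.add_nodes_from(range(len(self.cliques)))
        for i, j in combinations(range(len(self.cliques)), 2):
            inter = self.cliques[i] & self.cliques[j]
            if not inter:
                continue
            path = nx.shortest_path(g, i, j)
            for k in path:
                if not inter <= self.cliques[k]:
                    return False
        return True


def triangulate(g: nx.Graph) -> nx.Graph:
    """Chordal cover of ``g`` via min-fill elimination.

    At each step the node requiring the fewest fill edges among its not-yet
    eliminated neighbours is eliminated (ties broken by lexicographically
    smallest node id); its remaining neighbourhood is completed.  The output
    contains all original edges plus the fill edges.  Disconnected inputs are
    handled transparently (fill never crosses components).
    """
    h = g.copy()  # working graph, nodes removed as eliminated
    out = g.copy()
    while h.number_of_nodes() > 0:
        best = None
        best_key = None
        for v in h.nodes:
            nbrs = list(h.neighbors(v))
            fill = sum(
                0 if h.has_edge(a, b) else 1 for a, b in combinations(nbrs, 2)
            )
            key = (fill, str(v))
            if best_key is None or key < best_key:
                best, best_key = v, key
        nbrs = list(h.neighbors(best))
        for a, b in combinations(nbrs, 2):
            if not h.has_edge(a, b):
                h.add_edge(a, b)
                out.add_edge(a, b)
        h.remove_node(best)
    return out


def _mcs_peo(g: nx.Graph) -> list:
    """Maximum cardinality search: returns a perfect elimination ordering in
    reverse (visit order); lexicographic tie-break on node id."""
    weights = {v: 0 for v in g.nodes}
    order: list = []
    for _ in range(g.number_of_nodes()):
        # deterministic: highest weight, then smallest id
        best_w = max(weights.values())
        v = min((u for u, w in weights.items() if w == best_w), key=str)
        order.append(v)
        del weights[v]
        for u in g.neighbors(v):
            if u in weights:
                weights[u] += 1
    return order


def is_chordal_peo(g: nx.Graph, order: list) -> bool:
    """Check that the reverse of an MCS visit order is a perfect elimination
    ordering — true iff the graph is chordal."""
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        earlier = [u for u in g.neighbors(v) if pos[u] < pos[v]]
        if earlier:
            last = max(earlier, key=lambda u: pos[u])
            for u in earlier:
                if u != last and not g.has_edge(u, last):
                    return False
    return True


def build_clique_tree(chordal: nx.Graph) -> CliqueTree:
    """Clique tree of a chordal graph via maximum-weight spanning tree over
    clique intersection sizes (Kruskal, deterministic tie-break by sorted
    clique labels).  Raises on non-chordal input.

    RIP holds by the standard junction-tree theorem for any maximum-weight
    spanning tree of the clique intersection graph of a chordal graph.
    """
    if chordal.number_of_nodes() == 0:
        return CliqueTree()
    order = _mcs_peo(chordal)
    if not is_chordal_peo(chordal, order):
        raise ValueError("input graph is not chordal")

    # maximal cliques from the MCS order: v + already-visited neighbours,
    # keeping only the maximal candidates
    pos = {v: i for i, v in enumerate(order)}
    candidates: list[frozenset] = []
    for v in order:
        c = frozenset([v] + [u for u in chordal.neighbors(v) if pos[u] < pos[v]])
        candidates.append(c)
    cliques = [c for c in candidates if not any(c < d for d in candidates)]
    cliques = sorted(set(cliques), key=lambda c: sorted(map(str, c)))

    if len(cliques) == 1:
        return CliqueTree(cliques, [], [])

    labels = [tuple(sorted(map(str, c))) for c in cliques]
    pairs = sorted(
        combinations(range(len(cliques)), 2),
        key=lambda ij: (-len(cliques[ij[0]] & cliques[ij[1]]), labels[ij[0]], labels[ij[1]]),
    )
    # Kruskal
    parent = list(range(len(cliques)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges: list[tuple[int, int]] = []
    separators: list[frozenset] = []
    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree_edges.append((i, j))
            separators.append(cliques[i] & cliques[j])
        if len(tree_edges) == len(cliques) - 1:
            break
    return CliqueTree(cliques, tree_edges, separators)
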