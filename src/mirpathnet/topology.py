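"""Topological pathway analysis on Gaussian graphical models.

Each pathway is tested for differential behaviour between two sample classes
with two complementary permutation statistics computed under the GGM the
(moralized, triangulated) pathway graph defines:

* a *variance* statistic — the log-likelihood ratio of class-specific GGM
  fits against a pooled fit, sensitive to changes in the strength of the
  relations along the pathway;
* a *mean* statistic — a Hotelling-type quadratic form of the class mean
  difference weighted by the pooled GGM concentration, sensitive to
  coordinated expression shifts.

Null distributions come from permuting class labels; the same permutation
stream drives both statistics and the clique-level statistics, and p-values
use the add-one estimator p = (1 + #{perm >= obs}) / (1 + n_perm).

Within significant pathways, paths (sequences of adjacent cliques between
leaf cliques of the clique tree) are scored by the mean over their cliques
of -log10 of the smaller clique p-value.  The union of the top-scoring paths
across significant pathways forms the meta-pathway, which is re-analyzed;
paths in the upper quartile of the final score distribution are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chordal import CliqueTree, build_clique_tree, triangulate
from .expression import ExpressionMatrix
from .pathways import PathwayEdge, PathwayGraph, moral_graph
from .targets import bh_fdr

__all__ = [
    "PathwayTest",
    "PathResult",
    "pathway_tests",
    "clique_tests",
    "adjust_pathway_qvalues",
    "enumerate_clique_paths",
    "score_path",
    "scored_paths_for_pathway",
    "select_meta_pathway",
    "final_path_selection",
    "analyze_pathway",
]


@dataclass
class PathwayTest:
    """Whole-pathway permutation test result."""

    pathway_id: str
    p_mean: float
    p_var: float
    q_mean: float | None = None
    q_var: float | None = None
    significant: bool | None = None


@dataclass
class PathResult:
    """A clique-tree path: consecutive cliques are adjacent in the tree."""

    clique_indices: tuple[int, ...]
    nodes: frozenset
    score: float | None = None
    rank: int | None = None
    pathway_id: str | None = None

    @property
    def label(self) -> str:
        return "-".join(map(str, self.clique_indices))


# ---------------------------------------------------------------------------
# permutation engine


def _restrict_pathway(pw: PathwayGraph, keep: set[str]) -> PathwayGraph:
    nodes = {n: k for n, k in pw.nodes.items() if n in keep}
    edges = [e for e in pw.edges if e.src in nodes and e.dst in nodes]
    return PathwayGraph(pw.pathway_id, pw.name, nodes, edges)


def _expression_submatrix(
    mat: ExpressionMatrix, node_ids: list[str], class_a: str, class_b: str
):
    """Data matrix (samples x nodes) for the two classes, plus the class-a
    membership mask.  Samples keep annotation order within each class."""
    ann = mat.annotation
    samples_a = [s for s in ann.samples_in(class_a) if s in set(mat.sample_ids)]
    samples_b = [s for s in ann.samples_in(class_b) if s in set(mat.sample_ids)]
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("need at least 3 samples per class")
    samples = samples_a + samples_b
    x = mat.values.loc[node_ids, samples].to_numpy().T  # samples x nodes
    mask_a = np.zeros(len(samples), dtype=bool)
    mask_a[: len(samples_a)] = True
    return x, mask_a


def _batched_class_moments(x: np.ndarray, masks: np.ndarray):
    """Class means and MLE covariances for a batch of label assignments.

    x: n x p data; masks: K x n boolean (True = class a).  Returns
    (mean_a, mean_b, s_a, s_b, s_pooled) with leading batch dimension K.
    """
    n, p = x.shape
    m = masks.astype(float)
    n_a = m[0].sum()
    n_b = n - n_a
    mean_a = (m @ x) / n_a
    mean_b = ((1.0 - m) @ x) / n_b
    raw_a = np.einsum("kn,ni,nj->kij", m, x, x, optimize=True)
    raw_all = x.T @ x
    raw_b = raw_all[None, :, :] - raw_a
    s_a = raw_a / n_a - np.einsum("ki,kj->kij", mean_a, mean_a)
    s_b = raw_b / n_b - np.einsum("ki,kj->kij", mean_b, mean_b)
    s_pooled = (n_a * s_a + n_b * s_b) / n
    return mean_a, mean_b, s_a, s_b, s_pooled


def _batched_logdet(s: np.ndarray, subsets: list[list[int]]) -> np.ndarray:
    """Sum over index subsets of log det of the corresponding submatrices of
    each batched matrix; raises if any submatrix is not positive definite."""
    total = np.zeros(s.shape[0])
    for sub in subsets:
        block = s[np.ix_(range(s.shape[0]), sub, sub)]
        sign, ld = np.linalg.slogdet(block)
        if (sign <= 0).any():
            raise ValueError("degenerate covariance on a clique/separator")
        total += ld
    return total


def _batched_quadform(s: np.ndarray, d: np.ndarray, subsets: list[list[int]]) -> np.ndarray:
    """Sum over index subsets of d_sub' inv(S_sub) d_sub, batched."""
    total = np.zeros(s.shape[0])
    for sub in subsets:
        block = s[np.ix_(range(s.shape[0]), sub, sub)]
        rhs = d[:, sub]
        sol = np.linalg.solve(block, rhs[:, :, None])[:, :, 0]
        total += np.einsum("ki,ki->k", rhs, sol)
    return total


@dataclass(frozen=True)
class _Model:
    """A decomposable model over column indices: clique index lists and
    (possibly empty) separator index lists."""

    cliques: tuple[tuple[int, ...], ...]
    separators: tuple[tuple[int, ...], ...]


def _permutation_mean_var(
    x: np.ndarray,
    mask_a: np.ndarray,
    models: list[_Model],
    n_perm: int,
    seed: int,
):
    """Observed and permutation-null mean/variance statistics for a list of
    decomposable models sharing one data matrix and one permutation stream.

    Returns a list of (p_mean, p_var, t_mean_obs, t_var_obs) per model.
    """
    n = x.shape[0]
    n_a = int(mask_a.sum())
    n_b = n - n_a
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm + 1, n), dtype=bool)
    masks[0] = mask_a
    for k in range(1, n_perm + 1):
        perm = rng.permutation(n)
        masks[k, perm[:n_a]] = True

    mean_a, mean_b, s_a, s_b, s_p = _batched_class_moments(x, masks)
    d = mean_a - mean_b
    out = []
    for model in models:
        cl = [list(c) for c in model.cliques]
        sp = [list(s) for s in model.separators if s]
        ld_p = _batched_logdet(s_p, cl) - (_batched_logdet(s_p, sp) if sp else 0.0)
        ld_a = _batched_logdet(s_a, cl) - (_batched_logdet(s_a, sp) if sp else 0.0)
        ld_b = _batched_logdet(s_b, cl) - (_batched_logdet(s_b, sp) if sp else 0.0)
        t_var = n * ld_p - n_a * ld_a - n_b * ld_b
        quad = _batched_quadform(s_p, d, cl) - (
            _batched_quadform(s_p, d, sp) if sp else 0.0
        )
        t_mean = (n_a * n_b / n) * quad
        p_mean = (1 + np.sum(t_mean[1:] >= t_mean[0])) / (1 + n_perm)
        p_var = (1 + np.sum(t_var[1:] >= t_var[0])) / (1 + n_perm)
        out.append((float(p_mean), float(p_var), float(t_mean[0]), float(t_var[0])))
    return out


def _decompose(pw: PathwayGraph, mat: ExpressionMatrix):
    """Moralize, triangulate and build the clique tree for the pathway nodes
    present in the expression matrix.  Returns (node order, clique tree)."""
    present = set(pw.nodes) & set(mat.feature_ids)
    absent = set(pw.nodes) - present
    if absent:
        warnings.warn(
            f"{pw.pathway_id}: dropping {len(absent)} node(s) absent from the "
            f"expression matrix: {sorted(absent)[:5]}...",
            stacklevel=3,
        )
    restricted = _restrict_pathway(pw, present)
    chordal = triangulate(moral_graph(restricted))
    ct = build_clique_tree(chordal)
    nodes = sorted(present, key=str)
    return nodes, ct


def _model_from_clique_tree(ct: CliqueTree, nodes: list[str]) -> _Model:
    idx = {v: i for i, v in enumerate(nodes)}
    cliques = tuple(tuple(sorted(idx[v] for v in c)) for c in ct.cliques)
    seps = tuple(tuple(sorted(idx[v] for v in s)) for s in ct.separators)
    return _Model(cliques, seps)


# ---------------------------------------------------------------------------
# public operations


def pathway_tests(
    mat: ExpressionMatrix,
    pw: PathwayGraph,
    class_a: str,
    class_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> PathwayTest:
    """Whole-pathway permutation mean and variance tests (p-values only;
    q-values are attached by :func:`adjust_pathway_qvalues` across a pathway
    collection)."""
    nodes, ct = _decompose(pw, mat)
    if not nodes:
        raise ValueError(f"{pw.pathway_id}: no pathway node present in the matrix")
    x, mask_a = _expression_submatrix(mat, nodes, class_a, class_b)
    model = _model_from_clique_tree(ct, nodes)
    (p_mean, p_var, _, _), = _permutation_mean_var(x, mask_a, [model], n_perm, seed)
    return PathwayTest(pw.pathway_id, p_mean=p_mean, p_var=p_var)


def clique_tests(
    mat: ExpressionMatrix,
    clique_tree: CliqueTree,
    class_a: str,
    class_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    nodes: list[str] | None = None,
) -> list[tuple[float, float]]:
    """Per-clique (p_mean, p_var): both statistics on each clique's node
    subset under the saturated (complete) model, same permutation scheme as
    the pathway-level test."""
    if nodes is None:
        nodes = sorted(clique_tree.nodes(), key=str)
    x, mask_a = _expression_submatrix(mat, nodes, class_a, class_b)
    idx = {v: i for i, v in enumerate(nodes)}
    models = [
        _Model((tuple(sorted(idx[v] for v in c)),), ()) for c in clique_tree.cliques
    ]
    res = _permutation_mean_var(x, mask_a, models, n_perm, seed)
    return [(pm, pv) for pm, pv, _, _ in res]


def adjust_pathway_qvalues(
    tests: list[PathwayTest], q_max: float = 0.1, mode: str = "either"
) -> list[PathwayTest]:
    """BH-adjust the mean-test and variance-test p-value families separately
    across pathways; a pathway is significant when min(q_mean, q_var) <= q_max
    (mode "either", default) or max(...) <= q_max (mode "both")."""
    if not tests:
        raise ValueError("no pathway tests to adjust")
    q_mean = bh_fdr([t.p_mean for t in tests])
    q_var = bh_fdr([t.p_var for t in tests])
    out = []
    for t, qm, qv in zip(tests, q_mean, q_var):
        crit = min(qm, qv) if mode == "either" else max(qm, qv)
        out.append(
            replace(t, q_mean=float(qm), q_var=float(qv), significant=bool(crit <= q_max))
        )
    return out


def enumerate_clique_paths(ct: CliqueTree) -> list[PathResult]:
    """All simple paths between pairs of leaf cliques of the clique tree,
    per connected component (empty separators mark component boundaries).
    A single-clique tree (or isolated clique) yields its trivial path."""
    k = ct.n_cliques
    if k == 0:
        return []
    adj: dict[int, list[int]] = {i: [] for i in range(k)}
    for i, j in ct.component_edges():
        adj[i].append(j)
        adj[j].append(i)

    paths: list[PathResult] = []
    seen_components: set[int] = set()
    for start in range(k):
        if start in seen_components:
            continue
        # collect component by BFS
        comp = [start]
        seen = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        seen_components |= seen
        leaves = sorted(i for i in comp if len(adj[i]) <= 1)
        if len(comp) == 1:
            paths.append(
                PathResult((comp[0],), frozenset(ct.cliques[comp[0]]))
            )
            continue
        for a_i, a in enumerate(leaves):
            for b in leaves[a_i + 1:]:
                path = _tree_path(adj, a, b)
                nodes = frozenset().union(*(ct.cliques[i] for i in path))
                paths.append(PathResult(tuple(path), nodes))
    return paths


def _tree_path(adj: dict[int, list[int]], a: int, b: int) -> list[int]:
    """Unique simple path between two nodes of a tree (DFS)."""
    stack = [(a, [a])]
    while stack:
        u, path = stack.pop()
        if u == b:
            return path
        for v in adj[u]:
            if v not in path:
                stack.append((v, path + [v]))
    raise ValueError("no path between cliques (disconnected component)")


def score_path(path: PathResult, clique_results: list[tuple[float, float]]) -> float:
    """Mean over the path's cliques of -log10(min(p_mean, p_var)); larger
    scores mean stronger deregulation along the path."""
    vals = [
        -np.log10(min(clique_results[i][0], clique_results[i][1]))
        for i in path.clique_indices
    ]
    return float(np.mean(vals))


def scored_paths_for_pathway(
    ct: CliqueTree, clique_results: list[tuple[float, float]], pathway_id: str
) -> list[PathResult]:
    """Enumerate and score all leaf-pair paths of one pathway's clique tree."""
    paths = enumerate_clique_paths(ct)
    out = []
    for p in paths:
        out.append(replace(p, score=score_path(p, clique_results), pathway_id=pathway_id))
    out.sort(key=lambda p: (-p.score, p.pathway_id or "", p.label))
    for rank, p in enumerate(out, start=1):
        p.rank = rank
    return out


def select_meta_pathway(
    scored_paths: list[PathResult],
    augmented_graphs: dict[str, PathwayGraph],
    k: int = 10,
    meta_id: str = "meta",
) -> PathwayGraph:
    """Merge the top ``k`` paths (by score, across all significant pathways;
    ties broken by pathway id then path label) into the meta-pathway: the
    union of their node sets plus every edge of the augmented source graphs
    induced on that union.  Node provenance records the source pathway."""
    if not scored_paths:
        raise ValueError("no scored paths to merge")
    ranked = sorted(scored_paths, key=lambda p: (-p.score, p.pathway_id or "", p.label))
    top = ranked[:k]
    node_union: set[str] = set()
    for p in top:
        node_union |= p.nodes

    nodes: dict[str, str] = {}
    edges: dict[tuple[str, str, str], PathwayEdge] = {}
    for pid in sorted(augmented_graphs):
        g = augmented_graphs[pid]
        for n, kind in g.nodes.items():
            if n in node_union:
                nodes.setdefault(n, kind)
        for e in g.edges:
            if e.src in node_union and e.dst in node_union:
                key = (e.src, e.dst, e.etype)
                if key not in edges:
                    edges[key] = PathwayEdge(e.src, e.dst, e.directed, e.etype, pid)
    return PathwayGraph(meta_id, "meta-pathway", nodes, list(edges.values()))


def final_path_selection(
    meta: PathwayGraph,
    mat: ExpressionMatrix,
    class_a: str,
    class_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PathResult]:
    """Re-analyze the meta-pathway (moralize -> triangulate -> clique tree ->
    clique tests -> path scoring) and keep the paths whose score reaches the
    75th percentile (linear-interpolation quantile) of the score
    distribution; ties at the threshold are kept."""
    if not meta.nodes:
        raise ValueError("meta-pathway is empty")
    nodes, ct = _decompose(meta, mat)
    results = clique_tests(mat, ct, class_a, class_b, n_perm=n_perm, seed=seed, nodes=nodes)
    scored = scored_paths_for_pathway(ct, results, meta.pathway_id)
    if not scored:
        return []
    threshold = float(np.quantile([p.score for p in scored], 0.75))
    return [p for p in scored if p.score >= threshold]


def analyze_pathway(
    mat: ExpressionMatrix,
    pw: PathwayGraph,
    class_a: str,
    class_b: str,
    n_perm: int = 1000,
    seed: int = 0,
):
    """One-shot analysis of a pathway: whole-pathway test plus clique-level
    results and scored paths, sharing a single permutation stream.

    Returns (PathwayTest, CliqueTree, clique_results, scored_paths).
    """
    nodes, ct = _decompose(pw, mat)
    if not nodes:
        raise ValueError(f"{pw.pathway_id}: no pathway node present in the matrix")
    x, mask_a = _expression_submatrix(mat, nodes, class_a, class_b)
    idx = {v: i for i, v in enumerate(nodes)}
    pathway_model = _model_from_clique_tree(ct, nodes)
    clique_models = [
        _Model((tuple(sorted(idx[v] for v in c)),), ()) for c in ct.cliques
    ]
    res = _permutation_mean_var(
        x, mask_a, [pathway_model] + clique_models, n_perm, seed
    )
    p_mean, p_var, _, _ = res[0]
    clique_results = [(pm, pv) for pm, pv, _, _ in res[1:]]
    test = PathwayTest(pw.pathway_id, p_mean=p_mean, p_var=p_var)
    scored = scored_paths_for_pathway(ct, clique_results, pw.pathway_id)
    return test, ct, clique_results, scored
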