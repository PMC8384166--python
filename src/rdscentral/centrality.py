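"""Node centrality on recruitment trees.

Three measures are computed per connected component:

* **closeness** ``c(v) = N / sum_y d(y, v)`` with ``N`` the component size and
  ``d`` the unweighted shortest-path distance (unique in a tree).  The
  conventional ``N - 1`` numerator is available via ``numerator="N-1"``; the
  two differ by a constant factor within a component, so rankings agree.
* **betweenness** ``b(v) = sum_{s != v != t} sigma_st(v) / sigma_st``.  In a
  tree every pair of nodes has exactly one shortest path (``sigma_st = 1``),
  so b(v) is simply the number of unordered node pairs whose path passes
  through v.  No normalization is applied; only within-component rankings are
  consumed downstream.  Leaves always score 0.
* **eigenvector** — the Perron eigenvector of the component adjacency matrix,
  normalized to unit Euclidean length.  Trees are bipartite, so the adjacency
  spectrum is symmetric (+/- lambda_1) and plain power iteration oscillates;
  iterating on ``A + I`` shifts the spectrum without changing eigenvectors
  and converges to the principal eigenvector.

Components of size 1 receive a score of 0 for every measure; they are never
selected downstream.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

from rdscentral.errors import ConvergenceError

MEASURES = ("betweenness", "closeness", "eigenvector")


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("component is empty")
    if not nx.is_connected(g):
        raise ValueError("input must be a single connected component")


def closeness(component: nx.Graph, numerator: str = "N") -> dict:
    """Closeness centrality ``c(v) = N / sum_y d(y, v)`` per node.

    ``numerator="N-1"`` selects the conventional normalization instead.
    A size-1 component scores 0 (there are no distances to sum).
    """
    if numerator not in ("N", "N-1"):
        raise ValueError("numerator must be 'N' or 'N-1'")
    n = component.number_of_nodes()
    if n == 1:
        return {v: 0.0 for v in component}
    _require_connected(component)
    num = float(n if numerator == "N" else n - 1)
    scores = {}
    for v in component:
        total = sum(nx.single_source_shortest_path_length(component, v).values())
        scores[v] = num / total
    return scores


def betweenness(component: nx.Graph) -> dict:
    """Unnormalized betweenness on a tree: unordered pairs routed through v.

    Computed from subtree sizes: deleting v splits the tree into parts of
    sizes s_1..s_k; the pairs through v are ``sum_{i<j} s_i * s_j``.
    """
    n = component.number_of_nodes()
    if n == 1:
        return {v: 0.0 for v in component}
    _require_connected(component)
    if component.number_of_edges() != n - 1:
        raise ValueError("betweenness expects a tree component")

    root = min(component)
    order, parent_of = [], {root: None}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        order.append(u)
        for w in component[u]:
            if w not in parent_of:
                parent_of[w] = u
                queue.append(w)

    subtree = {v: 1 for v in component}
    for u in reversed(order):
        if parent_of[u] is not None:
            subtree[parent_of[u]] += subtree[u]

    scores = {}
    for v in component:
        parts = [subtree[w] for w in component[v] if parent_of.get(w) == v]
        if parent_of[v] is not None:
            parts.append(n - subtree[v])
        s = n - 1  # == sum(parts)
        scores[v] = float(s * s - sum(p * p for p in parts)) / 2.0
    return scores


def eigenvector(
    component: nx.Graph, tol: float = 1e-10, max_iter: int = 10000
) -> dict:
    """Principal (Perron) eigenvector of the adjacency matrix, unit L2 norm.

    Power iteration runs on ``A + I`` to break the bipartite +/-lambda tie;
    convergence is declared when successive iterates differ by less than
    ``tol`` in max-norm.
    """
    n = component.number_of_nodes()
    if n == 1:
        return {v: 0.0 for v in component}
    _require_connected(component)
    nodes = sorted(component)
    a = nx.to_numpy_array(component, nodelist=nodes)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            return dict(zip(nodes, y))
        x = y
    raise ConvergenceError(
        f"power iteration did not converge within {max_iter} iterations "
        f"for component rooted at {nodes[0]!r}"
    )


def component_scores(
    component: nx.Graph,
    measures=MEASURES,
    closeness_numerator: str = "N",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> dict[str, dict]:
    """All requested measures for one component, as measure -> node -> score."""
    out = {}
    for measure in measures:
        if measure == "betweenness":
            out[measure] = betweenness(component)
        elif measure == "closeness":
            out[measure] = closeness(component, numerator=closeness_numerator)
        elif measure == "eigenvector":
            out[measure] = eigenvector(component, tol=tol, max_iter=max_iter)
        else:
            raise ValueError(f"unknown centrality measure {measure!r}")
    return out


def scores_table(forest, measures=MEASURES, closeness_numerator: str = "N") -> pd.DataFrame:
    """Long-format table of scores for every component of every city.

    Columns: city, component_id, node_id, measure, score.
    """
    rows = []
    for city in forest.cities:
        g = forest.graph(city)
        for comp in forest.components(city):
            cid = min(comp)
            sub = g.subgraph(comp)
            for measure, scores in component_scores(
                sub, measures=measures, closeness_numerator=closeness_numerator
            ).items():
                for node in sorted(scores):
                    rows.append((city, cid, node, measure, scores[node]))
    return pd.DataFrame(
        rows, columns=["city", "component_id", "node_id", "measure", "score"]
    )
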