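"""Markov clustering of weighted protein-interaction graphs.

Edges below a minimum interaction score (default 0.40) are dropped,
self-loops of weight 1 are added, the weight matrix is column-normalized
and the standard expansion/inflation iteration (default inflation 1.7)
is run to convergence; clusters are the connected components of the
nonzero structure of the converged matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import Edge

logger = logging.getLogger(__name__)

MIN_SCORE = 0.40
INFLATION = 1.7


@dataclass
class InteractionGraph:
    """Ordered node list with a symmetric [0, 1] weight matrix."""

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node list")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix is not symmetric")
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w


@dataclass
class ClusterAssignment:
    """Node -> dense 1-based cluster id, plus a convergence flag."""

    assignment: dict[str, int]
    converged: bool = True
    n_iterations: int = 0

    @property
    def n_clusters(self) -> int:
        return max(self.assignment.values(), default=0)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return out


def build_graph(edges: list[Edge], nodes: list[str], min_score: float = MIN_SCORE) -> InteractionGraph:
    """Build the thresholded graph; edges with score < min_score drop.

    Nodes without a surviving edge are retained as isolated nodes; an
    edge endpoint missing from *nodes* is an error.
    """
    index = {n: i for i, n in enumerate(nodes)}
    if len(index) != len(nodes):
        raise ValueError("duplicate node identifiers")
    w = np.zeros((len(nodes), len(nodes)))
    n_dropped = 0
    for e in edges:
        if e.node_a not in index or e.node_b not in index:
            raise ValueError(f"edge endpoint not in node list: ({e.node_a}, {e.node_b})")
        if e.score < min_score:
            n_dropped += 1
            continue
        i, j = index[e.node_a], index[e.node_b]
        w[i, j] = w[j, i] = e.score
    if n_dropped:
        logger.info("build_graph: dropped %d edges below score %.2f", n_dropped, min_score)
    return InteractionGraph(list(nodes), w)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(
    graph: InteractionGraph,
    inflation: float = INFLATION,
    expansion: int = 2,
    self_loop_weight: float = 1.0,
    prune_epsilon: float = 1e-5,
    max_iter: int = 100,
    conv_tol: float = 1e-6,
    trace: list | None = None,
) -> ClusterAssignment:
    """Standard Markov clustering of an :class:`InteractionGraph`.

    When *trace* is a list, a copy of the stochastic matrix is appended
    after every inflation/renormalization step (for inspection/testing).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = len(graph.nodes)
    if n == 0:
        return ClusterAssignment({}, converged=True, n_iterations=0)
    m = graph.weights.copy()
    np.fill_diagonal(m, self_loop_weight)
    m = _normalize_columns(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = _normalize_columns(m**inflation)
        m[m < prune_epsilon] = 0.0
        m = _normalize_columns(m)
        if trace is not None:
            trace.append(m.copy())
        if np.max(np.abs(m - prev)) < conv_tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)
    structure = csr_matrix((m + m.T) > 0)
    _, labels = connected_components(structure, directed=False)
    # relabel to dense 1-based ids in order of first appearance
    relabel: dict[int, int] = {}
    assignment = {}
    for node, lab in zip(graph.nodes, labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignment[node] = relabel[lab]
    return ClusterAssignment(assignment, converged=converged, n_iterations=it)


def write_clusters(result: ClusterAssignment, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"node": n, "cluster": c} for n, c in result.assignment.items()],
        columns=["node", "cluster"],
    ).to_csv(path, sep="\t", index=False)
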