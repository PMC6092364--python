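"""PageRank centrality on weighted directed reaction graphs.

The random walk follows outgoing edge weights with probability ``lam`` and
teleports uniformly with probability ``1 - lam`` (dangling nodes teleport
with probability one), making the chain ergodic on arbitrary directed
graphs. The PageRank vector is the stationary distribution, computed by
power iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .graph_construction import ReactionGraph

__all__ = [
    "PageRankResult",
    "ConvergenceError",
    "transition_matrix",
    "pagerank",
    "pathway_pagerank",
]

DEFAULT_LAMBDA = 0.85


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested residual."""


@dataclass
class PageRankResult:
    scores: dict[tuple[str, str], float]
    percentiles: dict[tuple[str, str], float]
    lam: float

    def score_array(self, node_ids) -> np.ndarray:
        return np.array([self.scores[node] for node in node_ids])


def transition_matrix(
    graph: ReactionGraph | np.ndarray, lam: float = DEFAULT_LAMBDA
) -> np.ndarray:
    """Row-stochastic teleported transition matrix.

    ``B = lam * M + (1/N) [(1-lam) I + lam diag(a)] 1 1^T`` where ``M`` is the
    out-strength-normalised walk matrix (dangling out-strengths set to 1, so
    their rows of ``M`` are zero and the indicator ``a`` routes them fully
    into teleportation). Every row of ``B`` sums to one.
    """
    W = graph.W if isinstance(graph, ReactionGraph) else np.asarray(graph, float)
    if (W < 0).any():
        raise ValueError("negative edge weights")
    N = W.shape[0]
    k_out = W.sum(axis=1)
    dangling = k_out == 0
    k_safe = np.where(dangling, 1.0, k_out)
    M = W / k_safe[:, None]
    restart = ((1.0 - lam) + lam * dangling.astype(float)) / N
    return lam * M + restart[:, None] * np.ones((1, N))


def stationary_distribution(
    B: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000
) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix by power iteration."""
    N = B.shape[0]
    pi = np.full(N, 1.0 / N)
    for _ in range(max_iter):
        nxt = pi @ B
        nxt /= nxt.sum()
        residual = np.abs(nxt - pi).sum()
        pi = nxt
        if residual < tol:
            return pi
    raise ConvergenceError(
        f"power iteration: residual {residual:.3g} > tol {tol:.3g} "
        f"after {max_iter} iterations"
    )


def pagerank(
    graph: ReactionGraph,
    lam: float = DEFAULT_LAMBDA,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> PageRankResult:
    """PageRank scores and average-rank percentiles for every graph node.

    Reversible reactions contribute two direction nodes, each with its own
    score. Scores sum to one; percentiles are monotone in scores with ties
    sharing their average rank.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    B = transition_matrix(graph, lam)
    pi = stationary_distribution(B, tol=tol, max_iter=max_iter)
    ranks = scipy.stats.rankdata(pi, method="average")
    percentiles = 100.0 * ranks / len(pi)
    return PageRankResult(
        scores=dict(zip(graph.node_ids, pi.tolist())),
        percentiles=dict(zip(graph.node_ids, percentiles.tolist())),
        lam=lam,
    )


def pathway_pagerank(
    result: PageRankResult, subsystem: dict[str, str]
) -> dict[str, float]:
    """Cumulative PageRank per pathway (sums to 1 over pathways).

    Nodes whose reaction has no subsystem label are pooled under
    ``"unassigned"``.
    """
    totals: dict[str, float] = {}
    for (rid, _direction), score in result.scores.items():
        pathway = subsystem.get(rid, "unassigned")
        totals[pathway] = totals.get(pathway, 0.0) + score
    return totals
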