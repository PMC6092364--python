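"""Flux-based reaction graphs from stoichiometry and balanced fluxes.

Five constructions over a common unfolded representation in which every
reversible reaction contributes a forward and a reverse direction node:

* **RAG** — reaction adjacency graph ``A = S_hat^T S_hat`` on the original
  reactions (undirected; weights count shared metabolites; self-loops count
  the metabolites of each reaction).
* **NFG** — normalised flow graph: directed, with ``D_ij`` the probability
  that a metabolite molecule chosen uniformly at random is produced by
  direction node ``i`` and consumed by direction node ``j``,
  ``D = (1/n) (W+^† S+)^T (W-^† S-)``.
* **MFG** — mass flow graph: directed, edge weights in mmol/gDW/h obtained by
  allocating each metabolite's production flux to its consumers in proportion
  to their consumption flux, ``M = (S+ V*)^T J^† (S- V*)``.
* **Competition / synergy graphs** — undirected probabilistic graphs of
  shared-substrate and shared-product relationships,
  ``Dc = (1/n) S-^T (W-^†)^2 S-`` and ``Ds = (1/n) S+^T (W+^†)^2 S+``.

``†`` is the Moore–Penrose pseudoinverse of a diagonal matrix: reciprocal of
the non-zero entries, zero elsewhere. Metabolites that are never produced or
never consumed therefore contribute nothing instead of breaking the
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flux_balance import FluxSolution, SteadyStateError
from .model_io import MetabolicModel

__all__ = [
    "UnfoldedSystem",
    "ReactionGraph",
    "unfold",
    "build_rag",
    "build_nfg",
    "pairwise_flow",
    "build_mfg",
    "build_competition_graph",
    "build_synergy_graph",
    "average_graphs",
    "write_graphml",
    "read_graphml",
    "write_edgelist",
]

# weights smaller than this are treated as absent edges (affects edge counts)
EDGE_THRESHOLD = 1e-15
# MFG direction nodes with |flux| below this fraction of max|v| are pruned
FLUX_PRUNE_REL = 1e-9


@dataclass
class UnfoldedSystem:
    """Unfolded stoichiometry ``S2m = [S, -S diag(r)]`` with its splits.

    ``node_ids`` lists all ``2m`` direction columns ``(reaction_id, "fwd"|
    "rev")``; reverse columns of irreversible reactions are identically zero
    and are excluded from graph node sets (``active`` mask).
    """

    node_ids: list[tuple[str, str]]
    S2m: np.ndarray
    Splus: np.ndarray
    Sminus: np.ndarray
    wplus: np.ndarray
    wminus: np.ndarray
    active: np.ndarray  # bool mask over the 2m columns


def unfold(model: MetabolicModel) -> UnfoldedSystem:
    """Unfold reactions into forward/reverse columns and split by sign."""
    S = model.S
    S2m = np.hstack([S, -S * model.r[np.newaxis, :]])
    Splus = (np.abs(S2m) + S2m) / 2.0
    Sminus = (np.abs(S2m) - S2m) / 2.0
    node_ids = [(rid, "fwd") for rid in model.reaction_ids] + \
               [(rid, "rev") for rid in model.reaction_ids]
    active = np.concatenate([np.ones(model.m, bool), model.r.astype(bool)])
    return UnfoldedSystem(
        node_ids=node_ids, S2m=S2m, Splus=Splus, Sminus=Sminus,
        wplus=Splus.sum(axis=1), wminus=Sminus.sum(axis=1), active=active,
    )


@dataclass
class ReactionGraph:
    """Weighted reaction(-direction) graph with declared weight semantics."""

    node_ids: list[tuple[str, str]]
    W: np.ndarray
    directed: bool
    weight_semantics: str  # shared_metabolite_count | probability | flux_mmol_gDW_h

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        N = len(self.node_ids)
        if self.W.shape != (N, N):
            raise ValueError(f"W has shape {self.W.shape}, expected ({N}, {N})")
        if (self.W < 0).any():
            raise ValueError("negative edge weights")
        if not self.directed and not np.allclose(self.W, self.W.T):
            raise ValueError("undirected graph with asymmetric W")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def n_edges(self, include_self_loops: bool = True) -> int:
        """Count stored edges: directed ordered pairs, or unordered pairs
        plus self-loops for undirected graphs."""
        present = self.W > 0
        if self.directed:
            count = int(present.sum())
            if not include_self_loops:
                count -= int(np.diag(present).sum())
            return count
        count = int(np.triu(present, 1).sum())
        if include_self_loops:
            count += int(np.diag(present).sum())
        return count

    def total_weight(self) -> float:
        return float(self.W.sum())

    def node_index(self, rid: str, direction: str = "fwd") -> int:
        return self.node_ids.index((rid, direction))

    def to_networkx(self, subsystem: dict[str, str] | None = None):
        import networkx as nx

        G = nx.DiGraph() if self.directed else nx.Graph()
        for rid, direction in self.node_ids:
            attrs = {"reaction_id": rid, "direction": direction}
            if subsystem is not None:
                attrs["subsystem"] = subsystem.get(rid, "unassigned")
            G.add_node(f"{rid}[{direction}]" if direction else rid, **attrs)
        rows, cols = np.nonzero(self.W)
        names = [f"{rid}[{d}]" if d else rid for rid, d in self.node_ids]
        for i, j in zip(rows, cols):
            if not self.directed and j < i:
                continue
            G.add_edge(names[i], names[j], weight=float(self.W[i, j]))
        G.graph["directed"] = self.directed
        G.graph["weight_semantics"] = self.weight_semantics
        return G


def _threshold(W: np.ndarray, threshold: float) -> np.ndarray:
    W = np.where(np.abs(W) < threshold, 0.0, W)
    return W


def build_rag(model: MetabolicModel) -> ReactionGraph:
    """Reaction adjacency graph on the ``m`` original reactions.

    ``A = S_hat^T S_hat`` with ``S_hat`` boolean; symmetric with integer
    weights, the diagonal counting the metabolites of each reaction.
    """
    Shat = (model.S != 0).astype(float)
    A = Shat.T @ Shat
    return ReactionGraph(
        node_ids=[(rid, "") for rid in model.reaction_ids],
        W=A, directed=False, weight_semantics="shared_metabolite_count",
    )


def _active_graph_nodes(sys: UnfoldedSystem):
    idx = np.flatnonzero(sys.active)
    return idx, [sys.node_ids[i] for i in idx]


def _diag_pinv(w: np.ndarray) -> np.ndarray:
    out = np.zeros_like(w)
    nz = w != 0
    out[nz] = 1.0 / w[nz]
    return out


def build_nfg(
    model: MetabolicModel, edge_threshold: float = EDGE_THRESHOLD
) -> ReactionGraph:
    """Normalised flow graph over active direction nodes.

    The weight sum equals (number of metabolites both produced and consumed)
    divided by ``n``; it is exactly 1 when every metabolite has at least one
    producer and one consumer among the unfolded columns.
    """
    sys = unfold(model)
    wp_inv = _diag_pinv(sys.wplus)
    wm_inv = _diag_pinv(sys.wminus)
    D = (sys.Splus * wp_inv[:, None]).T @ (sys.Sminus * wm_inv[:, None]) / model.n
    idx, nodes = _active_graph_nodes(sys)
    D = D[np.ix_(idx, idx)]
    return ReactionGraph(
        node_ids=nodes, W=_threshold(D, edge_threshold),
        directed=True, weight_semantics="probability",
    )


def pairwise_flow(
    k: int, i: int, j: int, sys: UnfoldedSystem, sol: FluxSolution
) -> float:
    """Flux of metabolite ``k`` from direction node ``i`` to node ``j``.

    The production flux of ``k`` by ``i`` is allocated to its consumers in
    proportion to their consumption flux:
    ``(s+_ki v_i) * (s-_kj v_j) / (sum_h s-_kh v_h)``, in mmol/gDW/h.
    Zero total consumption gives 0 (pseudoinverse convention).
    """
    v = sol.v2m
    total_consumption = float(sys.Sminus[k] @ v)
    if total_consumption == 0.0:
        return 0.0
    produced = sys.Splus[k, i] * v[i]
    consumed = sys.Sminus[k, j] * v[j]
    return float(produced * consumed / total_consumption)


def build_mfg(
    model: MetabolicModel,
    sol: FluxSolution,
    *,
    flux_prune_rel: float = FLUX_PRUNE_REL,
    edge_threshold: float = EDGE_THRESHOLD,
    balance_tol: float = 1e-6,
) -> ReactionGraph:
    """Mass flow graph ``M(v*) = (S+ V*)^T J^† (S- V*)`` for a balanced flux.

    Direction nodes whose flux is below ``flux_prune_rel * max|v|`` are
    removed (LP solvers return numerical dust, and zero-flux reactions carry
    no mass). Self-loops are retained: they are the flux of autocatalytic
    reactions whose products are also reactants.
    """
    if not sol.optimal or sol.v is None:
        raise ValueError(f"flux solution is not optimal (status={sol.status})")
    imbalance = np.abs(model.S @ sol.v)
    scale = max(1.0, float(np.max(np.abs(sol.v), initial=0.0)))
    worst = int(np.argmax(imbalance))
    if imbalance[worst] > balance_tol * scale:
        raise SteadyStateError(
            f"flux vector unbalanced: |S v| = {imbalance[worst]:.3g} at "
            f"metabolite {model.metabolite_ids[worst]!r}"
        )
    sys = unfold(model)
    v2m = sol.v2m
    keep = sys.active & (v2m > flux_prune_rel * scale)
    idx = np.flatnonzero(keep)
    Sp = sys.Splus[:, idx] * v2m[idx]        # S+ V*, restricted
    Sm = sys.Sminus[:, idx] * v2m[idx]       # S- V*, restricted
    j_inv = _diag_pinv(sys.Sminus @ v2m)     # consumption-side metabolite flux
    M = Sp.T @ (Sm * j_inv[:, None])
    return ReactionGraph(
        node_ids=[sys.node_ids[i] for i in idx],
        W=_threshold(M, edge_threshold),
        directed=True, weight_semantics="flux_mmol_gDW_h",
    )


def _consumption_probability_graph(
    model: MetabolicModel, production_side: bool, edge_threshold: float
) -> ReactionGraph:
    sys = unfold(model)
    X = sys.Splus if production_side else sys.Sminus
    w_inv = _diag_pinv(X.sum(axis=1))
    G = (X * w_inv[:, None]).T @ (X * w_inv[:, None]) / model.n
    idx, nodes = _active_graph_nodes(sys)
    G = G[np.ix_(idx, idx)]
    return ReactionGraph(
        node_ids=nodes, W=_threshold(G, edge_threshold),
        directed=False, weight_semantics="probability",
    )


def build_competition_graph(
    model: MetabolicModel, edge_threshold: float = EDGE_THRESHOLD
) -> ReactionGraph:
    """Probability that two direction nodes consume a randomly chosen
    metabolite molecule: ``Dc = (1/n) S-^T (W-^†)^2 S-`` (undirected)."""
    return _consumption_probability_graph(model, False, edge_threshold)


def build_synergy_graph(
    model: MetabolicModel, edge_threshold: float = EDGE_THRESHOLD
) -> ReactionGraph:
    """Probability that two direction nodes produce a randomly chosen
    metabolite molecule: ``Ds = (1/n) S+^T (W+^†)^2 S+`` (undirected)."""
    return _consumption_probability_graph(model, True, edge_threshold)


def average_graphs(graphs: list[ReactionGraph]) -> ReactionGraph:
    """Arithmetic mean of an ensemble of graphs over the union node set.

    A graph lacking a node/edge contributes weight 0 for it. All graphs must
    share weight semantics and directedness.
    """
    if not graphs:
        raise ValueError("empty graph ensemble")
    semantics = {g.weight_semantics for g in graphs}
    directed = {g.directed for g in graphs}
    if len(semantics) > 1 or len(directed) > 1:
        raise ValueError(f"mixed graph semantics: {semantics}, directed={directed}")
    union: list[tuple[str, str]] = []
    seen = set()
    for g in graphs:
        for node in g.node_ids:
            if node not in seen:
                seen.add(node)
                union.append(node)
    pos = {node: i for i, node in enumerate(union)}
    W = np.zeros((len(union), len(union)))
    for g in graphs:
        idx = np.array([pos[node] for node in g.node_ids])
        W[np.ix_(idx, idx)] += g.W
    W /= len(graphs)
    return ReactionGraph(
        node_ids=union, W=W, directed=directed.pop(),
        weight_semantics=semantics.pop(),
    )


# --- writers ----------------------------------------------------------------

def write_graphml(
    graph: ReactionGraph, path, subsystem: dict[str, str] | None = None
) -> None:
    """GraphML export with reaction_id/direction/subsystem node attributes."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(subsystem), str(path))


def read_graphml(path) -> ReactionGraph:
    """Read a graph written by :func:`write_graphml` back into a ReactionGraph."""
    import networkx as nx

    G = nx.read_graphml(str(path))
    directed = G.is_directed()
    nodes = list(G.nodes)
    node_ids = [
        (G.nodes[v].get("reaction_id", v), G.nodes[v].get("direction", ""))
        for v in nodes
    ]
    pos = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0))
        W[pos[u], pos[v]] = w
        if not directed:
            W[pos[v], pos[u]] = w
    return ReactionGraph(
        node_ids=node_ids, W=W, directed=directed,
        weight_semantics=G.graph.get("weight_semantics", "probability"),
    )


def write_edgelist(graph: ReactionGraph, path) -> None:
    """3-column TSV edge list; weights printed with 17 significant digits."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        rows, cols = np.nonzero(graph.W)
        for i, j in zip(rows, cols):
            if not graph.directed and j < i:
                continue
            src = "{}[{}]".format(*graph.node_ids[i]) if graph.node_ids[i][1] \
                else graph.node_ids[i][0]
            tgt = "{}[{}]".format(*graph.node_ids[j]) if graph.node_ids[j][1] \
                else graph.node_ids[j][0]
            fh.write(f"{src}\t{tgt}\t{graph.W[i, j]:.17g}\n")
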