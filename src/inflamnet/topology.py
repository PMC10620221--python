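"""Topology metrics and influence ranking of cell-specific networks.

Five node-influence measures are computed on the simple digraph view of a
cell-specific signaling network — in-degree centrality, out-degree
centrality, closeness centrality (incoming distances, Wasserman–Faust
correction for disconnected graphs), eigenvector centrality (in-edge
convention), and VoteRank — each converted to a rank (1 = most influential,
mid-rank ties) and averaged into a single aggregate influence rank per node.

Directedness conventions (all configurable where noted):

* Closeness uses incoming shortest-path distances: a node is central when
  signals reach it quickly.
* Eigenvector centrality uses the in-edge (left-eigenvector) convention: a
  node is central when central nodes point at it.  Signaling networks are
  nearly acyclic, where the undamped power iteration is degenerate; on
  failure a uniform damping of 0.15/n is added to the iteration matrix and
  the fallback is reported on the result.
* VoteRank votes flow along edge direction — a node is voted for by its
  in-neighbors — and electing a node suppresses its in-neighbors' voting
  ability by 1/⟨k_out⟩.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConvergenceError
from .network import SignalingNetwork, _key

#: Damping added uniformly to the iteration matrix when the undamped power
#: iteration fails (scaled by 1/n), analogous to a small teleport term.
EIGEN_DAMPING = 0.15

METRICS = ("in_degree", "out_degree", "closeness", "eigenvector", "vote_rank")


def _adjacency(network: SignalingNetwork) -> tuple[list[str], dict[str, set[str]], dict[str, set[str]]]:
    """(sorted canonical keys, successors, predecessors) with labels collapsed."""
    keys = sorted(_key(n.id) for n in network.nodes())
    succ: dict[str, set[str]] = {k: set() for k in keys}
    pred: dict[str, set[str]] = {k: set() for k in keys}
    for sk, tk, _ in network.edge_keys():
        succ[sk].add(tk)
        pred[tk].add(sk)
    return keys, succ, pred


def _as_display(network: SignalingNetwork, d: dict[str, float]) -> dict[str, float]:
    return {network.display_id(k): v for k, v in d.items()}


def degree_centralities(network: SignalingNetwork) -> dict[str, tuple[float, float]]:
    """Per-node (in, out) degree centralities, normalized by n - 1."""
    if network.n_nodes < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    keys, succ, pred = _adjacency(network)
    denom = len(keys) - 1
    return {
        network.display_id(k): (len(pred[k]) / denom, len(succ[k]) / denom)
        for k in keys
    }


def closeness_centrality(network: SignalingNetwork) -> dict[str, float]:
    """Incoming-distance closeness with the Wasserman–Faust correction.

    For node v reached by r - 1 other nodes at total distance D:
    ``C(v) = ((r - 1)/(n - 1)) * ((r - 1)/D)``; a node reached by nothing
    scores 0.
    """
    if network.n_nodes < 2:
        raise ValueError("closeness centrality requires at least 2 nodes")
    keys, _, pred = _adjacency(network)
    n = len(keys)
    scores = {}
    for v in keys:
        # BFS over predecessors = incoming shortest-path distances to v
        dist = {v: 0}
        q = deque([v])
        total = 0
        while q:
            u = q.popleft()
            for w in pred[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    total += dist[w]
                    q.append(w)
        r = len(dist)
        if r <= 1:
            scores[v] = 0.0
        else:
            scores[v] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return _as_display(network, scores)


@dataclass
class EigenvectorResult:
    """Eigenvector scores plus convergence provenance."""

    scores: dict[str, float]
    iterations: int
    damped: bool
    trace: list[float] = field(repr=False, default_factory=list)


def eigenvector_centrality(
    network: SignalingNetwork,
    tol: float = 1e-10,
    max_iter: int = 1000,
    damp_on_failure: bool = True,
) -> EigenvectorResult:
    """Eigenvector centrality by power iteration, in-edge convention.

    Iterates ``x <- M x`` with ``M = A^T`` (so a node accumulates the scores
    of its in-neighbors), declaring convergence when successive iterates
    differ by less than ``tol * n`` in L1; the result is L2-normalized.  If
    the undamped iteration fails — typical on (near-)acyclic signaling
    networks, where the dominant eigenvalue is 0 — and ``damp_on_failure`` is
    set, a uniform ``0.15/n`` is added to every entry of ``M`` and the
    iteration rerun; ``damped=True`` on the result records the fallback.

    Raises
    ------
    ConvergenceError
        If the iteration (including the damped retry) fails; carries the L1
        change trace of the failed run.
    """
    if network.n_nodes < 2:
        raise ValueError("eigenvector centrality requires at least 2 nodes")
    keys, succ, _ = _adjacency(network)
    n = len(keys)
    idx = {k: i for i, k in enumerate(keys)}
    a = np.zeros((n, n))
    for u, vs in succ.items():
        for v in vs:
            a[idx[u], idx[v]] = 1.0
    m = a.T  # x_v <- sum over in-neighbors u of x_u

    def _iterate(mat: np.ndarray) -> tuple[np.ndarray, int] | list[float]:
        x = np.full(n, 1.0 / n)
        trace = []
        for it in range(1, max_iter + 1):
            x_new = mat @ x
            norm = np.linalg.norm(x_new)
            if norm == 0:
                return trace + [float("inf")]
            x_new = x_new / norm
            change = float(np.abs(x_new - x).sum())
            trace.append(change)
            x = x_new
            if change < tol * n:
                return x, it
        return trace

    res = _iterate(m)
    if isinstance(res, tuple):
        x, it = res
        scores = {keys[i]: float(x[i]) for i in range(n)}
        return EigenvectorResult(_as_display(network, scores), it, damped=False)
    if damp_on_failure:
        damped_m = m + EIGEN_DAMPING / n
        res2 = _iterate(damped_m)
        if isinstance(res2, tuple):
            x, it = res2
            scores = {keys[i]: float(x[i]) for i in range(n)}
            return EigenvectorResult(
                _as_display(network, scores), it, damped=True
            )
        raise ConvergenceError(
            f"eigenvector power iteration failed after {max_iter} iterations "
            "(undamped and damped)", trace=res2,
        )
    raise ConvergenceError(
        f"eigenvector power iteration failed after {max_iter} iterations",
        trace=res,
    )


def vote_rank(network: SignalingNetwork, k: int | None = None) -> list[str]:
    """Elect influential nodes by iterative directed voting.

    Every node starts with voting ability 1.  Each round a node's score is
    the summed voting ability of its in-neighbors (votes flow along edges);
    the highest-scoring unelected node is elected, with ties broken by
    lexicographic id.  The elected node's ability drops to 0 and each of its
    in-neighbors' ability is reduced by 1/⟨k_out⟩ (floored at 0), where
    ⟨k_out⟩ is the network's mean out-degree.  Election stops after ``k``
    nodes (default: all) or when every remaining score is 0.
    """
    keys, succ, pred = _adjacency(network)
    n = len(keys)
    if n == 0:
        return []
    if k is None:
        k = n
    n_edges = sum(len(v) for v in succ.values())
    avg_out = n_edges / n
    ability = {key: 1.0 for key in keys}
    elected: list[str] = []
    elected_set: set[str] = set()
    while len(elected) < k:
        best_key, best_score = None, 0.0
        for key in keys:  # keys sorted -> lexicographic tie-break
            if key in elected_set:
                continue
            score = sum(ability[u] for u in pred[key])
            if score > best_score:
                best_key, best_score = key, score
        if best_key is None:  # all remaining scores are 0
            break
        elected.append(best_key)
        elected_set.add(best_key)
        ability[best_key] = 0.0
        if avg_out > 0:
            for u in pred[best_key]:
                ability[u] = max(0.0, ability[u] - 1.0 / avg_out)
    return [network.display_id(key) for key in elected]


def _mid_ranks(scores: dict[str, float]) -> dict[str, float]:
    """Descending-score mid-ranks: rank 1 = highest score, ties averaged."""
    ids = sorted(scores)
    vals = np.array([scores[i] for i in ids], dtype=float)
    ranks = rankdata(-vals, method="average")
    return dict(zip(ids, ranks))


def vote_rank_positions(order: list[str], all_nodes: list[str]) -> dict[str, float]:
    """Election positions as ranks; unelected nodes share the mean remainder."""
    pos = {node: float(i + 1) for i, node in enumerate(order)}
    rest = [node for node in all_nodes if node not in pos]
    if rest:
        # remaining positions len(order)+1 .. n, shared mid-rank
        tail = np.arange(len(order) + 1, len(all_nodes) + 1)
        shared = float(tail.mean())
        for node in rest:
            pos[node] = shared
    return pos


def rank_and_aggregate(
    scores: dict[str, dict[str, float]],
    vote_order: list[str],
    roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Convert per-metric scores to ranks and aggregate by their mean.

    Parameters
    ----------
    scores:
        Mapping metric name -> {node: raw score} for the four continuous
        metrics (``in_degree``, ``out_degree``, ``closeness``,
        ``eigenvector``); all must cover the same node set.
    vote_order:
        VoteRank election order; positions serve directly as that metric's
        ranks, unelected nodes sharing the mean of the remaining positions.

    Returns
    -------
    DataFrame indexed 0..n-1, sorted ascending by ``aggregate_rank`` (ties by
    node id), with raw scores, per-metric ranks, and the aggregate.
    """
    continuous = ("in_degree", "out_degree", "closeness", "eigenvector")
    missing = [m for m in continuous if m not in scores]
    if missing:
        raise ValueError(f"missing metrics: {missing}")
    node_sets = {m: frozenset(scores[m]) for m in continuous}
    universe = node_sets[continuous[0]]
    if any(s != universe for s in node_sets.values()):
        raise ValueError("metrics computed on different node sets")
    stray = set(vote_order) - set(universe)
    if stray:
        raise ValueError(f"vote order contains unknown nodes: {sorted(stray)}")

    nodes = sorted(universe)
    ranks = {m: _mid_ranks(scores[m]) for m in continuous}
    ranks["vote_rank"] = vote_rank_positions(vote_order, nodes)

    rows = []
    for node in nodes:
        per_metric = [ranks[m][node] for m in METRICS]
        row = {"node": node, "role": (roles or {}).get(node, "other")}
        for m in continuous:
            row[f"score_{m}"] = scores[m][node]
        row["vote_position"] = ranks["vote_rank"][node]
        for m in METRICS:
            row[f"rank_{m}"] = ranks[m][node]
        row["aggregate_rank"] = float(np.mean(per_metric))
        rows.append(row)
    report = pd.DataFrame(rows)
    report = report.sort_values(
        ["aggregate_rank", "node"], kind="mergesort"
    ).reset_index(drop=True)
    report["position"] = np.arange(1, len(report) + 1)
    return report


def rank_nodes(network: SignalingNetwork) -> pd.DataFrame:
    """Full topology report for a network: five metrics, ranks, aggregate."""
    deg = degree_centralities(network)
    scores = {
        "in_degree": {n: d[0] for n, d in deg.items()},
        "out_degree": {n: d[1] for n, d in deg.items()},
        "closeness": closeness_centrality(network),
        "eigenvector": eigenvector_centrality(network).scores,
    }
    order = vote_rank(network)
    roles = {n.id: n.role for n in network.nodes()}
    return rank_and_aggregate(scores, order, roles)
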