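"""Topology metrics: closed forms, independent solvers, and hand simulation."""

import networkx as nx
import numpy as np
import pytest

from inflamnet import (
    ConvergenceError,
    closeness_centrality,
    degree_centralities,
    eigenvector_centrality,
    network_from_edges,
    rank_and_aggregate,
    rank_nodes,
    vote_rank,
)

from conftest import random_network


def in_star(n_leaves=4):
    """All leaves point at the hub H."""
    return network_from_edges([(f"L{i}", "H") for i in range(n_leaves)])


def cycle(n):
    return network_from_edges(
        [(f"C{i}", f"C{(i + 1) % n}") for i in range(n)]
    )


# ------------------------------------------------------------------ degrees


def test_star_degree_closed_form():
    deg = degree_centralities(in_star(4))  # n = 5
    assert deg["H"] == (1.0, 0.0)
    for i in range(4):
        assert deg[f"L{i}"] == (0.0, 0.25)


@pytest.mark.parametrize("n", [3, 5, 8])
def test_cycle_degree_symmetry(n):
    deg = degree_centralities(cycle(n))
    assert all(d == (1 / (n - 1), 1 / (n - 1)) for d in deg.values())


def test_degree_counting_oracle(rng):
    net = random_network(rng, 10, 0.3)
    deg = degree_centralities(net)
    pairs = {k[:2] for k in net.edge_keys()}
    n = net.n_nodes
    for node in net.node_ids:
        k = node.casefold()
        indeg = sum(1 for s, t in pairs if t == k)
        outdeg = sum(1 for s, t in pairs if s == k)
        assert deg[node] == (indeg / (n - 1), outdeg / (n - 1))


def test_degree_requires_two_nodes():
    net = network_from_edges([], roles={"A": "other"})
    with pytest.raises(ValueError):
        degree_centralities(net)


# ---------------------------------------------------------------- closeness


def test_closeness_hand_bfs_on_two_path():
    """C of A->B->C: incoming distances {A: 2, B: 1}, WF value 2/3."""
    net = network_from_edges([("A", "B"), ("B", "C")])
    c = closeness_centrality(net)
    assert c["C"] == pytest.approx(2 / 3)
    assert c["A"] == 0.0  # nothing reaches A
    assert c["B"] == pytest.approx((1 / 2) * (1 / 1))  # r=2, D=1


def test_closeness_isolated_node_zero():
    net = network_from_edges([("A", "B")])
    net.add_node("LONER")
    assert closeness_centrality(net)["LONER"] == 0.0


def test_closeness_cycle_symmetry():
    c = closeness_centrality(cycle(6))
    vals = list(c.values())
    assert max(vals) == pytest.approx(min(vals))


def test_closeness_matches_networkx(rng):
    """networkx's incoming-distance, WF-improved closeness is the oracle."""
    for _ in range(5):
        net = random_network(rng, 9, 0.3)
        ours = closeness_centrality(net)
        theirs = nx.closeness_centrality(net.to_networkx())
        for node in net.node_ids:
            assert ours[node] == pytest.approx(theirs[node], abs=1e-12)


# -------------------------------------------------------------- eigenvector


@pytest.mark.parametrize("n", [3, 5, 10])
def test_eigenvector_cycle_uniform(n):
    res = eigenvector_centrality(cycle(n))
    assert not res.damped
    for v in res.scores.values():
        assert v == pytest.approx(1 / np.sqrt(n), abs=1e-8)


def test_eigenvector_degenerate_two_node():
    """A->B alone cannot converge undamped; damping fallback is reported."""
    net = network_from_edges([("A", "B")])
    res = eigenvector_centrality(net)
    assert res.damped
    assert res.scores["B"] > res.scores["A"] > 0
    with pytest.raises(ConvergenceError):
        eigenvector_centrality(net, damp_on_failure=False, max_iter=50)


def test_eigenvector_matches_dense_solver(rng):
    """On strongly connected digraphs, compare to a dense eigendecomposition."""
    checked = 0
    while checked < 5:
        net = random_network(rng, 8, 0.4)
        g = net.to_networkx()
        if not nx.is_strongly_connected(g):
            continue
        checked += 1
        res = eigenvector_centrality(net, tol=1e-14)
        nodes = sorted(net.node_ids)
        a = nx.to_numpy_array(g, nodelist=nodes)
        w, v = np.linalg.eig(a.T)
        lead = np.argmax(w.real)
        vec = np.abs(v[:, lead].real)
        vec = vec / np.linalg.norm(vec)
        for i, node in enumerate(nodes):
            assert res.scores[node] == pytest.approx(vec[i], abs=1e-8)


def test_eigenvector_l2_normalized(rng):
    net = random_network(rng, 7, 0.5)
    res = eigenvector_centrality(net)
    assert np.linalg.norm(list(res.scores.values())) == pytest.approx(1.0)


# ----------------------------------------------------------------- voterank


def test_voterank_in_star_hub_first():
    order = vote_rank(in_star(4))
    assert order[0] == "H"


def test_voterank_cycle_lexicographic():
    order = vote_rank(cycle(4))
    assert order == sorted(order)


def voterank_hand_simulation(pairs, nodes):
    """Literal step-by-step simulation of the directed voting rules."""
    succ = {v: set() for v in nodes}
    pred = {v: set() for v in nodes}
    for s, t in pairs:
        succ[s].add(t)
        pred[t].add(s)
    avg_out = sum(len(s) for s in succ.values()) / len(nodes)
    ability = {v: 1.0 for v in nodes}
    elected = []
    while True:
        scores = {
            v: sum(ability[u] for u in pred[v])
            for v in nodes if v not in elected
        }
        best = max(scores.values(), default=0.0)
        if best <= 0:
            break
        winner = min(v for v, s in scores.items() if s == best)
        elected.append(winner)
        ability[winner] = 0.0
        for u in pred[winner]:
            ability[u] = max(0.0, ability[u] - 1.0 / avg_out) if avg_out else ability[u]
    return elected


@pytest.mark.parametrize("seed", range(6))
def test_voterank_equals_hand_simulation(seed):
    rng = np.random.default_rng(seed)
    net = random_network(rng, int(rng.integers(3, 7)), 0.4)
    pairs = {(net.display_id(a), net.display_id(b)) for a, b, _ in net.edge_keys()}
    want = voterank_hand_simulation(pairs, net.node_ids)
    assert vote_rank(net) == want


def test_voterank_matches_networkx_on_reversed_graph():
    """networkx's directed voterank scores nodes by their out-edges (the
    spreader convention); ours scores by in-edges, so the two agree on
    mutually reversed graphs (mean in-degree equals mean out-degree)."""
    edges = [("A", "D"), ("B", "D"), ("C", "D"), ("D", "E"), ("E", "A"), ("B", "E")]
    net = network_from_edges(edges)
    ours = vote_rank(net)
    theirs = nx.voterank(net.to_networkx().reverse())
    assert ours == theirs


# -------------------------------------------------------------- aggregation


def test_aggregate_all_first():
    scores = {
        m: {"X": 2.0, "Y": 1.0, "Z": 0.5}
        for m in ("in_degree", "out_degree", "closeness", "eigenvector")
    }
    rep = rank_and_aggregate(scores, vote_order=["X", "Y", "Z"])
    top = rep.iloc[0]
    assert top["node"] == "X" and top["aggregate_rank"] == 1.0
    assert rep.iloc[0]["position"] == 1


def test_aggregate_mirrored_ranks_tie():
    scores = {
        "in_degree": {"X": 2.0, "Y": 1.0},
        "out_degree": {"X": 1.0, "Y": 2.0},
        "closeness": {"X": 2.0, "Y": 1.0},
        "eigenvector": {"X": 1.0, "Y": 2.0},
    }
    # vote order puts neither ahead: no elections (empty), both share (1+2)/2
    rep = rank_and_aggregate(scores, vote_order=[])
    assert list(rep["aggregate_rank"]) == [1.5, 1.5]


def test_aggregate_node_set_mismatch_raises():
    scores = {
        "in_degree": {"X": 1.0},
        "out_degree": {"X": 1.0, "Y": 2.0},
        "closeness": {"X": 1.0},
        "eigenvector": {"X": 1.0},
    }
    with pytest.raises(ValueError, match="different node sets"):
        rank_and_aggregate(scores, vote_order=[])


def test_unelected_share_mean_remaining_positions():
    scores = {
        m: {"A": 3.0, "B": 2.0, "C": 1.0, "D": 0.5}
        for m in ("in_degree", "out_degree", "closeness", "eigenvector")
    }
    rep = rank_and_aggregate(scores, vote_order=["A"])  # only one elected
    vp = dict(zip(rep["node"], rep["rank_vote_rank"]))
    assert vp["A"] == 1.0
    assert vp["B"] == vp["C"] == vp["D"] == pytest.approx(3.0)  # mean of 2,3,4


def test_relabeling_invariance(rng):
    """Metric scores are invariant under a node-id permutation."""
    net = random_network(rng, 8, 0.35)
    mapping = {n: f"Z{i:02d}" for i, n in enumerate(reversed(net.node_ids))}
    relabeled = network_from_edges(
        [
            (mapping[net.display_id(s)], mapping[net.display_id(t)], i)
            for s, t, i in net.edge_keys()
        ]
    )
    for n in net.node_ids:
        relabeled.add_node(mapping[n])
    rep1 = rank_nodes(net).set_index("node")
    rep2 = rank_nodes(relabeled).set_index("node")
    for n in net.node_ids:
        for col in ("score_in_degree", "score_out_degree", "score_closeness"):
            assert rep1.loc[n, col] == pytest.approx(rep2.loc[mapping[n], col])
        assert rep1.loc[n, "score_eigenvector"] == pytest.approx(
            rep2.loc[mapping[n], "score_eigenvector"], abs=1e-6
        )


def test_report_sorted_and_bounded(rng):
    net = random_network(rng, 10, 0.3)
    rep = rank_nodes(net)
    assert list(rep["aggregate_rank"]) == sorted(rep["aggregate_rank"])
    assert rep["aggregate_rank"].between(1, net.n_nodes).all()
    assert rep["score_closeness"].between(0, 1).all()
    assert rep["score_in_degree"].between(0, 1).all()
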