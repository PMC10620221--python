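"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: path
enumeration is checked against exhaustive permutation testing, centralities
against hand formulas / dense linear algebra, and statistics against direct
formula evaluation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from inflamnet import SignalingNetwork, network_from_edges


def random_digraph_edges(rng: np.random.Generator, n: int, p: float) -> list[tuple[str, str]]:
    """Random simple digraph on nodes N00..N{n-1}, edge probability p."""
    nodes = [f"N{i:02d}" for i in range(n)]
    return [
        (u, v) for u in nodes for v in nodes if u != v and rng.random() < p
    ]


def random_network(rng: np.random.Generator, n: int, p: float) -> SignalingNetwork:
    edges = random_digraph_edges(rng, n, p)
    net = SignalingNetwork("random")
    for i in range(n):
        net.add_node(f"N{i:02d}")
    for u, v in edges:
        net.add_edge(u, v, "interacts")
    return net


def brute_force_simple_paths(
    edges: set[tuple[str, str]],
    nodes: list[str],
    inputs: set[str],
    outputs: set[str],
    max_nodes: int,
) -> set[tuple[str, ...]]:
    """All valid bounded simple paths by exhaustive permutation testing."""
    found = set()
    for length in range(2, min(max_nodes, len(nodes)) + 1):
        for seq in itertools.permutations(nodes, length):
            if seq[0] not in inputs or seq[-1] not in outputs:
                continue
            if all((seq[i], seq[i + 1]) in edges for i in range(length - 1)):
                found.add(seq)
    return found


@pytest.fixture
def chain_network() -> SignalingNetwork:
    """A -> B -> C."""
    return network_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
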