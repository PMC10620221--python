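"""Depth-bounded simple-path enumeration between measured mediators.

The pathology-specific subnetwork is obtained by enumerating every simple
path — a directed path with no repeated node — that starts at a measured
input mediator and ends at a measured output mediator, subject to a depth
cap, and then keeping exactly the nodes and edges those paths traverse.
The enumeration is a depth-first search with an explicit stack and on-path
membership marking, so correctness never depends on the Python recursion
limit.

The depth cap counts total nodes on the path including both endpoints
(cap 8 permits up to 7 edges); an edge-count convention is available via
``count_mode="edges"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import NetworkValidationError
from .network import SignalingNetwork, _key

logger = logging.getLogger(__name__)

#: Default search depth: paths of at most 8 nodes (7 edges).
DEFAULT_MAX_NODES = 8


@dataclass(frozen=True)
class MediatorPanel:
    """Measured mediators anchoring the pruning: upstream inputs, downstream outputs.

    The two sets may overlap — a cytokine can be both secreted into the system
    and measured out of it.
    """

    inputs: frozenset[str]
    outputs: frozenset[str]

    def __post_init__(self):
        if not self.inputs or not self.outputs:
            raise ValueError("mediator panel requires non-empty inputs and outputs")

    @classmethod
    def from_lists(cls, inputs, outputs) -> "MediatorPanel":
        return cls(frozenset(inputs), frozenset(outputs))

    @classmethod
    def read_tsv(cls, path) -> "MediatorPanel":
        """Read a two-column TSV (id, direction in {input, output})."""
        inputs, outputs = set(), set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if lineno == 1 and fields[0].lower() == "id":
                    continue
                if len(fields) < 2 or fields[1] not in ("input", "output"):
                    raise ValueError(
                        f"{path}:{lineno}: expected 'id<TAB>input|output'"
                    )
                (inputs if fields[1] == "input" else outputs).add(fields[0])
        return cls(frozenset(inputs), frozenset(outputs))

    def all_ids(self) -> frozenset[str]:
        return self.inputs | self.outputs

    def write_tsv(self, path) -> None:
        rows = ["id\tdirection"]
        rows += [f"{i}\tinput" for i in sorted(self.inputs)]
        rows += [f"{o}\toutput" for o in sorted(self.outputs)]
        with open(path, "w") as fh:
            fh.write("".join(r + "\n" for r in rows))


@dataclass
class PathSet:
    """All admissible simple paths plus the provenance of the enumeration."""

    paths: list[tuple[str, ...]]
    network: SignalingNetwork
    panel: MediatorPanel
    max_nodes: int
    unmatched: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.paths)

    def node_ids(self) -> set[str]:
        return {n for p in self.paths for n in p}

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Canonical-key (source, target) pairs traversed by at least one path."""
        return {
            (_key(p[i]), _key(p[i + 1]))
            for p in self.paths
            for i in range(len(p) - 1)
        }

    def write_paths(self, path) -> None:
        """One path per line, node ids joined by '->'."""
        with open(path, "w") as fh:
            for p in self.paths:
                fh.write("->".join(p) + "\n")


def _simple_paths_core(
    adj: dict, sources: list, targets: set, max_nodes: int
) -> list[tuple]:
    """Iterative depth-first enumeration of bounded simple paths.

    ``adj`` maps node -> sorted successor list.  Emission order is
    lexicographic when sources and successor lists are sorted.  Exposed for
    the exhaustive equivalence tests, which exercise it on raw adjacency maps.
    """
    out: list[tuple] = []
    if max_nodes < 2:
        return out
    for s in sources:
        visited = [s]
        on_path = {s}
        stack = [iter(adj.get(s, ()))]
        while stack:
            nxt = next(stack[-1], None)
            if nxt is None:
                stack.pop()
                on_path.discard(visited.pop())
            elif nxt not in on_path:
                visited.append(nxt)
                on_path.add(nxt)
                if nxt in targets:
                    out.append(tuple(visited))
                if len(visited) < max_nodes:
                    stack.append(iter(adj.get(nxt, ())))
                else:
                    on_path.discard(visited.pop())
    return out


def enumerate_simple_paths(
    network: SignalingNetwork,
    panel: MediatorPanel,
    max_nodes: int = DEFAULT_MAX_NODES,
    count_mode: str = "nodes",
) -> PathSet:
    """Enumerate all simple paths from panel inputs to panel outputs.

    Parameters
    ----------
    max_nodes:
        Depth cap.  With ``count_mode="nodes"`` (default) it bounds the total
        node count of a path; with ``count_mode="edges"`` it bounds the edge
        count (a cap of k edges permits k+1 nodes).
    Returns
    -------
    PathSet
        Paths in lexicographic order of their node-id sequences.  Panel ids
        that do not resolve to network nodes are logged, recorded in
        ``PathSet.unmatched``, and skipped.  Paths have at least one edge: a
        node that is both input and output is not by itself a path.
    """
    if count_mode not in ("nodes", "edges"):
        raise ValueError(f"count_mode must be 'nodes' or 'edges', got {count_mode!r}")
    cap = max_nodes if count_mode == "nodes" else max_nodes + 1
    if cap < 2:
        raise ValueError("max_nodes must allow at least one edge (>= 2 nodes)")

    adj = network.adjacency()
    sources, unmatched_in = [], []
    for i in sorted(panel.inputs):
        (sources if network.has_node(i) else unmatched_in).append(i)
    targets, unmatched_out = [], []
    for o in sorted(panel.outputs):
        (targets if network.has_node(o) else unmatched_out).append(o)
    unmatched = {}
    if unmatched_in:
        unmatched["inputs"] = unmatched_in
    if unmatched_out:
        unmatched["outputs"] = unmatched_out
    if unmatched:
        logger.warning("panel ids not in network, skipped: %s", unmatched)

    source_keys = sorted({_key(s) for s in sources})
    target_keys = {_key(t) for t in targets}
    if not source_keys or not target_keys:
        logger.warning("no resolvable panel inputs or outputs; empty path set")
        return PathSet([], network, panel, max_nodes, unmatched)

    raw = _simple_paths_core(adj, source_keys, target_keys, cap)
    paths = sorted(tuple(network.display_id(k) for k in p) for p in raw)
    return PathSet(paths, network, panel, max_nodes, unmatched)


def induce_subnetwork(network: SignalingNetwork, pathset: PathSet) -> SignalingNetwork:
    """Subnetwork of exactly the nodes and edges traversed by the paths.

    Only path-traversed edges are kept — not all edges among retained nodes —
    so shortcut interactions that lie on no admissible path stay pruned.
    Roles and provenance carry over from the source network.
    """
    sub = SignalingNetwork(f"{network.name}|pruned")
    for node_id in sorted(pathset.node_ids()):
        if not network.has_node(node_id):
            raise NetworkValidationError(
                f"path node {node_id!r} missing from source network"
            )
        node = network.node(node_id)
        sub.add_node(node.id, node.role, node.provenance)
    used_pairs = pathset.edge_pairs()
    for edge, prov in network.edges():
        if (_key(edge.source), _key(edge.target)) in used_pairs:
            sub.add_edge(edge.source, edge.target, edge.interaction, prov)
    sub.validate()
    return sub
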