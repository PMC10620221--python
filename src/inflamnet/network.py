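"""Directed signaling networks: SIF input/output, validation, and merging.

A :class:`SignalingNetwork` is a directed protein-interaction graph whose
nodes carry a signaling role (ligand, receptor, secondary messenger,
transcription factor, or other) and provenance labels naming the source
network(s) each node and edge came from.  Networks are read from and written
to Cytoscape's simple interaction format (SIF), and independently published
component networks are merged into a single cell-agnostic network by set
union with case-insensitive identifier matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import NetworkValidationError, SifParseError

logger = logging.getLogger(__name__)

#: Recognized signaling roles, ordered from most specific to least.
ROLES = ("ligand", "receptor", "secondary-messenger", "transcription-factor", "other")

_SPECIFIC_ROLES = frozenset(ROLES[:-1])


def _key(node_id: str) -> str:
    """Canonical (case-insensitive) identifier key."""
    return node_id.casefold()


@dataclass
class Node:
    """A network node: display identifier, signaling role, provenance labels."""

    id: str
    role: str = "other"
    provenance: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"unknown role {self.role!r} for node {self.id!r}; "
                f"expected one of {ROLES}"
            )


@dataclass(frozen=True)
class Edge:
    """A directed interaction: source → target with a free-text label."""

    source: str
    target: str
    interaction: str

    def key(self) -> tuple[str, str, str]:
        return (_key(self.source), _key(self.target), self.interaction)


class SignalingNetwork:
    """Directed signaling graph with role-tagged nodes and labelled edges.

    Invariants enforced on mutation and re-checked by :meth:`validate`:

    * every edge endpoint is a declared node,
    * node identifiers are unique after case-normalization,
    * no duplicate (source, target, interaction) triples,
    * no self-loops.
    """

    def __init__(self, name: str = "network"):
        self.name = name
        self._nodes: dict[str, Node] = {}  # canonical key -> Node
        self._edges: dict[tuple[str, str, str], set[str]] = {}  # edge key -> provenance
        self.meta: dict = {"self_loops_dropped": 0, "role_conflicts": []}

    # ------------------------------------------------------------------ nodes

    def add_node(
        self,
        node_id: str,
        role: str = "other",
        provenance: Iterable[str] = (),
    ) -> Node:
        """Add a node or update role/provenance of an existing one.

        Role conflicts are resolved by keeping the most specific non-"other"
        role; two distinct specific roles resolve to the lexicographically
        smaller, and the conflict is logged and recorded in ``meta``.
        """
        k = _key(node_id)
        node = self._nodes.get(k)
        if node is None:
            node = Node(node_id, role, set(provenance))
            self._nodes[k] = node
            return node
        node.provenance.update(provenance)
        node.role = self._reconcile_roles(node.id, node.role, role)
        return node

    def _reconcile_roles(self, node_id: str, old: str, new: str) -> str:
        if old == new:
            return old
        if new == "other":
            return old
        if old == "other":
            return new
        # two distinct specific roles: deterministic lexicographic resolution
        resolved = min(old, new)
        conflict = (node_id, old, new, resolved)
        self.meta["role_conflicts"].append(conflict)
        logger.warning(
            "role conflict for %r: %r vs %r, keeping %r", node_id, old, new, resolved
        )
        return resolved

    # ------------------------------------------------------------------ edges

    def add_edge(
        self,
        source: str,
        target: str,
        interaction: str = "interacts",
        provenance: Iterable[str] = (),
    ) -> None:
        """Add a directed edge; endpoints are auto-declared; self-loops dropped."""
        if _key(source) == _key(target):
            self.meta["self_loops_dropped"] += 1
            logger.debug("dropping self-loop on %r", source)
            return
        self.add_node(source, provenance=provenance)
        self.add_node(target, provenance=provenance)
        ekey = (_key(source), _key(target), interaction)
        self._edges.setdefault(ekey, set()).update(provenance)

    # ------------------------------------------------------------ inspection

    @property
    def node_ids(self) -> list[str]:
        """Display identifiers, sorted."""
        return sorted(n.id for n in self._nodes.values())

    def nodes(self) -> list[Node]:
        return [self._nodes[k] for k in sorted(self._nodes)]

    def node(self, node_id: str) -> Node:
        return self._nodes[_key(node_id)]

    def has_node(self, node_id: str) -> bool:
        return _key(node_id) in self._nodes

    def edges(self) -> list[tuple[Edge, set[str]]]:
        """Edge records with provenance, in deterministic (sorted) order."""
        out = []
        for (sk, tk, inter) in sorted(self._edges):
            edge = Edge(self._nodes[sk].id, self._nodes[tk].id, inter)
            out.append((edge, set(self._edges[(sk, tk, inter)])))
        return out

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def has_edge(self, source: str, target: str, interaction: str | None = None) -> bool:
        sk, tk = _key(source), _key(target)
        if interaction is not None:
            return (sk, tk, interaction) in self._edges
        return any(k[:2] == (sk, tk) for k in self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def adjacency(self) -> dict[str, list[str]]:
        """Successor map on canonical keys; parallel labels collapse; sorted."""
        adj: dict[str, set[str]] = {k: set() for k in self._nodes}
        for sk, tk, _ in self._edges:
            adj[sk].add(tk)
        return {k: sorted(v) for k, v in adj.items()}

    def display_id(self, key: str) -> str:
        return self._nodes[_key(key)].id

    def to_networkx(self) -> nx.DiGraph:
        """Simple digraph view (parallel interaction labels collapsed)."""
        g = nx.DiGraph()
        for node in self.nodes():
            g.add_node(node.id, role=node.role)
        for sk, tk, _ in self._edges:
            g.add_edge(self._nodes[sk].id, self._nodes[tk].id)
        return g

    # ------------------------------------------------------------ validation

    def validate(self) -> None:
        for sk, tk, inter in self._edges:
            if sk not in self._nodes or tk not in self._nodes:
                raise NetworkValidationError(
                    f"edge ({sk}, {tk}, {inter!r}) references undeclared node"
                )
            if sk == tk:
                raise NetworkValidationError(f"self-loop on {sk!r}")

    # -------------------------------------------------------------- equality

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalingNetwork):
            return NotImplemented
        mine = {k: (n.role, frozenset(n.provenance)) for k, n in self._nodes.items()}
        theirs = {k: (n.role, frozenset(n.provenance)) for k, n in other._nodes.items()}
        edges_mine = {k: frozenset(v) for k, v in self._edges.items()}
        edges_theirs = {k: frozenset(v) for k, v in other._edges.items()}
        return mine == theirs and edges_mine == edges_theirs

    def __repr__(self) -> str:
        return (
            f"SignalingNetwork({self.name!r}, {self.n_nodes} nodes, "
            f"{self.n_edges} edges)"
        )


# ---------------------------------------------------------------------- SIF


def read_sif(
    path: str | Path,
    node_attrs: str | Path | None = None,
    name: str | None = None,
    provenance: str | None = None,
) -> SignalingNetwork:
    """Read a SIF file into a validated :class:`SignalingNetwork`.

    Each non-empty line has either a single field (the SIF lone-node
    convention, declaring an isolated node) or at least three fields
    (``source interaction target [target ...]``); lines with multiple targets
    expand to one edge per target.  Fields are tab-delimited when the line
    contains a tab, otherwise whitespace-delimited (both SIF dialects occur in
    the wild).  Self-loops are dropped with a logged count.

    Parameters
    ----------
    node_attrs:
        Optional TSV sidecar with columns ``id`` and ``role`` assigning
        signaling roles; nodes not listed default to role ``other``.
    provenance:
        Label recorded on every node and edge; defaults to the file stem.
    """
    path = Path(path)
    label = provenance if provenance is not None else path.stem
    net = SignalingNetwork(name or path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) == 1:
                # SIF lone-node convention: a single field declares a node
                net.add_node(fields[0], provenance=[label])
                continue
            if len(fields) < 3:
                raise SifParseError(
                    f"{path}:{lineno}: expected 1 field (lone node) or >=3 "
                    f"fields (source interaction target...), got {len(fields)}",
                    line_number=lineno,
                )
            source, interaction, *targets = fields
            for target in targets:
                net.add_edge(source, target, interaction, provenance=[label])
    if net.meta["self_loops_dropped"]:
        logger.info(
            "%s: dropped %d self-loop(s)", path, net.meta["self_loops_dropped"]
        )
    if node_attrs is not None:
        _apply_node_attrs(net, Path(node_attrs))
    net.validate()
    return net


def _apply_node_attrs(net: SignalingNetwork, path: Path) -> None:
    seen: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and fields[0].lower() == "id":
                continue  # header
            if len(fields) < 2:
                raise SifParseError(
                    f"{path}:{lineno}: expected 'id<TAB>role'", line_number=lineno
                )
            node_id, role = fields[0], fields[1]
            k = _key(node_id)
            if k in seen and seen[k] != role:
                raise NetworkValidationError(
                    f"{path}:{lineno}: contradictory roles for {node_id!r}: "
                    f"{seen[k]!r} vs {role!r}"
                )
            seen[k] = role
            if net.has_node(node_id):
                net.node(node_id).role = role
                if role not in ROLES:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: unknown role {role!r}"
                    )


def write_sif(
    network: SignalingNetwork,
    path: str | Path,
    node_attrs: str | Path | None = None,
) -> None:
    """Write a network as tab-delimited SIF in deterministic line order.

    One line per edge, ``source<TAB>interaction<TAB>target``, sorted
    lexicographically.  If ``node_attrs`` is given, a TSV sidecar with node
    roles is written alongside.
    """
    network.validate()
    lines = [
        f"{e.source}\t{e.interaction}\t{e.target}" for e, _ in network.edges()
    ]
    connected = {x for k in network.edge_keys() for x in k[:2]}
    lines += [
        n.id for n in network.nodes() if _key(n.id) not in connected
    ]  # lone-node lines keep isolated nodes round-trippable
    lines.sort()
    Path(path).write_text("".join(line + "\n" for line in lines))
    if node_attrs is not None:
        rows = ["id\trole"] + [f"{n.id}\t{n.role}" for n in network.nodes()]
        Path(node_attrs).write_text("".join(r + "\n" for r in rows))


# -------------------------------------------------------------------- merge


def merge_networks(networks: list[SignalingNetwork], name: str = "merged") -> SignalingNetwork:
    """Union of networks into one cell-agnostic network.

    Node sets are united with case-insensitive identifier matching and
    provenance unioned; duplicate edges collapse with provenance unioned.
    Role conflicts resolve to the most specific role; ties between two
    specific roles resolve lexicographically and are recorded in
    ``merged.meta["role_conflicts"]``.
    """
    if not networks:
        raise ValueError("merge_networks requires a non-empty list")
    merged = SignalingNetwork(name)
    for net in networks:
        for node in net.nodes():
            merged.add_node(node.id, node.role, node.provenance)
        for edge, prov in net.edges():
            merged.add_edge(edge.source, edge.target, edge.interaction, prov)
    merged.validate()
    return merged


def network_from_edges(
    edges: Iterable[tuple[str, str] | tuple[str, str, str]],
    roles: Mapping[str, str] | None = None,
    name: str = "network",
    provenance: str | None = None,
) -> SignalingNetwork:
    """Convenience constructor from (source, target[, interaction]) tuples."""
    net = SignalingNetwork(name)
    prov = [provenance] if provenance else []
    for e in edges:
        if len(e) == 2:
            net.add_edge(e[0], e[1], provenance=prov)
        else:
            net.add_edge(e[0], e[1], e[2], provenance=prov)
    if roles:
        for node_id, role in roles.items():
            if net.has_node(node_id):
                net.add_node(node_id, role=role)
            else:
                net.add_node(node_id, role=role, provenance=prov)
    net.validate()
    return net
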