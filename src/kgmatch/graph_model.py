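"""Attributed directed graphs for medical knowledge-graph pattern matching.

Two graph kinds are modelled.  A *data graph* is a simple directed graph
whose nodes are care-process participants — attending physician (``AP``),
testing instrument (``TI``), tumor type (``TC``), nursing staff (``PM``),
treatment method (``TM``) — each carrying a trust impact factor ``dt`` in
[0, 1].  Edges carry three attributes in [0, 1]: a diagnostic/therapeutic
trust value ``dt_trust``, a treatment-cycle value ``dc`` (resource-allocation
efficiency) and a cost-benefit value ``cv`` (effect-per-unit-cost, E/C
convention).

A *pattern graph* is a DAG of role-constrained query nodes.  Pattern nodes
constrain the role and the trust impact factor of their matches through a
:class:`MembershipSpec` (a monotone map on [0, 1] plus a threshold).  Pattern
edges carry one membership spec per path-aggregated attribute and a hop bound
``length_bound`` (``None`` = unbounded): a pattern edge matches any
sufficiently short data *path*, not just a single data edge.

Readers and writers are provided for a JSON property-graph schema, GraphML,
and a CSV node/edge-list pair.  Attribute keys in files are fixed snake_case
names (``role``, ``name``, ``dt``, ``dt_trust``, ``dc``, ``cv``,
``length_bound``) so that interchange is dialect-free.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Union

import networkx as nx

from .errors import GraphValidationError, NotADAGError, ParseError

__all__ = [
    "DEFAULT_ROLES",
    "RoleLabel",
    "MembershipSpec",
    "MEMBERSHIP_FUNCTIONS",
    "register_membership",
    "DataNode",
    "DataEdge",
    "DataGraph",
    "PatternNode",
    "PatternEdge",
    "PatternGraph",
    "satisfies_node_constraint",
    "read_graph",
    "write_graph",
]

#: Role vocabulary of the lung-cancer consultation graph.  The set is
#: advisory, not enforced: any non-empty whitespace-free token is a legal role,
#: so the model extends to other domains without configuration.
DEFAULT_ROLES = ("AP", "TI", "TC", "PM", "TM")


class RoleLabel(str):
    """Node role token, e.g. ``AP`` for attending physician."""

    __slots__ = ()

    def __new__(cls, value: object) -> "RoleLabel":
        value = str(value)
        if not value or value != value.strip() or any(ch.isspace() for ch in value):
            raise GraphValidationError(
                f"role label must be a non-empty whitespace-free token, got {value!r}"
            )
        return super().__new__(cls, value)


def _check_unit(what: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise GraphValidationError(f"{what} must lie in [0, 1], got {value!r}")
    return value


def _identity(x: float) -> float:
    return float(x)


#: Registry of named monotone maps [0, 1] -> [0, 1] usable as membership
#: functions.  ``identity`` is the default and the only built-in.
MEMBERSHIP_FUNCTIONS: dict[str, Callable[[float], float]] = {"identity": _identity}


def register_membership(function_id: str, fn: Callable[[float], float]) -> None:
    """Register a named membership function for use in :class:`MembershipSpec`."""
    MEMBERSHIP_FUNCTIONS[str(function_id)] = fn


@dataclass(frozen=True)
class MembershipSpec:
    """A membership function plus the threshold its output must reach.

    An attribute value ``x`` (a node trust impact factor, or a path
    aggregate) satisfies the spec when ``f(x) >= threshold``.
    """

    threshold: float = 0.0
    function_id: str = "identity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "threshold", _check_unit("membership threshold", self.threshold))
        if self.function_id not in MEMBERSHIP_FUNCTIONS:
            raise GraphValidationError(
                f"unknown membership function {self.function_id!r}; "
                f"known: {sorted(MEMBERSHIP_FUNCTIONS)}"
            )

    def apply(self, value: float) -> float:
        return MEMBERSHIP_FUNCTIONS[self.function_id](value)

    def satisfied_by(self, value: float) -> bool:
        return self.apply(value) >= self.threshold


@dataclass(frozen=True)
class DataNode:
    """A participant in the data graph with trust impact factor ``dt``."""

    id: str
    role: RoleLabel
    name: str = ""
    dt: float = 0.0
    extras: Mapping[str, object] = field(default_factory=dict, compare=True)

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("node id must be non-empty")
        object.__setattr__(self, "role", RoleLabel(self.role))
        object.__setattr__(self, "dt", _check_unit(f"dt of node {self.id!r}", self.dt))


@dataclass(frozen=True)
class DataEdge:
    """A directed data edge with trust / cycle / cost-benefit attributes."""

    source: str
    target: str
    dt_trust: float = 0.0
    dc: float = 0.0
    cv: float = 0.0
    extras: Mapping[str, object] = field(default_factory=dict, compare=True)

    def __post_init__(self) -> None:
        label = f"edge ({self.source!r}, {self.target!r})"
        object.__setattr__(self, "dt_trust", _check_unit(f"dt_trust of {label}", self.dt_trust))
        object.__setattr__(self, "dc", _check_unit(f"dc of {label}", self.dc))
        object.__setattr__(self, "cv", _check_unit(f"cv of {label}", self.cv))

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class PatternNode:
    """A query node: role constraint plus trust-impact-factor membership."""

    id: str
    role: RoleLabel
    dt_membership: MembershipSpec = MembershipSpec()

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("pattern node id must be non-empty")
        object.__setattr__(self, "role", RoleLabel(self.role))


@dataclass(frozen=True)
class PatternEdge:
    """A query edge: per-aggregate memberships and a hop bound.

    ``length_bound`` is the maximum number of hops of a matching data path;
    ``None`` means unbounded.  The default of 2 is the conventional bound for
    this graph family.
    """

    source: str
    target: str
    dt_membership: MembershipSpec = MembershipSpec()
    dc_membership: MembershipSpec = MembershipSpec()
    cv_membership: MembershipSpec = MembershipSpec()
    length_bound: Union[int, None] = 2

    def __post_init__(self) -> None:
        if self.length_bound is not None:
            lb = int(self.length_bound)
            if lb < 1:
                raise GraphValidationError(
                    f"length_bound of pattern edge ({self.source!r}, {self.target!r}) "
                    f"must be >= 1 or None, got {self.length_bound!r}"
                )
            object.__setattr__(self, "length_bound", lb)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


def satisfies_node_constraint(pattern_node: PatternNode, data_node: DataNode) -> bool:
    """Role match plus trust-impact-factor membership (the node-level rule
    shared by candidate selection and path-endpoint checks)."""
    return (
        data_node.role == pattern_node.role
        and pattern_node.dt_membership.satisfied_by(data_node.dt)
    )


class _BaseGraph:
    """Shared node/edge bookkeeping for data and pattern graphs."""

    _node_cls: type
    _edge_cls: type

    def __init__(self, nodes: Iterable = (), edges: Iterable = ()) -> None:
        self.nodes: dict[str, object] = {}
        self.edges: dict[tuple[str, str], object] = {}
        self._succ: dict[str, set[str]] = {}
        self._pred: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    directed = True

    def add_node(self, node) -> None:
        if node.id in self.nodes:
            raise GraphValidationError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        self._succ.setdefault(node.id, set())
        self._pred.setdefault(node.id, set())

    def add_edge(self, edge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise GraphValidationError(
                    f"edge ({edge.source!r}, {edge.target!r}) references missing node "
                    f"{endpoint!r}"
                )
        if edge.key in self.edges:
            raise GraphValidationError(
                f"parallel edge ({edge.source!r}, {edge.target!r}): the graph is simple, "
                "at most one edge per ordered node pair"
            )
        self.edges[edge.key] = edge
        self._succ[edge.source].add(edge.target)
        self._pred[edge.target].add(edge.source)

    def successors(self, node_id: str) -> list[str]:
        return sorted(self._succ[node_id])

    def predecessors(self, node_id: str) -> list[str]:
        return sorted(self._pred[node_id])

    def node(self, node_id: str):
        return self.nodes[node_id]

    def edge(self, source: str, target: str):
        return self.edges[(source, target)]

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return (
            type(self) is type(other)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"{type(self).__name__}(|V|={len(self.nodes)}, |E|={len(self.edges)})"


class DataGraph(_BaseGraph):
    """Simple directed graph of :class:`DataNode` / :class:`DataEdge`."""

    _node_cls = DataNode
    _edge_cls = DataEdge

    def validate(self) -> "DataGraph":
        """Re-check structural invariants; attribute ranges are enforced on
        construction of nodes and edges."""
        for (s, t) in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise GraphValidationError(f"edge ({s!r}, {t!r}) has a dangling endpoint")
        return self

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(kind="data")
        for n in self.nodes.values():
            g.add_node(n.id, role=str(n.role), name=n.name, dt=n.dt)
        for e in self.edges.values():
            g.add_edge(e.source, e.target, dt_trust=e.dt_trust, dc=e.dc, cv=e.cv)
        return g


class PatternGraph(_BaseGraph):
    """Directed acyclic query graph of :class:`PatternNode` / :class:`PatternEdge`."""

    _node_cls = PatternNode
    _edge_cls = PatternEdge

    def validate(self) -> "PatternGraph":
        order: list[str] = []
        indeg = {u: len(self._pred[u]) for u in self.nodes}
        ready = sorted(u for u, d in indeg.items() if d == 0)
        while ready:
            u = ready.pop(0)
            order.append(u)
            for w in self.successors(u):
                indeg[w] -= 1
                if indeg[w] == 0:
                    ready.append(w)
            ready.sort()
        if len(order) != len(self.nodes):
            raise NotADAGError("pattern graph contains a directed cycle")
        return self

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(kind="pattern")
        for n in self.nodes.values():
            g.add_node(
                n.id,
                role=str(n.role),
                dt_threshold=n.dt_membership.threshold,
                dt_function=n.dt_membership.function_id,
            )
        for e in self.edges.values():
            g.add_edge(
                e.source,
                e.target,
                dt_threshold=e.dt_membership.threshold,
                dt_function=e.dt_membership.function_id,
                dc_threshold=e.dc_membership.threshold,
                dc_function=e.dc_membership.function_id,
                cv_threshold=e.cv_membership.threshold,
                cv_function=e.cv_membership.function_id,
                length_bound=-1 if e.length_bound is None else int(e.length_bound),
            )
        return g


Graph = Union[DataGraph, PatternGraph]

# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_DATA_NODE_KEYS = ("id", "role", "name", "dt")
_DATA_EDGE_KEYS = ("source", "target", "dt_trust", "dc", "cv")
_PATTERN_NODE_KEYS = ("id", "role", "dt_threshold", "dt_function")
_PATTERN_EDGE_KEYS = (
    "source",
    "target",
    "dt_threshold",
    "dt_function",
    "dc_threshold",
    "dc_function",
    "cv_threshold",
    "cv_function",
    "length_bound",
)


def _infer_format(path: Path, fmt: Union[str, None]) -> str:
    if fmt is not None:
        if fmt not in ("json", "graphml", "csv"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".graphml":
        return "graphml"
    if suffix in ("", ".csv") or path.is_dir():
        return "csv"
    raise ValueError(f"cannot infer graph format from {path}")


def _get(record: Mapping, key: str, where: str):
    try:
        return record[key]
    except (KeyError, TypeError):
        raise ParseError(f"{where}: missing required key {key!r} in record {record!r}") from None


def _membership(record: Mapping, prefix: str) -> MembershipSpec:
    return MembershipSpec(
        threshold=float(record.get(f"{prefix}_threshold", 0.0)),
        function_id=str(record.get(f"{prefix}_function", "identity")),
    )


def _data_graph_from_records(nodes: Iterable[Mapping], edges: Iterable[Mapping]) -> DataGraph:
    g = DataGraph()
    for i, rec in enumerate(nodes):
        extras = {k: v for k, v in rec.items() if k not in _DATA_NODE_KEYS}
        g.add_node(
            DataNode(
                id=str(_get(rec, "id", f"node record {i}")),
                role=str(_get(rec, "role", f"node record {i}")),
                name=str(rec.get("name", "")),
                dt=float(rec.get("dt", 0.0)),
                extras=extras,
            )
        )
    for i, rec in enumerate(edges):
        extras = {k: v for k, v in rec.items() if k not in _DATA_EDGE_KEYS}
        g.add_edge(
            DataEdge(
                source=str(_get(rec, "source", f"edge record {i}")),
                target=str(_get(rec, "target", f"edge record {i}")),
                dt_trust=float(rec.get("dt_trust", 0.0)),
                dc=float(rec.get("dc", 0.0)),
                cv=float(rec.get("cv", 0.0)),
                extras=extras,
            )
        )
    return g.validate()


def _pattern_graph_from_records(nodes: Iterable[Mapping], edges: Iterable[Mapping]) -> PatternGraph:
    g = PatternGraph()
    for i, rec in enumerate(nodes):
        g.add_node(
            PatternNode(
                id=str(_get(rec, "id", f"pattern node record {i}")),
                role=str(_get(rec, "role", f"pattern node record {i}")),
                dt_membership=_membership(rec, "dt"),
            )
        )
    for i, rec in enumerate(edges):
        lb = rec.get("length_bound", 2)
        if lb in (None, "", "*"):
            length_bound = None
        else:
            length_bound = int(lb)
            if length_bound < 0:  # -1 is the unbounded sentinel in GraphML/CSV
                length_bound = None
        g.add_edge(
            PatternEdge(
                source=str(_get(rec, "source", f"pattern edge record {i}")),
                target=str(_get(rec, "target", f"pattern edge record {i}")),
                dt_membership=_membership(rec, "dt"),
                dc_membership=_membership(rec, "dc"),
                cv_membership=_membership(rec, "cv"),
                length_bound=length_bound,
            )
        )
    return g.validate()


def _read_json(path: Path) -> Graph:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "nodes" not in payload or "edges" not in payload:
        raise ParseError(f"{path}: expected an object with 'nodes' and 'edges' arrays")
    kind = payload.get("kind")
    if kind is None:
        pattern_keys = {"dt_threshold", "dc_threshold", "cv_threshold", "length_bound"}
        records = list(payload["nodes"]) + list(payload["edges"])
        kind = "pattern" if any(pattern_keys & set(r) for r in records) else "data"
    if kind == "pattern":
        return _pattern_graph_from_records(payload["nodes"], payload["edges"])
    if kind == "data":
        return _data_graph_from_records(payload["nodes"], payload["edges"])
    raise ParseError(f"{path}: unknown graph kind {kind!r}")


def _write_json(graph: Graph, path: Path) -> None:
    if isinstance(graph, DataGraph):
        payload = {
            "kind": "data",
            "directed": True,
            "nodes": [
                {**dict(n.extras), "id": n.id, "role": str(n.role), "name": n.name, "dt": n.dt}
                for n in sorted(graph.nodes.values(), key=lambda n: n.id)
            ],
            "edges": [
                {
                    **dict(e.extras),
                    "source": e.source,
                    "target": e.target,
                    "dt_trust": e.dt_trust,
                    "dc": e.dc,
                    "cv": e.cv,
                }
                for e in sorted(graph.edges.values(), key=lambda e: e.key)
            ],
        }
    else:
        payload = {
            "kind": "pattern",
            "directed": True,
            "nodes": [
                {
                    "id": n.id,
                    "role": str(n.role),
                    "dt_threshold": n.dt_membership.threshold,
                    "dt_function": n.dt_membership.function_id,
                }
                for n in sorted(graph.nodes.values(), key=lambda n: n.id)
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "dt_threshold": e.dt_membership.threshold,
                    "dt_function": e.dt_membership.function_id,
                    "dc_threshold": e.dc_membership.threshold,
                    "dc_function": e.dc_membership.function_id,
                    "cv_threshold": e.cv_membership.threshold,
                    "cv_function": e.cv_membership.function_id,
                    "length_bound": e.length_bound,
                }
                for e in sorted(graph.edges.values(), key=lambda e: e.key)
            ],
        }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_graphml(path: Path) -> Graph:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat errors vary
        raise ParseError(f"{path}: not valid GraphML ({exc})") from exc
    kind = g.graph.get("kind", "data")
    nodes = [{"id": str(nid), **attrs} for nid, attrs in sorted(g.nodes(data=True))]
    edges = [
        {"source": str(s), "target": str(t), **attrs} for s, t, attrs in sorted(g.edges(data=True))
    ]
    if kind == "pattern":
        return _pattern_graph_from_records(nodes, edges)
    return _data_graph_from_records(nodes, edges)


def _write_graphml(graph: Graph, path: Path) -> None:
    g = graph.to_networkx()
    # GraphML cannot represent empty-string data cleanly across parsers; omit
    # blank names and restore the default on read.
    for _, attrs in g.nodes(data=True):
        if attrs.get("name") == "":
            del attrs["name"]
    nx.write_graphml(g, path)


def _read_csv(path: Path) -> Graph:
    nodes_path, edges_path = path / "nodes.csv", path / "edges.csv"
    for p in (nodes_path, edges_path):
        if not p.exists():
            raise ParseError(f"{p}: missing (CSV graphs are a nodes.csv/edges.csv pair)")
    with nodes_path.open(newline="") as fh:
        node_records = list(csv.DictReader(fh))
    with edges_path.open(newline="") as fh:
        edge_records = list(csv.DictReader(fh))
    headers: set[str] = set()
    for rec in node_records + edge_records:
        headers |= set(rec)
    if {"dt_threshold", "length_bound"} & headers:
        return _pattern_graph_from_records(node_records, edge_records)
    return _data_graph_from_records(node_records, edge_records)


def _write_csv(graph: Graph, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(graph, DataGraph):
        node_rows = [
            (n.id, str(n.role), n.name, repr(n.dt))
            for n in sorted(graph.nodes.values(), key=lambda n: n.id)
        ]
        edge_rows = [
            (e.source, e.target, repr(e.dt_trust), repr(e.dc), repr(e.cv))
            for e in sorted(graph.edges.values(), key=lambda e: e.key)
        ]
        node_header, edge_header = _DATA_NODE_KEYS, _DATA_EDGE_KEYS
    else:
        node_rows = [
            (n.id, str(n.role), repr(n.dt_membership.threshold), n.dt_membership.function_id)
            for n in sorted(graph.nodes.values(), key=lambda n: n.id)
        ]
        edge_rows = [
            (
                e.source,
                e.target,
                repr(e.dt_membership.threshold),
                e.dt_membership.function_id,
                repr(e.dc_membership.threshold),
                e.dc_membership.function_id,
                repr(e.cv_membership.threshold),
                e.cv_membership.function_id,
                "" if e.length_bound is None else str(e.length_bound),
            )
            for e in sorted(graph.edges.values(), key=lambda e: e.key)
        ]
        node_header, edge_header = _PATTERN_NODE_KEYS, _PATTERN_EDGE_KEYS
    with (path / "nodes.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(node_header)
        w.writerows(node_rows)
    with (path / "edges.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(edge_header)
        w.writerows(edge_rows)


def read_graph(path: Union[str, Path], format: Union[str, None] = None) -> Graph:
    """Read a data or pattern graph from ``path``.

    The format (``json``, ``graphml`` or ``csv``) is inferred from the path
    suffix when not given; ``csv`` expects a directory holding ``nodes.csv``
    and ``edges.csv``.  The graph kind is detected from the file content.
    All invariants are validated; a violation raises
    :class:`~kgmatch.errors.GraphValidationError`, a malformed file raises
    :class:`~kgmatch.errors.ParseError` naming the offending record.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt != "csv" and not path.exists():
        raise FileNotFoundError(path)
    return {"json": _read_json, "graphml": _read_graphml, "csv": _read_csv}[fmt](path)


def write_graph(graph: Graph, path: Union[str, Path], format: Union[str, None] = None) -> None:
    """Write ``graph`` to ``path``; inverse of :func:`read_graph` (round-trip
    preserves ids, roles and attributes)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    {"json": _write_json, "graphml": _write_graphml, "csv": _write_csv}[fmt](graph, path)
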