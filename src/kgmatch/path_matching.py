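"""Bounded-length path matching for a single pattern edge.

A pattern edge ``(u, u')`` does not require a single data edge: it matches
any *simple* directed path in the data graph from a candidate of ``u`` to a
node satisfying ``u'``'s constraints, with at most ``length_bound`` hops
(bounded simulation).  Intermediate nodes are unconstrained — only the
endpoint is checked — so a path may pass through nodes of any role.

Edge attributes are aggregated along the path: the treatment-cycle value
``dc`` and the cost-benefit value ``cv`` multiply (both are efficiencies
that compound hop by hop), while the trust value ``dt_trust`` averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

from .errors import InvalidPathError
from .graph_model import DataGraph, PatternEdge, PatternNode, satisfies_node_constraint

__all__ = ["PathMatch", "PathList", "aggregate_path_attributes", "enumerate_matching_paths"]


@dataclass(frozen=True)
class PathMatch:
    """A simple data path matching one pattern edge, with its aggregates."""

    pattern_edge: tuple[str, str]
    node_sequence: tuple[str, ...]
    a_dt: float  # mean of edge dt_trust values
    a_dc: float  # product of edge dc values
    a_cv: float  # product of edge cv values

    def __post_init__(self) -> None:
        if len(self.node_sequence) < 2:
            raise InvalidPathError(
                f"path {self.node_sequence!r} must contain at least one hop"
            )
        if len(set(self.node_sequence)) != len(self.node_sequence):
            raise InvalidPathError(f"path {self.node_sequence!r} revisits a node")
        object.__setattr__(self, "node_sequence", tuple(self.node_sequence))

    @property
    def hops(self) -> int:
        return len(self.node_sequence) - 1

    @property
    def key(self) -> tuple[str, ...]:
        """Identity of the path within selection/ranking structures."""
        return self.node_sequence


@dataclass
class PathList:
    """All matching paths for one pattern edge sharing a source data node.

    ``endpoint_pair`` is ``(v, v')``; a ``None`` second component marks a
    pooled list covering several endpoints (used when path selection is to be
    run across the whole pattern edge rather than per endpoint).
    """

    endpoint_pair: tuple[str, Union[str, None]]
    pattern_edge: tuple[str, str]
    paths: list[PathMatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        v, v_prime = self.endpoint_pair
        for p in self.paths:
            if p.pattern_edge != self.pattern_edge:
                raise InvalidPathError(
                    f"path {p.node_sequence!r} belongs to pattern edge {p.pattern_edge!r}, "
                    f"not {self.pattern_edge!r}"
                )
            if p.node_sequence[0] != v or (v_prime is not None and p.node_sequence[-1] != v_prime):
                raise InvalidPathError(
                    f"path {p.node_sequence!r} does not share endpoint pair "
                    f"{self.endpoint_pair!r}"
                )


def aggregate_path_attributes(
    node_sequence: Sequence[str], g: DataGraph
) -> tuple[float, float, float]:
    """Aggregate edge attributes along ``node_sequence``.

    Returns ``(a_dt, a_dc, a_cv)``: the mean of ``dt_trust`` and the products
    of ``dc`` and ``cv`` over the path's edges.  Each lies in [0, 1].
    Raises :class:`InvalidPathError` for sequences with fewer than two nodes
    or with a missing edge.
    """
    seq = tuple(node_sequence)
    if len(seq) < 2:
        raise InvalidPathError(f"path {seq!r} must contain at least one hop")
    dts, dc, cv = [], 1.0, 1.0
    for s, t in zip(seq, seq[1:]):
        if (s, t) not in g.edges:
            raise InvalidPathError(f"path {seq!r}: edge ({s!r}, {t!r}) not in the data graph")
        e = g.edges[(s, t)]
        dts.append(e.dt_trust)
        dc *= e.dc
        cv *= e.cv
    return (math.fsum(dts) / len(dts), dc, cv)


def enumerate_matching_paths(
    v: str,
    pe: PatternEdge,
    g: DataGraph,
    target_constraint: PatternNode,
) -> list[PathList]:
    """Enumerate all bounded simple paths from ``v`` matching ``pe``.

    Breadth-first expansion from ``v``: every simple path with at most
    ``pe.length_bound`` hops (all hops when unbounded) whose terminal node
    satisfies ``target_constraint`` (role + dt membership) is collected.
    Results are grouped per endpoint into :class:`PathList`\\ s, in
    deterministic order: endpoints id-sorted, paths within a group ordered by
    BFS level then id-sorted expansion.
    """
    if v not in g.nodes:
        raise InvalidPathError(f"start node {v!r} not in the data graph")
    max_hops = pe.length_bound if pe.length_bound is not None else max(len(g.nodes) - 1, 1)
    by_endpoint: dict[str, list[PathMatch]] = {}
    frontier: list[tuple[str, ...]] = [(v,)]
    for _level in range(max_hops):
        nxt: list[tuple[str, ...]] = []
        for path in frontier:
            for w in g.successors(path[-1]):
                if w in path:
                    continue  # simple paths only
                extended = path + (w,)
                nxt.append(extended)
                if satisfies_node_constraint(target_constraint, g.nodes[w]):
                    a_dt, a_dc, a_cv = aggregate_path_attributes(extended, g)
                    by_endpoint.setdefault(w, []).append(
                        PathMatch(pe.key, extended, a_dt, a_dc, a_cv)
                    )
        if not nxt:
            break
        frontier = nxt
    return [
        PathList(endpoint_pair=(v, w), pattern_edge=pe.key, paths=by_endpoint[w])
        for w in sorted(by_endpoint)
    ]
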