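"""Synthetic consultation-style knowledge graphs and bundled fixtures.

The generator emulates the structure of lung-cancer consultation graphs:
five participant roles (AP, TI, TC, PM, TM), directed edges restricted by
default to the role pairs of the reference consultation pattern (plus
treatment-to-treatment edges, which occur in practice when one treatment
feeds another), and node/edge attributes drawn independently from a
configurable distribution on [0, 1] — uniform by default, mirroring graphs
whose attribute values are randomly generated.  Edge density is a free
parameter: published corpus sizes for this graph family are contradictory,
so no particular node/edge ratio is baked in.

Optionally, a number of *planted embeddings* of a pattern are injected:
disjoint node tuples wired with every pattern edge, their attributes raised
just above the pattern's thresholds, guaranteeing recoverable matches for
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Union

import numpy as np

from .errors import GraphValidationError
from .graph_model import (
    DataEdge,
    DataGraph,
    DataNode,
    MembershipSpec,
    PatternEdge,
    PatternGraph,
    PatternNode,
    read_graph,
)
from .mc_filter import MCConfig
from .path_matching import PathList, PathMatch

__all__ = [
    "DEFAULT_ROLE_PAIRS",
    "SynthSpec",
    "generate_data_graph",
    "reference_pattern",
    "consultation_pattern",
    "consultation_data_graph",
    "worked_example_paths",
]

#: Role pairs wired by default: the reference pattern's pairs plus (TM, TM).
DEFAULT_ROLE_PAIRS = (
    ("AP", "TI"),
    ("AP", "TC"),
    ("TI", "TC"),
    ("PM", "TC"),
    ("TC", "TM"),
    ("TM", "TM"),
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic data graph.

    ``edge_probability`` is either one probability in (0, 1] for every
    permitted role pair or a mapping per pair.  ``attribute_distribution``
    is ``("uniform",)`` or ``("beta", a, b)``.
    """

    nodes_per_role: Mapping[str, int]
    edge_probability: Union[float, Mapping[tuple[str, str], float]] = 0.1
    attribute_distribution: tuple = ("uniform",)
    planted_embeddings: int = 0
    seed: int = 0
    allowed_role_pairs: Union[tuple[tuple[str, str], ...], None] = None
    pattern: Union[PatternGraph, None] = None  # planting target; default reference pattern

    def __post_init__(self) -> None:
        for role, count in self.nodes_per_role.items():
            if count < 0:
                raise GraphValidationError(f"node count for role {role!r} must be >= 0")
        probs = (
            self.edge_probability.values()
            if isinstance(self.edge_probability, Mapping)
            else [self.edge_probability]
        )
        for prob in probs:
            if not 0.0 < prob <= 1.0:
                raise GraphValidationError(f"edge probability must lie in (0, 1], got {prob}")
        if self.planted_embeddings < 0:
            raise GraphValidationError("planted_embeddings must be >= 0")
        if self.attribute_distribution[0] not in ("uniform", "beta"):
            raise GraphValidationError(
                f"unknown attribute distribution {self.attribute_distribution!r}"
            )

    def probability(self, pair: tuple[str, str]) -> float:
        if isinstance(self.edge_probability, Mapping):
            return float(self.edge_probability.get(pair, 0.0))
        return float(self.edge_probability)


def _draw(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    if dist[0] == "uniform":
        return rng.uniform(0.0, 1.0, size)
    _, a, b = dist
    return rng.beta(a, b, size)


def generate_data_graph(spec: SynthSpec) -> DataGraph:
    """Generate a role-structured random data graph; reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    node_ids: dict[str, list[str]] = {}
    node_dt: dict[str, float] = {}
    for role in sorted(spec.nodes_per_role):
        count = spec.nodes_per_role[role]
        ids = [f"{role}{i:03d}" for i in range(count)]
        node_ids[role] = ids
        for nid, dt in zip(ids, _draw(rng, spec.attribute_distribution, count)):
            node_dt[nid] = float(dt)
    node_roles = {nid: role for role, ids in node_ids.items() for nid in ids}

    pairs = spec.allowed_role_pairs if spec.allowed_role_pairs is not None else DEFAULT_ROLE_PAIRS
    edge_attrs: dict[tuple[str, str], list[float]] = {}
    for r1, r2 in sorted(set(pairs)):
        prob = spec.probability((r1, r2))
        sources, targets = node_ids.get(r1, []), node_ids.get(r2, [])
        if not sources or not targets:
            continue
        hits = rng.random((len(sources), len(targets))) < prob
        attrs = _draw(rng, spec.attribute_distribution, 3 * len(sources) * len(targets))
        k = 0
        for i, u in enumerate(sources):
            for j, v in enumerate(targets):
                if u != v and hits[i, j]:
                    edge_attrs[(u, v)] = [float(a) for a in attrs[k : k + 3]]
                k += 3

    if spec.planted_embeddings:
        _plant(spec, node_ids, node_roles, node_dt, edge_attrs)

    g = DataGraph()
    for nid in sorted(node_dt):
        g.add_node(DataNode(id=nid, role=node_roles[nid], name=nid, dt=node_dt[nid]))
    for (u, v) in sorted(edge_attrs):
        dt_trust, dc, cv = edge_attrs[(u, v)]
        g.add_edge(DataEdge(source=u, target=v, dt_trust=dt_trust, dc=dc, cv=cv))
    return g.validate()


def _plant(
    spec: SynthSpec,
    node_ids: dict[str, list[str]],
    node_roles: dict[str, str],
    node_dt: dict[str, float],
    edge_attrs: dict[tuple[str, str], list[float]],
) -> None:
    """Inject ``spec.planted_embeddings`` disjoint pattern occurrences,
    raising attributes to 0.1 above each threshold so recovery is guaranteed
    for thresholds at or below the planted floor."""
    pattern = spec.pattern if spec.pattern is not None else reference_pattern()
    by_role: dict[str, list] = {}
    for pn in sorted(pattern.nodes.values(), key=lambda n: n.id):
        by_role.setdefault(str(pn.role), []).append(pn)
    for role, pns in by_role.items():
        needed = spec.planted_embeddings * len(pns)
        if len(node_ids.get(role, [])) < needed:
            raise GraphValidationError(
                f"planting {spec.planted_embeddings} embeddings needs {needed} nodes of "
                f"role {role!r}, spec provides {len(node_ids.get(role, []))}"
            )
    for j in range(spec.planted_embeddings):
        binding: dict[str, str] = {}
        for role, pns in by_role.items():
            for slot, pn in enumerate(pns):
                binding[pn.id] = node_ids[role][j * len(pns) + slot]
        for pn in pattern.nodes.values():
            nid = binding[pn.id]
            floor = min(1.0, pn.dt_membership.threshold + 0.1)
            node_dt[nid] = max(node_dt[nid], floor)
        for pe in pattern.edges.values():
            u, v = binding[pe.source], binding[pe.target]
            attrs = edge_attrs.setdefault((u, v), [0.0, 0.0, 0.0])
            for idx, spec_m in enumerate(
                (pe.dt_membership, pe.dc_membership, pe.cv_membership)
            ):
                attrs[idx] = max(attrs[idx], min(1.0, spec_m.threshold + 0.1))


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------


def reference_pattern(
    node_threshold: float = 0.3,
    edge_threshold: float = 0.2,
    length_bound: Union[int, None] = 2,
) -> PatternGraph:
    """The five-role consultation pattern.

    Attending physician (AP) consults a testing instrument (TI) and a tumor
    type (TC); the instrument confirms the tumor type; nursing staff (PM)
    supports it; the tumor type leads to a treatment (TM).  All edges share
    one hop bound and one threshold per aggregate; nodes share one
    trust-impact threshold.
    """
    node_m = MembershipSpec(threshold=node_threshold)
    edge_m = MembershipSpec(threshold=edge_threshold)
    g = PatternGraph()
    for role in ("AP", "TI", "TC", "PM", "TM"):
        g.add_node(PatternNode(id=role, role=role, dt_membership=node_m))
    for src, tgt in (("AP", "TI"), ("AP", "TC"), ("TI", "TC"), ("PM", "TC"), ("TC", "TM")):
        g.add_edge(
            PatternEdge(
                source=src,
                target=tgt,
                dt_membership=edge_m,
                dc_membership=edge_m,
                cv_membership=edge_m,
                length_bound=length_bound,
            )
        )
    return g.validate()


def _load_packaged(name: str):
    with resources.as_file(resources.files("kgmatch").joinpath("data", name)) as path:
        return read_graph(path, format="json")


def consultation_pattern() -> PatternGraph:
    """The reference pattern as shipped in the packaged JSON fixture."""
    return _load_packaged("consultation_pattern.json")


def consultation_data_graph() -> DataGraph:
    """A six-participant toy consultation graph (packaged JSON fixture).

    One attending physician (Helen), one testing instrument (RATS), one
    tumor type (SLCLIA), one nurse (Meg) and two treatments (Drug,
    Operation), wired like the worked matching examples.  Attribute values
    are synthetic, chosen to pass the reference pattern's thresholds.
    """
    return _load_packaged("consultation_data.json")


def worked_example_paths() -> tuple[PathList, MCConfig]:
    """The three-path selection walkthrough for pattern edge (TC, TM).

    Returns one pooled :class:`PathList` holding the paths
    (SLCLIA, Drug), (SLCLIA, Operation) and (SLCLIA, Drug, Operation) with
    aggregates {0.5, 0.7, 0.5}, {0.5, 0.6, 0.6} and {0.5, 0.48, 0.54}, plus
    the matching configuration (1000 draws, top-2, two-decimal proportions).
    The aggregates are stored directly: jointly they are not realizable by
    any single attribute assignment on the shared edges, so they document the
    selection arithmetic, not a concrete graph.
    """
    pe = ("TC", "TM")
    paths = [
        PathMatch(pe, ("SLCLIA", "Drug"), 0.5, 0.7, 0.5),
        PathMatch(pe, ("SLCLIA", "Operation"), 0.5, 0.6, 0.6),
        PathMatch(pe, ("SLCLIA", "Drug", "Operation"), 0.5, 0.48, 0.54),
    ]
    pooled = PathList(endpoint_pair=("SLCLIA", None), pattern_edge=pe, paths=paths)
    return pooled, MCConfig(n_draws=1000, top_n=2, rounding_decimals=2)
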