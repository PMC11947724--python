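"""Full pattern matching: recursive drivers, verifier and summary statistic.

Three matchers share one driver:

* ``tem_match`` — edge-level Monte Carlo: deterministic node candidates,
  roulette selection of candidate paths per pattern edge.
* ``thm_match`` — hologram variant: roulette selection for candidate nodes
  *and* candidate paths.
* ``baseline_match`` — exhaustive reference: no roulette anywhere, every
  membership-passing path is kept.  It serves as the oracle the stochastic
  matchers are tested against; with vacuous Monte-Carlo settings (``top_n``
  at least every pool size) the stochastic matchers coincide with it.

The match relation is simulation-style, not injective: a pattern node may
bind several data nodes and distinct pattern nodes may share a data node.
Per candidate of the start pattern node (the lexicographically smallest
in-degree-0 node), pattern edges are processed in topological order of their
source; afterwards bindings without path support are pruned to a fixed
point.  Every surviving subgraph satisfies the matching relation, which
``verify_match`` checks independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from ._rng import CountingGenerator
from .candidate_selection import get_node_candidates, get_node_candidates_mc
from .errors import KGMatchError, NotADAGError
from .graph_model import (
    DataGraph,
    PatternGraph,
    satisfies_node_constraint,
)
from .mc_filter import MCConfig, apply_membership_constraints, edge_attribute_filter
from .path_matching import PathMatch, aggregate_path_attributes, enumerate_matching_paths

__all__ = [
    "TopoPlan",
    "MatchSubgraph",
    "MatchResult",
    "MeanValSummary",
    "VerificationReport",
    "topological_plan",
    "tem_match",
    "thm_match",
    "baseline_match",
    "verify_match",
    "meanval_statistic",
    "result_to_dict",
    "result_from_dict",
]


@dataclass(frozen=True)
class TopoPlan:
    """Topological order of the pattern nodes plus its in-degree-0 sources."""

    order: tuple[str, ...]
    sources: tuple[str, ...]
    start_node: str


@dataclass
class MatchSubgraph:
    """One matched subgraph: node bindings plus the matched paths per edge."""

    assignment: dict[str, frozenset[str]]
    edge_paths: dict[tuple[str, str], tuple[PathMatch, ...]]

    def identity(self) -> tuple:
        """Canonical form used for deduplication."""
        return (
            tuple(sorted((u, tuple(sorted(vs))) for u, vs in self.assignment.items())),
            tuple(
                sorted(
                    (pe, p.node_sequence)
                    for pe, paths in self.edge_paths.items()
                    for p in paths
                )
            ),
        )

    def all_paths(self) -> list[PathMatch]:
        return [p for paths in self.edge_paths.values() for p in paths]


@dataclass
class MatchResult:
    """All matched subgraphs of one run, with its configuration snapshot."""

    subgraphs: list[MatchSubgraph]
    algorithm: str  # "tem" | "thm" | "baseline"
    config: MCConfig
    seed: Union[int, None]
    draws_consumed: int = 0

    def __len__(self) -> int:
        return len(self.subgraphs)


@dataclass(frozen=True)
class MeanValSummary:
    """Mean of the dc and cv aggregates over a sample of matched paths."""

    meanval: float
    values: tuple[float, ...]  # the pooled a_dc and a_cv values sampled
    n_paths: int


@dataclass(frozen=True)
class VerificationReport:
    ok: bool
    violations: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.ok


def topological_plan(p: PatternGraph) -> TopoPlan:
    """Kahn ordering with lexicographic tie-break; raises on cycles.

    ``start_node`` is the lexicographically smallest in-degree-0 node; the
    drivers enumerate its candidates in the outer loop and seed the remaining
    sources inside the recursion.
    """
    indeg = {u: len(p._pred[u]) for u in p.nodes}
    sources = tuple(sorted(u for u, d in indeg.items() if d == 0))
    ready = list(sources)
    order: list[str] = []
    while ready:
        u = ready.pop(0)
        order.append(u)
        for w in p.successors(u):
            indeg[w] -= 1
            if indeg[w] == 0:
                ready.append(w)
        ready.sort()
    if len(order) != len(p.nodes):
        raise NotADAGError("pattern graph contains a directed cycle")
    if not order:
        raise KGMatchError("pattern graph is empty")
    return TopoPlan(tuple(order), sources, sources[0])


def _ordered_pattern_edges(p: PatternGraph, plan: TopoPlan):
    pos = {u: i for i, u in enumerate(plan.order)}
    return sorted(p.edges.values(), key=lambda e: (pos[e.source], pos[e.target], e.target))


def _prune_to_fixed_point(
    bindings: dict[str, set[str]],
    edge_paths: dict[tuple[str, str], list[PathMatch]],
    p: PatternGraph,
) -> bool:
    """Iteratively drop unsupported bindings and orphaned paths.

    A binding of data node ``v`` to pattern node ``u`` needs, for every
    pattern edge incident to ``u``, at least one stored path in which ``v``
    plays the matching endpoint; paths in turn need both endpoints bound.
    Returns True when every pattern node keeps a binding and every pattern
    edge keeps a path.
    """
    changed = True
    while changed:
        changed = False
        for pe_key, paths in edge_paths.items():
            src, tgt = pe_key
            kept = [
                q
                for q in paths
                if q.node_sequence[0] in bindings.get(src, set())
                and q.node_sequence[-1] in bindings.get(tgt, set())
            ]
            if len(kept) != len(paths):
                edge_paths[pe_key] = kept
                changed = True
        for u in p.nodes:
            vs = set(bindings.get(u, set()))
            for pe_key in edge_paths:
                src, tgt = pe_key
                if src == u:
                    vs = {v for v in vs if any(q.node_sequence[0] == v for q in edge_paths[pe_key])}
                if tgt == u:
                    vs = {v for v in vs if any(q.node_sequence[-1] == v for q in edge_paths[pe_key])}
            if vs != bindings.get(u, set()):
                bindings[u] = vs
                changed = True
    return all(bindings.get(u) for u in p.nodes) and all(edge_paths[k] for k in edge_paths)


def _run(
    g: DataGraph,
    p: PatternGraph,
    cfg: MCConfig,
    limit: Union[int, None],
    algorithm: str,
) -> MatchResult:
    plan = topological_plan(p)
    rng = CountingGenerator(cfg.seed)

    def select(u):
        if algorithm == "thm":
            return get_node_candidates_mc(
                p.nodes[u], g, cfg, rng, apply_dt_threshold=cfg.node_dt_threshold
            )
        return get_node_candidates(p.nodes[u], g)

    edge_order = _ordered_pattern_edges(p, plan)
    incident = {u: False for u in p.nodes}
    for e in edge_order:
        incident[e.source] = incident[e.target] = True
    isolated = [u for u, has in incident.items() if not has and u != plan.start_node]

    results: list[MatchSubgraph] = []
    seen: set[tuple] = set()
    for v_s in select(plan.start_node).members:
        bindings: dict[str, set[str]] = {plan.start_node: {v_s}}
        edge_paths: dict[tuple[str, str], list[PathMatch]] = {}
        dead = False
        for pe in edge_order:
            if pe.source not in bindings:
                # a non-start source node seen for the first time
                bindings[pe.source] = set(select(pe.source).members)
            stored: list[PathMatch] = []
            for v_c in sorted(bindings[pe.source]):
                pathlists = enumerate_matching_paths(v_c, pe, g, p.nodes[pe.target])
                if algorithm == "baseline":
                    for pl in pathlists:
                        stored.extend(apply_membership_constraints(pl.paths, pe))
                else:
                    for pl in edge_attribute_filter(pathlists, pe, cfg, rng):
                        stored.extend(pl.paths)
            edge_paths[pe.key] = stored
            bindings.setdefault(pe.target, set()).update(q.node_sequence[-1] for q in stored)
            if not stored:
                dead = True
                break
        if dead:
            continue
        for u in isolated:
            bindings[u] = set(select(u).members)
        if not _prune_to_fixed_point(bindings, edge_paths, p):
            continue
        sub = MatchSubgraph(
            assignment={u: frozenset(vs) for u, vs in bindings.items()},
            edge_paths={k: tuple(v) for k, v in edge_paths.items()},
        )
        ident = sub.identity()
        if ident in seen:
            continue
        seen.add(ident)
        results.append(sub)
        if limit is not None and len(results) >= limit:
            break
    return MatchResult(results, algorithm, cfg, cfg.seed, rng.n_drawn)


def tem_match(
    g: DataGraph,
    p: PatternGraph,
    cfg: Union[MCConfig, None] = None,
    limit: Union[int, None] = None,
) -> MatchResult:
    """Edge-level Monte-Carlo matching (deterministic node candidates,
    roulette path selection per pattern edge)."""
    return _run(g, p, cfg or MCConfig(), limit, "tem")


def thm_match(
    g: DataGraph,
    p: PatternGraph,
    cfg: Union[MCConfig, None] = None,
    limit: Union[int, None] = None,
) -> MatchResult:
    """Hologram Monte-Carlo matching (roulette selection for both candidate
    nodes and candidate paths)."""
    return _run(g, p, cfg or MCConfig(), limit, "thm")


def baseline_match(
    g: DataGraph,
    p: PatternGraph,
    limit: Union[int, None] = None,
) -> MatchResult:
    """Exhaustive matching: membership thresholds only, no Monte Carlo."""
    return _run(g, p, MCConfig(), limit, "baseline")


def verify_match(sub: MatchSubgraph, g: DataGraph, p: PatternGraph) -> VerificationReport:
    """Independently check a subgraph against the matching relation.

    Checks: (a) every pattern node is assigned; (b) each assigned node passes
    role and trust-impact membership; (c) for every pattern edge and every
    assigned source node there is a stored path of at most ``length_bound``
    hops ending at a node assigned to the target; (d) every stored path is a
    real simple path in the data graph whose recomputed aggregates match the
    stored ones and satisfy the edge memberships.
    """
    violations: list[str] = []
    for u in p.nodes:
        assigned = sub.assignment.get(u, frozenset())
        if not assigned:
            violations.append(f"pattern node {u!r} has no assigned data node")
            continue
        for v in sorted(assigned):
            if v not in g.nodes:
                violations.append(f"assigned node {v!r} (pattern {u!r}) not in data graph")
            elif not satisfies_node_constraint(p.nodes[u], g.nodes[v]):
                violations.append(
                    f"assigned node {v!r} violates the role/trust constraint of {u!r}"
                )
    for pe in p.edges.values():
        paths = sub.edge_paths.get(pe.key, ())
        if not paths:
            violations.append(f"pattern edge {pe.key!r} has no matched path")
            continue
        src_assigned = sub.assignment.get(pe.source, frozenset())
        tgt_assigned = sub.assignment.get(pe.target, frozenset())
        for q in paths:
            label = f"path {q.node_sequence!r} of edge {pe.key!r}"
            if pe.length_bound is not None and q.hops > pe.length_bound:
                violations.append(f"{label}: {q.hops} hops exceeds bound {pe.length_bound}")
            if q.node_sequence[0] not in src_assigned:
                violations.append(f"{label}: source not assigned to {pe.source!r}")
            if q.node_sequence[-1] not in tgt_assigned:
                violations.append(f"{label}: endpoint not assigned to {pe.target!r}")
            try:
                a_dt, a_dc, a_cv = aggregate_path_attributes(q.node_sequence, g)
            except KGMatchError as exc:
                violations.append(f"{label}: {exc}")
                continue
            if max(abs(a_dt - q.a_dt), abs(a_dc - q.a_dc), abs(a_cv - q.a_cv)) > 1e-9:
                violations.append(f"{label}: stored aggregates disagree with the data graph")
            if not (
                pe.dt_membership.satisfied_by(a_dt)
                and pe.dc_membership.satisfied_by(a_dc)
                and pe.cv_membership.satisfied_by(a_cv)
            ):
                violations.append(f"{label}: aggregates violate the edge memberships")
        for v in sorted(src_assigned):
            if not any(
                q.node_sequence[0] == v and q.node_sequence[-1] in tgt_assigned for q in paths
            ):
                violations.append(
                    f"assigned node {v!r} of {pe.source!r} has no supporting path on {pe.key!r}"
                )
    return VerificationReport(not violations, tuple(violations))


def meanval_statistic(
    result: MatchResult,
    sample_edges: int,
    rng: Union[np.random.Generator, None] = None,
) -> MeanValSummary:
    """Mean of the dc and cv aggregates over sampled matched paths.

    ``sample_edges`` matched paths are drawn uniformly without replacement
    across all subgraphs of the result (all of them when the sample covers
    the pool, making the statistic exact).  The summary's ``values`` hold the
    pooled per-path ``a_dc`` and ``a_cv`` values, whose spread reflects the
    diversity of the result set.
    """
    if sample_edges < 1:
        raise ValueError("sample_edges must be >= 1")
    pool = [q for sub in result.subgraphs for q in sub.all_paths()]
    if not pool:
        raise KGMatchError("cannot summarize an empty match result")
    if sample_edges >= len(pool):
        sampled = pool
    else:
        rng = rng if rng is not None else np.random.default_rng(result.seed or 0)
        idx = rng.choice(len(pool), size=sample_edges, replace=False)
        sampled = [pool[i] for i in sorted(idx)]
    values = tuple(v for q in sampled for v in (q.a_dc, q.a_cv))
    return MeanValSummary(float(np.mean(values)), values, len(sampled))


# ---------------------------------------------------------------------------
# JSON-friendly serialization of results
# ---------------------------------------------------------------------------


def _config_to_dict(cfg: MCConfig) -> dict:
    return {
        "n_draws": cfg.n_draws,
        "top_n": cfg.top_n,
        "seed": cfg.seed,
        "rounding_decimals": cfg.rounding_decimals,
        "node_dt_threshold": cfg.node_dt_threshold,
    }


def result_to_dict(result: MatchResult) -> dict:
    return {
        "algorithm": result.algorithm,
        "seed": result.seed,
        "draws_consumed": result.draws_consumed,
        "config": _config_to_dict(result.config),
        "subgraphs": [
            {
                "assignment": {u: sorted(vs) for u, vs in sub.assignment.items()},
                "edges": [
                    {
                        "source": src,
                        "target": tgt,
                        "paths": [
                            {
                                "nodes": list(q.node_sequence),
                                "a_dt": q.a_dt,
                                "a_dc": q.a_dc,
                                "a_cv": q.a_cv,
                            }
                            for q in paths
                        ],
                    }
                    for (src, tgt), paths in sorted(sub.edge_paths.items())
                ],
            }
            for sub in result.subgraphs
        ],
    }


def result_from_dict(payload: Mapping) -> MatchResult:
    cfg = MCConfig(**payload.get("config", {}))
    subgraphs = []
    for rec in payload.get("subgraphs", ()):
        assignment = {u: frozenset(vs) for u, vs in rec.get("assignment", {}).items()}
        edge_paths: dict[tuple[str, str], tuple[PathMatch, ...]] = {}
        for erec in rec.get("edges", ()):
            key = (erec["source"], erec["target"])
            edge_paths[key] = tuple(
                PathMatch(key, tuple(prec["nodes"]), prec["a_dt"], prec["a_dc"], prec["a_cv"])
                for prec in erec.get("paths", ())
            )
        subgraphs.append(MatchSubgraph(assignment, edge_paths))
    return MatchResult(
        subgraphs,
        payload.get("algorithm", "tem"),
        cfg,
        payload.get("seed"),
        payload.get("draws_consumed", 0),
    )
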