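"""Candidate data nodes for a pattern node.

Two selectors are provided.  The deterministic one keeps every unvisited
node of the right role whose trust impact factor passes the pattern node's
membership threshold.  The Monte-Carlo one (used by the hologram matcher)
runs a roulette over the role-matching nodes weighted by their trust impact
factors and keeps the ``top_n`` nodes by hit count; by default it also
applies the trust threshold so that selected nodes always satisfy the node
membership constraint, but the pure label-filter-then-roulette behaviour is
available via ``apply_dt_threshold=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, Union

from .errors import DegenerateWeightsError
from .graph_model import DataGraph, PatternNode, satisfies_node_constraint
from .mc_filter import MCConfig, build_intervals, mc_sample_counts, normalize_proportions

__all__ = ["CandidateSet", "get_node_candidates", "get_node_candidates_mc"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateSet:
    """Ordered candidate node ids for one pattern node."""

    pattern_node: str
    members: tuple[str, ...]
    provenance: str  # "deterministic" | "monte_carlo"

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"candidate members must be unique, got {self.members}")
        if self.provenance not in ("deterministic", "monte_carlo"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def get_node_candidates(
    u: PatternNode, g: DataGraph, visited: FrozenSet[str] = frozenset()
) -> CandidateSet:
    """Deterministic selection: role match + trust-impact membership.

    ``visited`` excludes nodes already bound in the current matching pass (a
    transient flag, never serialized).  Members are id-sorted; repeated calls
    are identical — no randomness is involved.
    """
    members = tuple(
        nid
        for nid in sorted(g.nodes)
        if nid not in visited and satisfies_node_constraint(u, g.nodes[nid])
    )
    return CandidateSet(u.id, members, "deterministic")


def get_node_candidates_mc(
    u: PatternNode,
    g: DataGraph,
    cfg: MCConfig,
    rng,
    visited: FrozenSet[str] = frozenset(),
    apply_dt_threshold: bool = False,
) -> CandidateSet:
    """Monte-Carlo selection: roulette over trust impact factors.

    Role-matching nodes are weighted by their ``dt`` proportion of the total,
    mapped to a cumulative partition of [0, 1] and sampled ``cfg.n_draws``
    times; the ``cfg.top_n`` nodes by hit count are kept (all nodes when the
    pool is no larger).  Hit-count ties at the boundary are broken by the
    larger ``dt``, then lexicographic id.  The roulette always runs when two
    or more candidates exist, so the sampling effort of a run reflects its
    pool sizes.  Full-precision proportions are used: display rounding would
    collapse the weights of large pools.

    With every weight zero and more candidates than ``top_n`` the
    proportional mapping is undefined and
    :class:`~kgmatch.errors.DegenerateWeightsError` is raised.
    """
    pool = [
        g.nodes[nid]
        for nid in sorted(g.nodes)
        if nid not in visited
        and g.nodes[nid].role == u.role
        and (not apply_dt_threshold or u.dt_membership.satisfied_by(g.nodes[nid].dt))
    ]
    if len(pool) <= 1:
        return CandidateSet(u.id, tuple(n.id for n in pool), "monte_carlo")
    weights = [n.dt for n in pool]
    if sum(weights) <= 0:
        if len(pool) <= cfg.top_n:
            return CandidateSet(u.id, tuple(n.id for n in pool), "monte_carlo")
        raise DegenerateWeightsError(
            f"all candidate trust impact factors for {u.id!r} are zero; "
            "proportional selection is undefined"
        )
    proportions = normalize_proportions(weights, rounding_decimals=None)
    partition = build_intervals(proportions, keys=[n.id for n in pool])
    counts = mc_sample_counts(partition, cfg, rng).counts
    ranked = sorted(pool, key=lambda n: (-counts[n.id], -n.dt, n.id))
    members = tuple(sorted(n.id for n in ranked[: cfg.top_n]))
    logger.debug(
        "node roulette for %s: pool=%d draws=%d counts=%s kept=%s",
        u.id,
        len(pool),
        cfg.n_draws,
        counts,
        members,
    )
    return CandidateSet(u.id, members, "monte_carlo")
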