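"""Edge-normalized Monte-Carlo path selection (the roulette-wheel filter).

For the candidate paths of a pattern edge, the two uncertainty-bearing
aggregates — treatment-cycle value ``a_dc`` and cost-benefit value ``a_cv`` —
are each normalized to proportions of their sum, mapped onto a contiguous
partition of [0, 1] whose interval widths equal the proportions, and sampled
with ``n_draws`` uniform variates.  Paths are ranked by hit count per
attribute; the intersection of the two top-``n`` lists survives.  Surviving
paths finally face the membership thresholds on all three aggregates
(including the deterministic trust mean ``a_dt``, which is never sampled).

Proportions may be rounded to a fixed number of decimals (default 2, the
convention used in worked examples); cumulative interval bounds are
renormalized so the last upper bound is exactly 1, so no draw is ever left
unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Sequence, Union

import numpy as np

from .errors import DegenerateWeightsError
from .graph_model import PatternEdge
from .path_matching import PathList, PathMatch

__all__ = [
    "MCConfig",
    "IntervalPartition",
    "SampleCounts",
    "normalize_proportions",
    "build_intervals",
    "mc_sample_counts",
    "select_candidate_paths",
    "apply_membership_constraints",
    "edge_attribute_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo parameters.

    n_draws
        Uniform variates per roulette (per attribute, per path group).
    top_n
        Number of top-ranked candidates kept per roulette.
    seed
        Seed for the run's random generator.
    rounding_decimals
        Decimals for displayed/partitioned proportions; ``None`` = full
        precision.
    node_dt_threshold
        Whether the Monte-Carlo node-candidate roulette also applies the
        pattern node's trust-impact threshold (the deterministic selector
        always does).  Kept on by default so that matched nodes always
        satisfy the node membership constraint.
    """

    n_draws: int = 1000
    top_n: int = 2
    seed: int = 0
    rounding_decimals: Union[int, None] = 2
    node_dt_threshold: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if self.rounding_decimals is not None and self.rounding_decimals < 0:
            raise ValueError("rounding_decimals must be None or >= 0")


@dataclass(frozen=True)
class IntervalPartition:
    """Contiguous half-open partition of [0, 1]; the last interval is closed."""

    items: tuple[tuple[Hashable, float, float], ...]

    @property
    def keys(self) -> tuple[Hashable, ...]:
        return tuple(k for k, _, _ in self.items)

    @property
    def uppers(self) -> tuple[float, ...]:
        return tuple(hi for _, _, hi in self.items)

    def bin(self, x: float) -> Hashable:
        """Map a value in [0, 1] to the key of the interval containing it."""
        idx = int(np.searchsorted(np.asarray(self.uppers), x, side="right"))
        return self.items[min(idx, len(self.items) - 1)][0]


@dataclass
class SampleCounts:
    """Hit counts per key; they always sum to the number of draws."""

    counts: dict[Hashable, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def normalize_proportions(
    values: Sequence[float], rounding_decimals: Union[int, None] = 2
) -> list[float]:
    """Normalize ``values`` by their sum, optionally rounding.

    Raises :class:`DegenerateWeightsError` when all values are zero (the
    proportional mapping is undefined) and ``ValueError`` on negatives.
    """
    values = [float(v) for v in values]
    if any(v < 0 for v in values):
        raise ValueError(f"proportional weights must be non-negative, got {values}")
    total = sum(values)
    if total <= 0:
        raise DegenerateWeightsError("all weights are zero; proportions are undefined")
    props = [v / total for v in values]
    if rounding_decimals is not None:
        props = [round(p, rounding_decimals) for p in props]
    return props


def build_intervals(
    proportions: Sequence[float], keys: Union[Sequence[Hashable], None] = None
) -> IntervalPartition:
    """Map proportions onto a cumulative partition of [0, 1].

    Item ``i`` spans ``[c_{i-1}, c_i)`` with ``c_i`` the cumulative sum of
    proportions, renormalized by their total so the final upper bound is
    exactly 1 (rounded proportions need not sum to 1 exactly).
    """
    props = [float(p) for p in proportions]
    if any(p < 0 for p in props):
        raise ValueError(f"proportions must be non-negative, got {props}")
    total = sum(props)
    if total <= 0:
        raise DegenerateWeightsError("proportions sum to zero; no partition exists")
    if keys is None:
        keys = tuple(range(len(props)))
    elif len(keys) != len(props):
        raise ValueError("keys and proportions must have equal length")
    items, lo, cum = [], 0.0, 0.0
    for key, p in zip(keys, props):
        cum += p
        hi = cum / total
        items.append((key, lo, hi))
        lo = hi
    key, lo, _ = items[-1]
    items[-1] = (key, lo, 1.0)
    return IntervalPartition(tuple(items))


def mc_sample_counts(partition: IntervalPartition, cfg: MCConfig, rng) -> SampleCounts:
    """Draw ``cfg.n_draws`` uniform variates and bin them into ``partition``.

    ``rng`` is any object with a numpy-style ``random(size)`` method; the
    result is reproducible for a fixed seed.
    """
    draws = np.asarray(rng.random(cfg.n_draws))
    uppers = np.asarray(partition.uppers)
    idx = np.minimum(np.searchsorted(uppers, draws, side="right"), len(uppers) - 1)
    binned = np.bincount(idx, minlength=len(uppers))
    return SampleCounts({key: int(n) for key, n in zip(partition.keys, binned)})


def _top_ranking(
    paths: Sequence[PathMatch], counts: SampleCounts, aggregate: str
) -> list[PathMatch]:
    """Paths sorted by hit count; count ties broken by the higher aggregate,
    then lexicographic path key."""
    return sorted(
        paths,
        key=lambda p: (-counts.counts.get(p.key, 0), -getattr(p, aggregate), p.key),
    )


def select_candidate_paths(
    paths: Union[PathList, Sequence[PathMatch]],
    counts_dc: SampleCounts,
    counts_cv: SampleCounts,
    top_n: int,
) -> list[PathMatch]:
    """Keep the intersection of the top-``n`` paths by dc hits and by cv hits.

    With ``len(paths) <= top_n`` all paths are returned unchanged.  An empty
    intersection falls back to ascending rank-sum (dc rank + cv rank, ranks
    taken in the two hit-count orderings), with ties broken by the larger
    ``a_dc * a_cv`` product, then lexicographic path key.  Output preserves
    the input path order.
    """
    plist = list(paths.paths if isinstance(paths, PathList) else paths)
    if len(plist) <= top_n:
        return plist
    rank_dc = _top_ranking(plist, counts_dc, "a_dc")
    rank_cv = _top_ranking(plist, counts_cv, "a_cv")
    top_dc = {p.key for p in rank_dc[:top_n]}
    top_cv = {p.key for p in rank_cv[:top_n]}
    crossing = top_dc & top_cv
    if crossing:
        return [p for p in plist if p.key in crossing]
    pos_dc = {p.key: i for i, p in enumerate(rank_dc)}
    pos_cv = {p.key: i for i, p in enumerate(rank_cv)}
    by_rank_sum = sorted(
        plist, key=lambda p: (pos_dc[p.key] + pos_cv[p.key], -(p.a_dc * p.a_cv), p.key)
    )
    chosen = {p.key for p in by_rank_sum[: min(top_n, len(plist))]}
    return [p for p in plist if p.key in chosen]


def apply_membership_constraints(
    paths: Sequence[PathMatch], pe: PatternEdge
) -> list[PathMatch]:
    """Keep paths whose three aggregates satisfy the pattern edge's
    membership thresholds."""
    return [
        p
        for p in paths
        if pe.dt_membership.satisfied_by(p.a_dt)
        and pe.dc_membership.satisfied_by(p.a_dc)
        and pe.cv_membership.satisfied_by(p.a_cv)
    ]


def edge_attribute_filter(
    pathlists: Sequence[PathList], pe: PatternEdge, cfg: MCConfig, rng
) -> list[PathList]:
    """Run the full roulette screening per path group.

    For each :class:`PathList` (endpoint-id order): normalize the group's dc
    and cv aggregates, build the two partitions, sample each ``cfg.n_draws``
    times (dc first, then cv, from the single ``rng``), keep the top-``n``
    intersection, then apply the membership thresholds.  Groups no larger
    than ``top_n`` skip the sampling entirely — selection would be vacuous —
    so degenerate configurations are exactly plain membership filtering.
    Groups left empty are dropped.
    """
    out: list[PathList] = []
    for pl in sorted(pathlists, key=lambda pl: (pl.endpoint_pair[0], pl.endpoint_pair[1] or "")):
        if len(pl.paths) > cfg.top_n:
            props_dc = normalize_proportions([p.a_dc for p in pl.paths], cfg.rounding_decimals)
            props_cv = normalize_proportions([p.a_cv for p in pl.paths], cfg.rounding_decimals)
            keys = [p.key for p in pl.paths]
            part_dc = build_intervals(props_dc, keys)
            part_cv = build_intervals(props_cv, keys)
            counts_dc = mc_sample_counts(part_dc, cfg, rng)
            counts_cv = mc_sample_counts(part_cv, cfg, rng)
            selected = select_candidate_paths(pl, counts_dc, counts_cv, cfg.top_n)
            if logger.isEnabledFor(logging.DEBUG):
                logger.debug(
                    "edge %s group %s: props_dc=%s props_cv=%s counts_dc=%s counts_cv=%s "
                    "selected=%s",
                    pe.key,
                    pl.endpoint_pair,
                    props_dc,
                    props_cv,
                    counts_dc.counts,
                    counts_cv.counts,
                    [p.key for p in selected],
                )
        else:
            selected = list(pl.paths)
        survivors = apply_membership_constraints(selected, pe)
        if survivors:
            out.append(PathList(pl.endpoint_pair, pl.pattern_edge, survivors))
    return out
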