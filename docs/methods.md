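# Methods

## Model

kgmatch matches a pattern DAG `G_P` against an attributed directed data
graph `G_D` under bounded simulation semantics. A binary relation
`S ⊆ V_P × V` is a match when every pattern node is related to at least one
data node, every related data node satisfies the pattern node's role and
trust-impact membership constraint, and for every pattern edge `(u, u′)` and
every `(u, v) ∈ S` there is a simple data path `p` from `v` to some `v′`
with `(u′, v′) ∈ S` and `plen(p) ≤ k` hops. The relation is deliberately
not injective: one pattern node may bind several data nodes and two pattern
nodes may share one. A returned `MatchSubgraph` records the bindings per
pattern node plus the supporting paths per pattern edge.

Path aggregates follow the attribute semantics: the treatment-cycle value
`dc` and the cost-benefit value `cv` are efficiencies that compound hop by
hop, so they aggregate by product; the trust value `dt_trust` is a degree of
confidence, aggregated by arithmetic mean. Each aggregate must pass the
pattern edge's membership function/threshold pair. Membership functions are
monotone maps on [0, 1] looked up in a registry; only `identity` ships, and
thresholds are compared as `f(x) ≥ θ`.

### Assumptions

- **Simple paths.** Matching paths never revisit a node. Without this the
  unbounded-length option (`length_bound=None`) would admit infinitely many
  paths through any cycle.
- **Endpoint-only constraints.** Intermediate nodes of a matching path are
  unconstrained; only the terminal node must satisfy the target pattern
  node's role and trust membership. (A treatment path may legitimately pass
  through another treatment node.)
- **Simple directed data graphs.** At most one edge per ordered node pair;
  parallel edges are rejected on input rather than silently merged.
- **Pattern graphs are DAGs.** The drivers start from a topological order,
  so cyclic patterns are an input error, not a silently degraded case.

## Monte-Carlo selection

Uncertainty in `dc`/`cv` is handled by proportional (roulette-wheel)
selection rather than deterministic ranking. For one group of candidate
paths, each attribute's aggregates `v_i` become proportions
`k_i = v_i / Σv`, laid out as a contiguous cumulative partition of [0, 1]
(half-open intervals, the last closed). `n_draws` uniform variates are
binned per attribute; the paths ranked top-`top_n` by hit count under *both*
attributes (the crossing of the two lists) survive. An empty crossing falls
back to ascending rank-sum (dc rank + cv rank), tie-broken by the larger
`a_dc · a_cv`, then lexicographic path key — the crossing rule alone can be
empty for `top_n = 1` with discordant attributes.

The hologram matcher additionally runs a roulette over candidate *nodes*,
weighted by trust impact factor, keeping the `top_n` by hit count (ties:
larger `dt`, then id).

### Numerical conventions

- **Rounding.** `rounding_decimals=2` (the worked-example display
  convention) rounds proportions before the partition is built; `None`
  keeps full precision. Interval bounds are always renormalized by the
  proportion total so the final upper bound is exactly 1 — rounded
  proportions need not sum to 1, and a partition with a gap would leave
  draws unassigned. The node roulette always uses full precision: with
  pools of hundreds of candidates, two-decimal proportions would all round
  to zero.
- **Degenerate weights.** If every weight in a pool is zero the
  proportional mapping is undefined: the selector returns the whole pool
  when it fits within `top_n` and raises `DegenerateWeightsError`
  otherwise.
- **Vacuous selection.** A path group no larger than `top_n` skips
  sampling entirely, so with `top_n` at least every pool size the
  stochastic matchers coincide exactly, result for result, with the
  exhaustive baseline. The node roulette, by contrast, runs whenever two
  or more candidates exist (its specification samples unconditionally);
  this is what makes the hologram matcher's sampling cost strictly larger
  than the edge-level matcher's on equal instances, a property the
  acceptance suite measures by counting draws rather than timing.
- **Determinism.** One seeded generator (`MCConfig.seed`) is threaded
  through a run in a fixed order: node roulettes as in-degree-0 pattern
  nodes are seeded, then per pattern edge in topological order, dc before
  cv per endpoint group (endpoint groups id-sorted). Identical
  configuration + seed gives identical results and identical draw counts.
- **Node threshold in the node roulette.** The node-roulette specification
  omits the trust threshold that the deterministic selector applies. As
  printed, the hologram matcher could bind nodes that violate the node
  membership constraint and its own output would fail verification, so
  inside `thm_match` the threshold is applied by default
  (`MCConfig.node_dt_threshold=True`); the standalone
  `get_node_candidates_mc` defaults to the printed label-filter-only
  behaviour via `apply_dt_threshold=False`.

## Matching drivers

All three matchers share one driver. The pattern is Kahn-ordered
(lexicographic tie-break); the start node is the lexicographically smallest
in-degree-0 node. Per candidate of the start node, pattern edges are
processed in topological order of their source: candidates of a non-source
pattern node are exactly the endpoints of already-matched paths (a memoized
`G_temp`), remaining in-degree-0 nodes are seeded by the node selector when
first needed. After all edges, bindings are pruned to a fixed point — a
binding must be an endpoint of a surviving path on every incident pattern
edge, and paths lose validity when their endpoints lose their bindings. A
subgraph emptied by pruning is discarded; survivors are deduplicated by
(assignment, path-set) identity, and an optional `limit` stops the run after
that many stored subgraphs (so a limited run is a prefix of the full run
under the same seed).

`baseline_match` is this driver with the roulettes bypassed (every
membership-passing path kept, deterministic candidates). It realizes the
matching relation exhaustively and serves three test roles: exact-equality
oracle under vacuous Monte-Carlo settings, weak-containment bound for
stochastic results (each stochastic subgraph's bindings and paths are a
subset of some exhaustive subgraph's), and recovery check for planted
embeddings.

`verify_match` re-derives every condition from the data graph — assignments
present and constraint-satisfying, per-edge path support, hop bounds,
aggregates recomputed (1e-9 tolerance) and threshold-checked — so corrupted
or hand-edited results are caught independently of the matcher.

`meanval_statistic` pools the `a_dc` and `a_cv` values of sampled matched
paths (uniformly, without replacement, across all subgraphs; the whole pool
when the sample covers it) into one mean, `MeanVal`. The spread of the
pooled values is the result-diversity signal: roulette selection keeps
non-maximal paths, so its support spans several values where a pure
max-aggregate selector concentrates on the single best path.

## Synthetic data generator

`generate_data_graph` emulates consultation-style tumor knowledge graphs:
five role classes with configurable counts, directed edges restricted by
default to the consultation pattern's role pairs plus treatment→treatment,
wired independently with a per-pair probability, and all attributes drawn
i.i.d. from uniform(0, 1) (optionally beta) — matching the convention that
these attribute values are randomly generated. Edge density is a free
parameter: reported corpus statistics for this graph family are internally
contradictory about the node/edge ratio, so no particular density is baked
in. Planting injects disjoint node tuples wired with every pattern edge,
raising each planted attribute to 0.1 above its threshold, which guarantees
recovery by the exhaustive matcher for thresholds at or below that floor.

What the generator does *not* emulate: hub/degree skew, correlated
attributes (trust and cost-benefit are independent here, unlikely in real
care data), role-imbalanced populations, or graphs at the reported corpus
scale (10^5–10^6 edges). Passing tests therefore demonstrate algorithmic
correctness and calibration of the sampling machinery, not performance or
statistical behaviour on real clinical graphs.

The packaged fixtures are a six-participant toy consultation graph and the
reference five-role pattern (node threshold 0.3, edge thresholds 0.2,
`k = 2`). The worked three-path selection example stores its printed
aggregates directly on `PathMatch` objects because they are not jointly
realizable by any single attribute assignment on the shared edges; it
documents the selection arithmetic, not a concrete graph. That example also
pools paths of one pattern edge across two distinct endpoints into a single
roulette; the filter therefore operates per supplied `PathList` — per
endpoint group when fed by the enumerator, pooled when fed the fixture.

## Problem sizes

Randomized suites use desk-scale instances chosen to exercise every code
path with an exhaustive oracle in reach: 12-node graphs (100 seeds) for
oracle equality, ~11–15-node planted graphs (50 seeds) for soundness,
10^5 draws for the law-of-large-numbers calibration (binomial standard
error ≈ 0.0015, well inside the ±0.01 band). The default `n_draws=1000`
matches the conventional roulette size for this method family; the
sensitivity range 1 000–4 000 is available through `MCConfig`.

## Known limitations

- Path enumeration is exponential in the worst case (it is an exhaustive
  bounded simple-path search); practical use relies on small hop bounds
  (`k = 2` default) and role-restricted wiring.
- With `top_n = 1` and discordant dc/cv rankings the crossing rule is
  empty and the rank-sum fallback decides; other resolutions of the
  ambiguous "crossing point" phrase would pick differently. The fallback is
  deterministic and documented above.
- `GraphML`/CSV round-trips preserve the fixed attribute schema only;
  arbitrary extra attributes survive JSON round-trips alone.
- The verifier checks the successor (bounded-simulation) conditions; it
  does not impose predecessor (strong-simulation) locality, which is a
  different matching model.
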