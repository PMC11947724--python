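# kgmatch

Multi-constraint graph pattern matching for attributed medical knowledge
graphs, with Monte-Carlo roulette selection of candidate paths and nodes.

## The problem

Clinical decision support over a tumor knowledge graph asks questions like:
*find every consultation team — attending physician, testing instrument,
tumor type, nurse, treatment — whose mutual relations are trustworthy,
efficient and cost-effective enough.* The data is a directed graph
`G_D = (V, E)` whose nodes carry a role label ρ ∈ {AP, TI, TC, PM, TM} and a
trust impact factor `dt ∈ [0, 1]`, and whose edges carry three attributes in
[0, 1]: a trust value `T_DT`, a treatment-cycle value `T_DC` and a
cost-benefit value `T_CV`.

The query is a pattern DAG `G_P` whose nodes constrain role and trust impact
(`f(dt) ≥ T_Dtm`) and whose edges constrain *paths*: a pattern edge
`(u, u′)` matches any simple data path `p` from a candidate of `u` to a
candidate of `u′` with `plen(p) ≤ k` hops (bounded simulation; `k = 2` by
default). Attributes aggregate along the path — `A_DC` and `A_CV` by
product, `A_DT` by arithmetic mean — and must satisfy membership thresholds
`T_DTm`, `T_DCm`, `T_CVm`. The match relation is simulation-style, not a
bijection: a pattern node may bind several data nodes.

Cycle and cost-benefit values carry genuine uncertainty, so candidate paths
are not ranked deterministically. Instead, each endpoint group's `A_DC` (and
separately `A_CV`) values are normalized to proportions `k_i = v_i / Σv`,
mapped onto a cumulative partition of [0, 1] with interval widths `k_i`, and
sampled with `n` uniform draws; the top-`n` paths by hit count under both
attributes (their crossing) survive, then face the membership thresholds.
Three matchers share this machinery:

- **`tem_match`** — edge-level: deterministic node candidates, roulette
  path selection per pattern edge.
- **`thm_match`** — hologram: roulette selection for candidate nodes
  (weighted by trust impact factor) *and* candidate paths.
- **`baseline_match`** — exhaustive reference without any roulette; the
  stochastic matchers reduce to it exactly when `top_n` exceeds every pool.

A verifier (`verify_match`) independently re-checks every returned subgraph
against the matching relation, and `meanval_statistic` summarizes a result
set by the mean (`MeanVal`) of the `A_DC`/`A_CV` aggregates over a random
sample of matched paths.

## Worked example

The packaged toy fixtures describe a six-participant consultation (one
physician Helen, instrument RATS, tumor type SLCLIA, nurse Meg, treatments
Drug and Operation):

```python
import kgmatch as km

data = km.consultation_data_graph()
pattern = km.reference_pattern()          # thresholds: nodes 0.3, edges 0.2, k = 2
result = km.tem_match(data, pattern, km.MCConfig(n_draws=1000, top_n=2, seed=1))
print("subgraphs:", len(result))
for sub in result.subgraphs:
    print({u: sorted(v) for u, v in sub.assignment.items()})
summary = km.meanval_statistic(result, sample_edges=50)
print(f"MeanVal = {summary.meanval:.4f} over {summary.n_paths} paths")
```

prints

```
subgraphs: 1
{'AP': ['Helen'], 'TI': ['RATS'], 'TC': ['SLCLIA'], 'PM': ['Meg'], 'TM': ['Drug', 'Operation']}
MeanVal = 0.6875 over 8 paths
```

One matched subgraph: Helen's team, with both treatments bound to the TM
pattern node (the pattern edge (TC, TM) matches the direct paths
SLCLIA→Drug and SLCLIA→Operation plus the two-hop SLCLIA→Drug→Operation).
MeanVal 0.6875 is the mean of the dc and cv aggregates of the 8 matched
paths — a summary of how efficient/cost-effective the matched relations are.

The same flow from the shell, on a synthetic graph with two planted pattern
occurrences:

```
$ cat spec.yaml
nodes_per_role: {AP: 6, TI: 6, TC: 6, PM: 6, TM: 6}
edge_probability: 0.15
planted_embeddings: 2
seed: 3

$ kgmatch generate --spec spec.yaml --out data.json --pattern-out pattern.json
nodes: 30  edges: 38  seed: 3
$ kgmatch match --algorithm tem --data data.json --pattern pattern.json --seed 7 --out result.json
algorithm: tem
subgraphs: 2
MeanVal: 0.3583 over 11 paths
$ kgmatch verify --result result.json --data data.json --pattern pattern.json
subgraphs checked: 2  violations: 0
```

Both planted teams are recovered and every stored subgraph re-verifies
against the matching relation. Graphs are read and written as JSON property
graphs, GraphML, or CSV node/edge-list pairs (`read_graph` / `write_graph`).

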