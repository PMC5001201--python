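# Methods

## The problem

A perturbation (gene overexpression, knockdown, disease onset) enters a
cell's interaction network at a small number of proteins and ripples
outward, while the cell's stress response ripples back.  Given (a) a
directed molecular interaction network and (b) one expression profile
per condition (control and perturbed, normalized signal intensities on
the linear scale), the package nominates *epicenters*: nodes from which
highly active paths spread out specifically in one condition.  An
epicenter is the most influential node of a condition, not necessarily
the causal source of the perturbation — a source whose expression stays
low in both conditions cannot appear in any highest-activity network,
and only its activated surroundings will be flagged.

## Model

**Node weights and edge costs.**  Each node `i` is weighted by its
signal intensity in condition `x`, `w_i^x = SI^x`, taking transcript
level as a proxy for protein abundance.  Each directed edge `(u, v)`
costs

    c^x(u, v) = 1 / sqrt(w_u^x · w_v^x)

By mass-action reasoning interaction activity scales with the abundance
of the participants, so active interactions are cheap and minimum-cost
(Dijkstra) paths are *highest-activity paths* (HAPs).  Costs are
positive and finite because intensities are required to be strictly
positive (readers reject non-positive values, or optionally floor them
at 1e-3 × the smallest positive observed intensity).

**HAP extraction.**  For every ordered pair of nodes the minimum-cost
path is computed per condition; paths with fewer than two edges are
discarded (a single edge carries no ripple information).  Path costs are
ranked ascending and the paths inside a percentile `q` (default 0.1) are
retained: with `N` candidate paths the realized cutoff is the
`ceil(q/100·N)`-th smallest cost, and boundary ties are all kept.
Retention is monotone in `q`.

**Condition-specific networks.**  A path whose exact node sequence
appears in both conditions is active regardless of the perturbation and
is discarded from both sides (costs may differ; identity is the
sequence).  The surviving condition-specific paths edge-induce one
*condition-specific highest-activity network* (CSHAN) per condition.
Two CSHANs may still share nodes and edges — only whole paths are
matched — and those shared nodes are exactly the "re-wired"
participants the global epicenter list reports.

**Ripple centrality.**  On a CSHAN, for each node `u`:

* outward closeness `C(u)` = 1 / Σ_v σ(u, v) over nodes `v` reachable
  from `u` (0 if none), with σ the cost-weighted shortest-path distance;
* outward reachability `R_out(u)` = number of nodes reachable from `u`.

Both are normalized — `R_out` by `N − 1`, `C` by the maximum raw
closeness in the CSHAN — and multiplied:

    ripple(u) = C_norm(u) · R_out_norm(u)

The product acts as a logical AND: a node scoring high must source
*active* paths to *many* nodes.  The CSHAN's nodes are ranked by ripple
score (competition ranking; scores equal within relative 1e-9 share a
rank), split into the list of nodes absent from the other condition's
CSHAN (*condition-specific* epicenters) and the list of nodes present in
both (*global* epicenters), and each list is truncated at rank ≤ k
(default 10) keeping whole tie groups.  Each ranked node is annotated
with membership in the CSHAN's largest strongly connected component,
where epicenters are empirically found.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `percentile` (q) | 0.1 | % of candidate paths retained as HAPs (dimensionless) |
| `top_k` | 10 | rank cutoff of the epicenter lists |
| `analyze` | perturbed | which CSHAN to rank (`control` for knockdowns, `both` if unknown) |
| `hops` | 2 | influence-zone radius (unweighted hops, both directions) |
| `fc_cutoff` | 2.0 (zones), 1.5 (ranking annotation) | fold-change significance threshold: significant iff fc ≥ c or ≤ 1/c |
| `max_frac` | 0.05 | sensitivity: per-gene noise bound (fraction) |
| `reps` | 100 | sensitivity repetitions per direction |

## Influence zones

The immediate influence zone of an epicenter is every node within
`hops` unweighted hops upstream or downstream in a chosen graph (a CSHAN
or the full condition network).  The summary table lists the input node
first (hop 0), then one row per dysregulated gene in the zone:
direction `down_<epi>` (reachable from the epicenter) or `up_<epi>`
(reaches it) — a gene within range in both directions gets two rows —
the BFS hop count, the fold change, a four-way label locating the gene
relative to the two CSHANs, and, for genes more than one hop away, the
intermediate node(s) of one unweighted shortest path with their fold
changes and labels.  Intermediates are computed on the same graph the
zone was taken from; tie paths resolve deterministically (BFS with
neighbors in lexicographic order).  Rows are emitted downstream-first,
then by hop count and gene id — the source material fixes only the
downstream-before-upstream convention, the rest is this package's
choice.  Optionally, dysregulated genes (by default downregulated ones,
the relevant direction when an overexpression is analyzed on the
perturbed CSHAN) within range in the *full* network are spliced into the
zone, since a CSHAN built from the perturbed condition's most active
paths systematically under-represents downregulated genes.  Combined
zones for several epicenters union the per-epicenter zones, record which
epicenters reach each node, and can be pruned to a keep-list plus the
nodes lying on shortest paths between kept nodes (minimal connectors).

## Sensitivity protocol

Detector noise is emulated by independently scaling every gene's
intensity in *both* condition profiles by `1 + u` (direction `up`) or
`1 − u` (direction `down`), `u ~ Uniform(0, max_frac]`, re-running the
whole pipeline per repetition, and aggregating: the set of nodes present
in the top-k of every repetition (k ∈ {10, 20}), per-node mean rank, and
per-node top-k frequency.  Draws come from a counter-based stream keyed
by (master seed, repetition, condition, gene id) — hash-derived, so
results are bit-reproducible, independent of gene ordering, and safe to
parallelize.  Both profiles are perturbed because detector variability
affects every array, not only the perturbed one.

## Synthetic cases

The generator emulates an overexpression experiment on a scale-free
network so every stage is testable offline:

* **network**: Barabási–Albert preferential attachment (`N` = 300,
  `m` = mean_degree/2) with each edge randomly oriented and a 20 %
  chance of the reverse edge (biological networks contain feedback, and
  strongly connected structure matters for ripple spread);
* **control profile**: log-normal intensities `exp(N(μ=5, σ=0.3))`;
* **planted epicenter**: the node with the largest 2-hop downstream
  coverage among nodes covering ≥ 10 % of the graph (so an epicenter is
  geometrically possible), with control intensity pinned at
  `exp(μ − 2σ)`: a near-silenced gene, as in the classic scenario where
  a gene lost in the disease line is re-expressed;
* **perturbation**: the planted node's intensity is multiplied by
  exactly `f` = 8; a gene `h ≤ d` = 2 hops downstream responds with
  expected ratio `1 + (f−1)·α^h` (α = 0.5), inverted for a
  Bernoulli(0.35) fraction of responders (real cascades mix signs);
  every other gene gets multiplicative log-normal noise (sd 0.1), which
  cascade genes receive on top of their effect.

The σ and baseline defaults are a deliberate calibration: recovery of
the planted node requires `ln f` to exceed the intensity spread between
its baseline and the population's top tail, and at desk scale (300
nodes, ~70 retained paths per condition) a microarray-realistic σ ≈ 1
lets random high-intensity backbones swamp an 8-fold signal — either
drowning the planted node or dragging its hub onto control paths.  The
calibration was validated against the aggregate recovery criterion
(mean planted rank ≤ 3 over seeds 1–20; measured 2.0), not tuned per
seed: at the reference seed 42 the planted node ranks 2nd behind a
hop-1 cascade gene whose single very cheap CSHAN edge maximizes raw
closeness — a known small-graph pathology of max-normalized closeness
that the reachability factor cannot always outweigh.  A green recovery
test therefore establishes that the pipeline finds a strong, localized
overexpression in a clean scale-free world; it does not establish
recovery on real arrays, with wider dynamic range, correlated probe
noise, or perturbations whose source stays silent.

## Numerical choices

* **Dijkstra determinism**: the priority queue is keyed by (distance,
  node id), predecessors update only on strict improvement, and
  neighbors are explored in lexicographic order; among tied minimum-cost
  paths one is selected reproducibly, seedlessly, and platform-
  independently.  One path is kept per ordered pair.
* **Scale invariance**: multiplying every intensity by `k` multiplies
  every cost by `1/k`, so retained node sequences, CSHANs and rankings
  are invariant under global rescaling (the absolute ripple values are
  not, and are implementation-defined up to the normalization choice).
* **Path-cost accumulation**: a path's stored cost is the Dijkstra
  distance; it agrees with the sum of its edge costs to relative 1e-12.
* **Degenerate inputs**: a CSHAN with fewer than 3 nodes cannot arise
  from ≥ 2-edge paths; ripple scoring returns all-zero vectors for such
  graphs instead of ranking noise.  An empty analyzed CSHAN raises an
  error suggesting a larger percentile.
* **Memory**: above a configurable node threshold (default 400) the
  all-pairs stage never materializes all O(V²) paths; a first sweep
  collects costs only, fixes the realized cutoff, and a second sweep
  reconstructs the retained paths.

## Known limitations

* Absolute ripple values depend on the max-normalization of closeness;
  only ranks are comparable across runs, and on small CSHANs a node with
  one very cheap edge can take the closeness ceiling (see above).
* Expression input is reduced to one value per gene per condition
  (replicates averaged); no differential-expression statistics are
  computed beyond fold-change flags.
* The all-pairs stage is exact; graphs far beyond ~10⁴ nodes will need
  the streaming mode and patience, there is no approximate backend.
* Influence-zone intermediate annotations follow the zone's own graph;
  when a zone is taken from a CSHAN but augmented from the full network,
  the augmented rows' intermediates come from the full network.
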