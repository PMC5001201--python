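# epitracer

Epicenter detection in condition-specific biological networks.

Diseases and experimental interventions perturb a handful of proteins,
and the change ripples through the interaction network while the cell
responds.  `epitracer` takes a directed molecular interaction network
and two expression profiles (control and perturbed, linear-scale
normalized intensities) and ranks the nodes from which highly active
paths spread out *specifically in one condition* — the epicenters of
the perturbation or of the response to it.  It is aimed at systems
biologists with a genome-scale PPI/regulatory network and a pair of
expression datasets who want an unbiased, network-wide shortlist of
influential players that plain differential expression cannot provide.

## Method in brief

Expression is mapped onto the network as node weights `w_i^x = SI^x`;
each directed edge is costed

    c^x(u, v) = 1 / sqrt(w_u^x · w_v^x)

so that, by mass action, highly active interactions are cheap and
minimum-cost paths are highest-activity paths (HAPs).  Per condition,
all-pairs lowest-cost paths with ≥ 2 edges are ranked by cost and the
top percentile (default 0.1) is retained; paths identical in both
conditions are discarded and the survivors edge-induce one
condition-specific highest-activity network (CSHAN) per condition.
CSHAN nodes are scored by **ripple centrality**

    ripple(u) = C(u) · R_out(u)

the product of normalized outward closeness `C(u) = 1/Σ_v σ(u,v)` and
normalized outward reachability `R_out(u) = |{v : u ⇝ v}|` — a logical
AND of path activity and spread.  The ranking is split into epicenters
specific to the analyzed condition and global (re-wired) epicenters,
annotated with largest-strongly-connected-component membership.  The
package also extracts influence zones (dysregulated genes within k hops
of an epicenter, with intermediates) and runs a rank-stability protocol
under bounded expression noise.  See `docs/methods.md` for the full
model, parameter table and limitations.

## Worked example

No external data is needed — the package ships a generator that plants
a known epicenter (an 8-fold overexpression cascading two hops
downstream) in a scale-free network:

```
$ epitracer simulate --n 300 --seed 42 --outdir case --check-recovery
planted epicenter: G000 (covers 101 nodes within 2 hops)
planted node recovered at rank 2.0
case written to case

$ epitracer run --network case/network.tsv --expression case/expression.tsv \
    --control-cols control --perturbed-cols perturbed --analyze both --outdir out
perturbed: top specific epicenters: G087 (rank 1), G000 (rank 2), G105 (rank 3)
control: top specific epicenters: G037 (rank 1), G113 (rank 2), G114 (rank 3)
artifacts written to out

$ head -4 out/ranking_perturbed_specific.tsv
rank  gene  ripple   closeness  reachability  membership  in_lscc  fold_change
1     G087  0.03561  0.81906    0.04348       specific    False    4.29961
2     G000  0.03134  0.03794    0.82609       specific    True     8.0
3     G105  0.01838  0.02225    0.82609       specific    True     4.53551
```

Reading the output: the planted gene `G000` (fold change exactly 8.0)
is recovered near the top of the perturbation-specific list — it
reaches 83 % of the perturbed CSHAN (`reachability 0.826`) through
newly active paths and sits inside the CSHAN's largest strongly
connected component (`in_lscc True`).  Rank 1 went to `G087`, a gene
one hop downstream of the planted node whose single, extremely active
outgoing path maximizes normalized closeness — an instructive
illustration that epicenters are the *sources of condition-specific
activity*, not necessarily the causal perturbation.  The control list
contains the nodes displaced from the top paths by the perturbation.

Other subcommands: `epitracer influence-zone --epicenter G000 ...`
writes the dysregulation summary table around an epicenter, and
`epitracer sensitivity --reps 100 --max-frac 0.05 ...` re-runs the
pipeline under bounded per-gene expression noise and reports which
epicenters are always in the top ranks.  Everything is also available
as a library (`epitracer.run_stages`, `epitracer.generate_case`, ...).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the reference synthetic case from the given seed, runs the
complete workflow (both analysis directions), prints the planted
node's recovered rank, and writes the results file.
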