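# Methods

This note documents the models and procedures implemented in `pathwaybn`,
the parameter choices that matter, what the synthetic test-bed does and
does not emulate, and the package's known limitations.

## Discretization

Bayesian-network nodes need a finite state space; expression is binned into
five ordered states per microarray (per sample column), so a state always
means "relative to the rest of that array":

* **σ–μ**: states split at μ±σ and μ±2σ of the array (sample sd, n−1
  denominator). Boundaries belong to the outer state (a value exactly 1σ
  above the mean is *medium high*). A zero-variance array degenerates to
  all-*medium* with a warning.
* **quantile**: breakpoints at the 20/40/60/80% empirical quantiles.
  Intervals are left-closed, so a value equal to a breakpoint joins the
  upper interval and a constant array collapses to state 1.
* **PAM**: 1-D k-medoids with L1 cost. Medoids start at the points nearest
  the 0.1/0.3/0.5/0.7/0.9 quantiles, are refined by alternating
  assignment/median updates, and then by PAM's swap phase (greedy
  medoid/non-medoid exchanges until no swap lowers the cost). The swap
  phase matters when cluster masses are unbalanced: the alternating phase
  alone can park two medoids in one heavy mode and merge two light ones.
  Final states come from nearest *ordered* medoid, guaranteeing a monotone
  value→state map. Arrays with fewer than k distinct values fall back to
  the quantile rule (logged).

Cells flagged Absent by detection calls are forced to state 1 regardless of
method. The feature filter keeps a feature iff its Present-or-Marginal
fraction is strictly above 85% (when calls exist) and its CV = sd/mean is at
least 50%; both thresholds are arguments, since other platforms use e.g. a
20% CV rule. CV is computed on the scale of the data as given.

Discretizations are compared by the UPGMA phenotype contrast: for a gene,
Δ = mean |x−y| over all cross-phenotype sample pairs of discrete states
(0 ≤ Δ ≤ 4), averaged over differentially expressed genes. On multi-modal
panels PAM attains the largest Δ because its bins adapt to the modes, while
quantile bins are tied to fixed mass fractions and σ–μ collapses most of a
unimodal-ish array into the central state.

## Pathway preprocessing

KGML entries of type `gene` become nodes (one node per constituent gene id;
group entries are flattened); relations survive only with a whitelisted
subtype: expression, repression, activation, inhibition, indirect effect.
Cycle removal scans edges in lexicographic (source, target) order and keeps
an edge iff it closes no cycle with the kept set — a deterministic, 
order-dependent rule; which edge of a loop is dropped is otherwise
arbitrary. Unmeasured nodes are removed with bypass rewiring (each parent
connects to each child, edge labelled `indirect`), applied iteratively so
chains of unmeasured nodes collapse into a single bypass; reachability
among retained nodes is preserved. Downstream inference ignores edge
semantics — only direction matters.

## Regulator ranking

For each pathway gene, two 5-class supervised tables are formed: the
response is the gene's state across arrays; predictors are the states of
its candidate TFs (through their encoding genes, on the pooled mRNA-only
datasets) or candidate microRNAs (on the pooled concurrent datasets — the
only arrays measuring both kinds). A forest of CART trees is grown; each
tree trains on a two-thirds subsample drawn *without* replacement, with
`max(1, floor(k/3))` predictors considered per split and states treated as
numeric. Importance is Breiman's mean decrease of accuracy: the drop in
that tree's out-of-bag accuracy when one predictor's OOB column is
permuted, averaged over trees. Raw (un-normalized) scores are used; ties
break lexicographically; a fixed seed gives a bit-identical ranking.
Defaults are 2,000 trees for TFs and 500 for microRNAs, both configurable.

The top 5 TFs and top 3 microRNAs with strictly positive importance become
parents of the gene. Note that a statistically null predictor's estimated
importance is positive with probability ≈ ½ at any forest size, so the
positive-score rule admits some spurious parents by construction; their
main cost is dilution of the conditional probability tables (below). A
regulator appearing in several genes' rankings becomes a single node with
multiple out-edges; a TF whose encoding gene already is a pathway node is
not added again.

## Bayesian network

Each node carries a CPT over (parents…, node) with axes in lexicographic
parent order. Counting starts from an all-ones table (add-one smoothing:
every state combination is deemed possible), one increment per array's
observation vector; each parent-configuration slice is then normalized
independently into P(node | parents). Normalizing per slice rather than
dividing by the table's grand total keeps the declared conditional
semantics; the two differ only by a per-slice constant that cancels in
Gibbs full conditionals. Root priors get the same smoothing,
(count+1)/(M+5). The dataset-selection rule: if the node or any parent is
a microRNA, counts come from one concurrent dataset; otherwise from the
pooled mRNA-only datasets. With p parents the table has 5^(p+1) cells —
5^100 configurations for 100 parents — which is the combinatorial reason
for capping the regulator in-degree.

Smoothing dominates when 5^(p+1) ≫ number of arrays, pulling conditionals
toward uniform; this attenuates, but never reverses, the evidence-driven
contrasts, and is the main reason the calling thresholds below are
demanding.

**Exact inference** uses variable elimination with a greedy min-fill
ordering, one elimination per query node; evidence reduces factors before
elimination and zero total mass raises an "impossible evidence" error.
Intermediate factors beyond 5^13 cells are refused — the engine is meant
for toy-scale calibration networks and the desk-scale synthetic study, not
for production-size pathways.

**Gibbs sampling** draws `Q × n_nodes` network samples (default Q = 250;
one sample = the state after resampling every unobserved node once, in
sorted order, from its full conditional — own CPT row times children's CPT
entries at the current Markov-blanket state). Smoothed CPTs make all full
conditionals strictly positive, so the chain is irreducible. The first 10%
of samples are discarded as burn-in (single chain); the chain is
initialized by ancestral sampling consistent with the evidence, and a fixed
seed makes the run reproducible. Marginals are post-burn-in state
frequencies; evidence nodes are returned as exact point masses. The
approximation error metric is the maximum absolute difference over nodes
and states; on the 16-node calibration toy it stays below 0.05 from
roughly 4,000 samples on and keeps shrinking with longer chains.

## Two-scenario inference and calling

Evidence: every differentially expressed gene that is a pathway node
(regulator nodes never serve as evidence) is clamped to the lower median
(order statistic ⌈n/2⌉, always a valid state) of its discrete values over
one phenotype's samples, pooled across all panels measuring the gene.
The same network is queried under the two phenotype-derived evidence sets;
with the Gibbs engine the two runs use independent child seeds. Regulator
nodes are called when

1. some state is above `p_hi` (default 0.8) in one scenario and below it in
   the other (strict on both sides), or
2. some state changes by at least `fold` (default 2×, with a guarded
   division when the smaller probability is ~0) and the larger probability
   exceeds `p_min` (default 0.5).

Both criteria are symmetric under swapping scenarios, and tightening any
threshold can only remove calls. Calls are restricted to TF/microRNA nodes
by default (a `kinds` argument widens this); one call per (node, criterion)
records the state with the largest probability difference. Building the
network once per concurrent dataset and intersecting the called node ids
gives the two-variant cross-validation.

## Synthetic test-bed

The generator emulates the *statistical shape* of a multi-cohort
two-phenotype study, not microarray physics. Per dataset and sample:
regulator activity aᵣ = base + effect·1[elevated phenotype] + N(0,1), with
the per-sample activity noise paired across the two phenotype blocks
(common random numbers — a zero effect then leaves group means exactly
equal); gene expression = baseline + Σ wᵣ·aᵣ + 0.5·(parent signal) +
N(0, noise_sd); TF encoding genes and microRNAs are observed as activity +
noise. Planted regulators carry weight ±1 (negative for microRNAs, which
repress); non-planted catalog candidates are decoys (weight 0), reflecting
that sequence-predicted candidate lists are dominated by condition-inactive
predictions. Feature baselines: pathway genes N(0, 1.5) — the
mid-dynamic-range where a shift stays visible after discretization —
against a wide N(0, 3) background of 200 features per array, enough for
stable per-array bin boundaries. The reference study: six mRNA datasets and
two concurrent datasets, 40 samples per phenotype each, noise_sd 0.5, one
planted TF (effect 2.0) driving three of five pathway genes. Ground-truth
DE genes are those whose pooled phenotype means differ by more than one
noise_sd.

Not emulated: probe effects, batch structure, normalization artifacts,
annotation noise, cycles with feedback semantics, and regulator-regulator
interactions. Passing the planted-recovery test therefore demonstrates the
pipeline's mechanics end to end — discretization preserving a planted
contrast, ranking surfacing the active candidate, counting/inference
propagating clamped evidence into a regulator's posterior — not performance
on real cohorts.

A separate 16-node toy (three chained pathway genes, 13 root regulators,
CPTs counted from a seeded synthetic panel, middle gene clamped to its
median state) calibrates the Gibbs sampling rate; it is small enough for
exact marginals, and 4,000 samples ≙ Q = 250 per node.

## Numerical and design notes

* All randomness flows from explicit integer seeds; sub-seeds are spawned
  via `numpy.random.SeedSequence`.
* Quantile ties: left-closed intervals; PAM midpoint ties go to the lower
  state; even-n medians take the lower middle value.
* Forest subsampling uses floor(M/3) OOB rows (at least 1).
* CPT parent order is lexicographic, making the JSON serialization
  canonical; exact and Gibbs engines agree on evidence nodes by
  construction (point masses).
* The end-to-end driver defaults to 400/200 trees per TF/microRNA forest —
  at 3–6 candidates per gene the ranking is already stable at these sizes,
  and the full-scale defaults (2000/500) remain available per call.

## Limitations

* Exact inference is exponential in treewidth; real KEGG-scale extended
  networks require the Gibbs engine.
* The >0 importance rule admits spurious regulator parents (see above);
  calls survive this because the criteria demand large posterior contrasts,
  but CPT dilution grows with in-degree.
* Cycles are cut, not modelled; feedback loops are represented only by the
  acyclic remainder of the pathway.
* Most-probable-explanation queries and importance-sampling variants are
  out of scope.
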