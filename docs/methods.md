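# Methods

## The permutation model

Let a network have m edges over one node class (unipartite) or two
disjoint classes (bipartite). The sampler is a Markov chain on the set
of networks sharing the input's exact degree sequence. One step draws
two edge slots uniformly at random (independently, so the same slot can
be drawn twice), orients each stored undirected edge uniformly at random
as (a, b) or (b, a), and proposes replacing (a, b), (c, d) by (a, d),
(c, b). The proposal is rejected — with the reason recorded — if it

* leaves the edge set unchanged (`noop`, including same-slot draws),
* creates a self-loop while loops are disallowed (`loop`),
* creates an antiparallel pair i→j, j→i while disallowed
  (`antiparallel`),
* duplicates an existing edge (`duplicate`), or
* would create a pair listed as excluded (`excluded`).

Excluded pairs are shielded in both directions: they are never created,
and an excluded existing edge is never selected for swapping, so it
persists untouched. The attempts identity
`attempts = performed + Σ rejections` holds exactly and is asserted
throughout the test suite.

The random re-orientation of undirected edges is load-bearing: without
it, only one of the two target-exchange variants of an undirected swap
is reachable and the chain is not ergodic. The 4-node path graph makes
this concrete — its degree sequence (1, 2, 2, 1) admits exactly two
graphs, and only the re-orienting chain visits both (each with long-run
frequency ½, which the tests verify against exhaustive enumeration).

A run makes `ceil(multiplier·m)` attempts. The default multiplier is 10
attempts per edge: for the sparse networks the generator produces, the
fraction of original edges retained has reached its asymptote well
before 10·m attempts (see the retention analysis below), and the
multiplier is exposed for denser networks, which mix more slowly.

Per-ensemble reproducibility: permutation i of an ensemble runs with
seed `params.seed + i`, so streams are deterministic and any single
member can be regenerated in isolation.

Edge membership queries go through an `EdgeIndex` with two backends:
a hash set of packed integers (memory ∝ m) and a dense boolean matrix
over the full pair space (memory ∝ n_source·n_target, faster per query);
`auto` uses the dense backend for pair spaces up to 2²² cells.

## The edge prior

For node pair (i, j) with source degree u and target degree v, the edge
prior is the fraction of permuted networks in which the pair is
connected — the binomial maximum-likelihood estimate, with no
pseudocounts. Because a degree-preserving permutation treats all pairs
with the same (u, v) identically, the estimator pools them
(degree-grouping): the group estimate is

    prior(u, v) = (edge occurrences in the group, summed over the
                   ensemble) / (group size × number of permutations)

and every pair inherits its group's value. Two exact consequences are
asserted as invariants: priors are constant within degree groups, and
they sum to m over the candidate pair universe (each permuted network
contributes exactly m edges). The candidate universe matches what
permutation can produce: all source×target pairs (bipartite), ordered
pairs i≠j plus loops when allowed (directed), unordered pairs i<j plus
loops when allowed (undirected).

The estimator never sees the original edge set beyond its degrees;
permuting the input first changes the estimate only by Monte-Carlo
noise, which the tests check directly.

### Analytical approximation

    P(u, v; m) = u·v / sqrt((u·v)² + (m − u − v + 1)²)

The denominator is the root of a sum of two squares, which gives the
three properties a probability proxy needs: P ∈ [0, 1] always,
P → u·v/m when u·v ≪ m (the expected-occupancy limit), and P → 1 as the
degree product dominates. The approximation is accurate for sparse
networks — on a 300-node, 600-edge heavy-tailed fixture its Spearman
correlation with the permutation prior exceeds 0.999 — but it assumes
edge occupancies are nearly independent, which fails on tiny dense
graphs: for the path graph's end-pair (degrees 1, 1, m = 3) it gives
0.447 where the exact prior is 0. It should be used when permutation is
too expensive, not on toy graphs.

The scaled degree product u·v / max(u·v) is kept as the naive
comparator: it ranks pairs almost identically to the prior (AUROCs
agree to a few thousandths on fixtures) but is badly calibrated, which
is exactly the contrast the Brier decomposition exposes.

## Features

Features are defined for undirected unipartite networks (requests on
directed or bipartite networks raise `UnsupportedStructureError` rather
than guessing semantics). Adamic/Adar uses the natural logarithm.
Jaccard with an empty neighborhood union is 0. Random walk with restart
solves p = r·e_s + (1 − r)·W·p by fixed-point iteration (W the
column-stochastic uniform-neighbor transition; dangling-node mass
redirected to the restart node, so columns sum to 1), stopping when
successive iterates differ by less than `tol` in L1 and raising if
`max_iter` is exceeded. Defaults: restart 0.25, tol 1e−8, max_iter 1e5;
the pair score is symmetrized, (p_s(t) + p_t(s))/2. Preferential
attachment is a pure function of degree — its scores are bitwise
identical on every degree-preserving permutation, which the evaluation
module exploits as an exact sanity check.

## Evaluation

AUROC is the Mann–Whitney rank statistic with midranks, so tied
positive–negative pairs count ½; it agrees exactly with brute-force
pair comparison (tested) and scikit-learn (tested).

Calibration bins pairs by predictor value. By default, finite-support
predictors (at most `n_bins` distinct values — e.g. the degree-grouped
prior, or a constant) are binned by exact unique value; continuous
scores fall back to 20 equal-count bins. With bin k holding n_k pairs
at mean score f_k and event rate o_k:

    calibration = Σ n_k (f_k − o_k)² / N
    refinement  = Σ n_k o_k (1 − o_k) / N

and their sum equals the mean squared error of the binned scores (the
two-component Brier decomposition; the identity is asserted to 1e−9).
For unique-value bins the bin "mean" is taken as the unique value
itself, so a constant predictor at prevalence p yields calibration
exactly 0 and refinement p(1 − p) without summation round-off.

Three tasks mirror the three ways a degree predictor can be asked to
generalize: **reconstruction** (predict a network's own edges; negatives
are all other candidate pairs), **holdout** (keep a fraction of edges,
build the predictor on the sample, score only pairs absent from the
sample), and **transfer** (build on one network, score another sharing
the node universe; nodes unseen in training have degree 0 and hence
prior 0). Transfer requires index-aligned universes — callers with
labeled data align through a shared `NodeLabelMap` first.

The permuted-feature baseline computes a feature on each of n permuted
networks and scores it against the *original* edges. Its AUROC
distribution is the degree-attributable part of the feature's
performance; the edge prior's AUROC on the same task is the degree
ceiling. A feature that exceeds its own permuted baseline captures
structure beyond degree.

## Synthetic networks

`generate_network` draws exactly m edges without replacement with
probability proportional to w_i·w_j, where node weights follow a
Zipf-like law rank^(−γ) over a seeded random ranking. γ = 0 gives
near-uniform degrees; γ around 1 reproduces the hub-dominated degree
distributions typical of curated biomedical networks. For directed
networks without antiparallel edges, sampling is sequential with the
reverse pair masked after each draw, so the constraint holds by
construction. `generate_clustered_network` multiplies within-block
weights by an assortativity factor (degree-corrected planted
partition), producing networks whose neighborhood structure carries
information beyond degree — the substrate for the decomposition
analyses.

`biased_subsample` emulates inspection bias: per-node study intensities
s are lognormal(0, 1) draws, and edge (i, j) is retained with
probability proportional to (s_i·s_j)^bias. bias = 0 is uniform
subsampling; at bias ≈ 2–3 the retained network's degrees decorrelate
from the complement's, reproducing the signature difference between
literature-derived and systematically measured networks.

What the generator does *not* emulate: real networks' motif
distributions, transitivity profiles beyond the planted blocks,
node-type heterogeneity within one edge type, and any correlation
between study intensity and true degree. Tests passing on these
fixtures therefore validate the estimator machinery and the direction
of the degree effects, not magnitudes on any particular real network.

## Numerical and design choices

* Undirected edges are stored canonically (min, max); duplicate input
  edges are an error (silent deduplication would bias degrees).
* Subsample sizes are `round(fraction · m)`; zero-degree nodes remain
  in the universe after subsampling so that downstream tasks can score
  all pairs.
* Retention curves are estimated by checkpointing one trajectory per
  repetition at each multiplier's attempt budget (common random numbers
  across multipliers), with per-multiplier standard deviations reported
  for Monte-Carlo error bars. At the plateau the true curve is flat, so
  monotonicity checks must allow for sampling noise; the tests use a
  3-standard-error band.
* Problem sizes in tests and the acceptance script (networks of 150–300
  nodes, ensembles of 20–200 permutations, 2000 permutations for the
  enumeration oracle) are chosen so every Monte-Carlo comparison has
  comfortable margins while the whole suite runs in about a minute.

## Known limitations

* The XSwap chain samples the degree-sequence graph space uniformly in
  the cases validated here, but uniformity for every network class is
  assumed, not proven; the enumeration oracle covers only small spaces.
* The permutation prior's accuracy for rare degree pairs is limited by
  group size × permutations; callers needing smoothed estimates must
  apply their own.
* Features are implemented densely (adjacency matrices for RWR), which
  is appropriate up to a few thousand nodes, not for genome-scale
  networks.
* The approximation's error is largest for dense or tiny networks and
  for pairs whose degrees are a large fraction of m.
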