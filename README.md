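# permprior

Degree-preserving network permutation and the **edge prior**: a
degree-only baseline for network edge prediction.

## The problem

Biomedical networks — protein interactions, gene regulation,
compound–gene bindings — have wildly unequal node degrees, and much of
that inequality reflects *how* the data were collected (inspection bias)
rather than biology. Edge-prediction methods that lean on degree can
therefore look accurate while making nonspecific or non-generalizable
predictions. To evaluate a predictor honestly you need to know how much
of its performance comes from degree alone.

`permprior` answers that with a permutation framework:

* **Generalized XSwap** randomizes a network while preserving every
  node's source and target degree. Two random edges (a, b) and (c, d)
  exchange targets to (a, d) and (c, b) whenever the result is valid;
  undirected, directed, and bipartite networks are supported, with
  `allow_loops` / `allow_antiparallel` switches, excluded (shielded)
  pairs, and exact accounting of attempted, performed, and rejected
  swaps.
* **The edge prior** P(i~j) is estimated as the fraction of permuted
  networks containing the edge (i, j) — the binomial MLE of an
  edge-existence probability that knows only the degree sequence. All
  node pairs with the same degree pair (u, v) are pooled
  ("degree-grouping"), so the priors are exactly constant within degree
  groups and sum to m over the candidate pair universe. A closed-form
  approximation

      P(u, v; m) = u·v / sqrt((u·v)² + (m − u − v + 1)²)

  is provided for when permutation is too expensive, along with the
  scaled degree product u·v / max(u·v) as a naive comparator.
* **Evaluation tools** compute tie-corrected AUROC, calibration curves,
  the two-component Brier decomposition (calibration + refinement),
  three prediction tasks (self-reconstruction, uniform holdout,
  cross-network transfer), and the *permuted-feature baseline*: a
  feature computed on permuted networks and scored against the real
  edges isolates the degree-attributable part of its performance.
* **Classical features** (preferential attachment, Jaccard,
  Adamic/Adar, resource allocation, random walk with restart) and a
  **synthetic network generator** with tunable degree heterogeneity,
  planted communities, and inspection-bias subsampling round out the
  toolkit.

## Worked example

The path graph a–b–c–d has degree sequence (1, 2, 2, 1), which exactly
two simple graphs realize: {ab, bc, cd} and {ac, bc, bd}. The edge bc is
in both, ad in neither, and each remaining pair in exactly one — so the
exact degree-only edge probabilities are 1, 0, and ½. The permutation
prior recovers them:

```python
import permprior as pp

path = pp.Network(frozenset({(0, 1), (1, 2), (2, 3)}), 4, 4)
prior = pp.edge_prior(path, n_permutations=2000, params=pp.SwapParams(seed=0))
print(prior.table.to_string(index=False))
```

```
 source  target  u  v  prior
      0       1  1  2    0.5
      0       2  1  2    0.5
      0       3  1  1    0.0
      1       2  2  2    1.0
      1       3  2  1    0.5
      2       3  2  1    0.5
```

On a heavy-tailed synthetic network (300 nodes, 600 edges), degree alone
reconstructs the network remarkably well, and the prior is almost
perfectly calibrated:

```python
net = pp.generate_network(
    pp.GeneratorConfig(n_source=300, m=600, heterogeneity=1.0, seed=1))
prior = pp.edge_prior(net, n_permutations=100, params=pp.SwapParams(seed=2))
report = pp.run_reconstruction_task(net, prior)
print(f"edge prior reconstruction AUROC: {report.auroc:.3f}")
print(f"Brier calibration component:     {report.brier_calibration:.2e}")
```

```
edge prior reconstruction AUROC: 0.944
Brier calibration component:     1.87e-06
```

An AUROC of 0.944 achieved *without looking at any true edge* means most
of any predictor's headline performance on this network could be pure
degree. The permuted-feature baseline makes that decomposition explicit
— on a clustered network the Jaccard index beats its own degree-only
null, showing it captures community structure beyond degree:

```python
clustered = pp.generate_clustered_network(
    pp.GeneratorConfig(n_source=150, m=900, heterogeneity=0.8, seed=5),
    n_blocks=2, assortativity=8.0)
baseline = pp.permuted_feature_baseline(
    clustered, "jaccard", n_permutations=20, params=pp.SwapParams(seed=3))
print(f"Jaccard AUROC unpermuted: {baseline.feature_auroc:.3f}, "
      f"permuted mean: {baseline.permuted_aurocs.mean():.3f}, "
      f"edge prior: {baseline.prior_auroc:.3f}")
```

```
Jaccard AUROC unpermuted: 0.634, permuted mean: 0.599, edge prior: 0.825
```

## Command line

Every step is also exposed as a subcommand of `permprior`:

```bash
permprior generate --nodes 300 --edges 600 --gamma 1.0 --seed 0 --out net.tsv
permprior permute net.tsv --n 100 --multiplier 10 --seed 0 --out-dir perms/
permprior prior net.tsv --n 100 --seed 0 --method permutation --out prior.tsv
permprior evaluate net.tsv --task reconstruct --predictor prior --out report.json
permprior retention net.tsv --multipliers 1,5,10,50 --reps 20 --out retention.json
```

Networks are two-column TSV edge lists (`#` comments allowed); label
maps travel as JSON sidecars; reports are JSON with a provenance block
(parameters, seed, input checksums), so identical command lines produce
identical outputs.

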