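# gbhc — Gaussian Bayesian hierarchical clustering

`gbhc` clusters gene-expression data (samples or probes) with Bayesian
hierarchical clustering under a Gaussian model: each cluster is a mixture
component with unknown per-dimension mean μ and precision τ, carrying a
normal-gamma conjugate prior NG(μ, τ | 0, c, a, b). Because the prior is
conjugate, the marginal likelihood of any cluster is available in closed
form, and merges are ranked by the posterior probability that two clusters
belong to one component instead of by an ad-hoc distance. The number of
clusters falls out of the dendrogram automatically: the tree is cut where
the posterior merge probability r drops to one half.

For clusters D_i, D_j merging into D_k, the engine evaluates

    r_k = π_k p(D_k|H1) / [ π_k p(D_k|H1) + (1 − π_k) p(D_i|T_i) p(D_j|T_j) ],

with Dirichlet-process weights d_k = αΓ(n_k) + d_i d_j and
π_k = αΓ(n_k)/d_k, all in log space. Two empirical-Bayes flavours infer the
hyperparameters (c, a, b):

- **GBHC-TREE** — one triple for the whole dendrogram, maximizing the root's
  tree marginal likelihood by alternating greedy builds with
  fixed-structure optimization;
- **GBHC-NODE** — one triple per merger, maximizing the hyperparameter
  posterior (marginal likelihood × gamma hyper-priors) with analytic
  digamma gradients at every candidate merge; faster, and local by design.

The package also ships the standard preparation pipeline (log2 transform,
Wilcoxon rank-sum feature filtering, z-scoring), synthetic mixture
benchmarks with ground-truth labels, and partition-quality indices
(adjusted Rand index, biological homogeneity index). See
[docs/methods.md](docs/methods.md) for the full model description and
numerical choices.

## Worked example

```python
from gbhc import (BHCConfig, HyperPriorConfig, ScenarioSpec,
                  adjusted_rand_index, generate_scenario1, run_gbhc)

X, labels = generate_scenario1(ScenarioSpec(n=120, seed=42))
for scheme in ("tree", "node"):
    root, part = run_gbhc(X, BHCConfig(scheme=scheme), HyperPriorConfig())
    print(scheme, part.n_clusters(), adjusted_rand_index(part.labels, labels))
```

Running `python examples/cluster_synthetic.py` (the same computation with
narration) prints:

```
data: 120 observations x 10 dimensions, 7 true components
GBHC-TREE: 7 clusters, ARI vs truth = 1.000
GBHC-NODE: 7 clusters, ARI vs truth = 1.000
```

Both flavours recover the generating partition exactly (adjusted Rand index
1.000) and infer the true number of components from the data — no cluster
count was supplied anywhere. The other scripts in `examples/` demonstrate
the preprocessing pipeline and the evaluation indices.

The same machinery is available from the shell:

```bash
gbhc simulate --scenario 1 --n 300 --seed 1 \
     --out-matrix X.tsv --out-labels truth.tsv
gbhc cluster --input X.tsv --scheme node \
     --out-partition part.tsv --out-dendrogram tree.nwk
gbhc evaluate --partition part.tsv --reference truth.tsv
```

Dendrograms are written as Newick with each internal node's merge
probability in a `[&r=...]` comment; partitions are two-column
(id, cluster) text.

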