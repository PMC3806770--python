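# Methods

## Model

`gbhc` clusters an observations × variables matrix under an infinite Gaussian
mixture. Observations in one cluster are modelled, dimension by dimension, as
i.i.d. draws from a Gaussian with unknown mean μ and unknown precision τ;
dimensions are independent (diagonal covariance within a component). The
conjugate prior on (μ, τ) is the normal-gamma distribution

    NG(μ, τ | m, c, a, b) = N(μ | m, (cτ)⁻¹) · Gamma(τ | shape a, rate b),

with the location m pinned at 0 because the input is assumed z-score
normalized (each variable has mean 0 and variance 1). Conjugacy gives the
marginal likelihood of a cluster of n points with per-dimension mean x̄ and
sum of squared deviations S in closed form, via the posterior update

    cₙ = c + n,   aₙ = a + n/2,   bₙ = b + S/2 + c n x̄² / (2(c + n)),

    log p(D) = Σ_dims [ lgΓ(aₙ) − lgΓ(a) + a log b − aₙ log bₙ
                        + ½(log c − log cₙ) − (n/2) log 2π ].

The closed form is not taken on faith: the test suite integrates the
likelihood-times-prior integrand numerically over (μ, τ) with nested adaptive
quadrature and requires agreement to 1e−6 relative (observed ~1e−12) over a
3×3×3 grid of hyperparameters and sample sizes up to five. Clusters only
ever enter through the sufficient statistics (n, x̄, S), which merge exactly
by the pooled-mean/pooled-SSD identities.

## Agglomeration

Bayesian hierarchical clustering starts from singletons and greedily merges
the pair of clusters with the highest posterior merge probability

    r_k = π_k p(D_k|H1) / p(D_k|T_k),
    p(D_k|T_k) = π_k p(D_k|H1) + (1 − π_k) p(D_i|T_i) p(D_j|T_j),

where H1 is the hypothesis that the merged data come from a single component
and the prior weight π_k comes from the Dirichlet-process-mixture recursion

    d_k = α Γ(n_k) + d_i d_j,   π_k = α Γ(n_k) / d_k,

with d = α and π = 1 at leaves. The concentration α (default 1.0) sets the
expected number of clusters; larger α means more clusters. α is held fixed
rather than optimized; an optional evidence-based grid search
(`grid_search_alpha`, comparing optimized root marginal likelihoods) is
exposed for users who want the data to choose it. The flat
partition is read off by descending from the root and splitting every node
with r ≤ 0.5 (the boundary splits; the spec of "more likely than not to be
one cluster" is a strict inequality).

Numerical choices that matter here:

- Everything is in log space; Γ(n) overflows at n ≈ 171 otherwise.
- log(1 − π_k) is computed from the exact identity 1 − π_k = d_i d_j / d_k,
  never via `log1p(−exp(log π))`. At n_k of a few dozen, π_k is within
  double-precision rounding of 1 and the naive route silently zeroes the
  split branch of the recursion — which converts the whole algorithm into
  "merge everything". This identity is the single most load-bearing
  numerical detail in the package.
- Candidate-pair scores are cached; after a merge only pairs involving the
  new cluster are rescored, giving O(n²) score evaluations overall. Ties in
  r are broken by the lexicographically smallest pair of cluster creation
  ids, so runs are exactly reproducible.

## Hyperparameter inference

Two empirical-Bayes schemes infer (c, a, b); both keep one shared triple
across dimensions (the gradient system is three-dimensional).

**TREE** maximizes the root's tree marginal likelihood with one triple for
the whole dendrogram. The objective's gradient is tractable only for a fixed
hierarchy, so the scheme alternates: build the tree greedily under the
current triple, then optimize the triple on the frozen structure (the
per-node sufficient statistics and merge priors are cached in postorder
arrays, so one objective evaluation is a vectorized pass plus the two-term
recursion), rebuild, and repeat until the root log-ML stops improving
(relative tolerance 1e−8, at most 20 rounds). The frozen-structure step uses
Nelder-Mead on (log c, log a, log b); the contract is monotone ascent — a
candidate that does not improve the best root log-ML seen so far is
discarded — not any particular optimizer. The best (triple, tree) pair is
returned, and the returned tree is always the one actually built under the
returned triple.

**NODE** gives every node its own triple, the mode of the hyperparameter
posterior: cluster marginal likelihood × independent gamma hyper-priors on
c, a, b. Leaves included, every candidate merger is optimized when it is
first scored, warm-started from the larger child's optimum, and cached until
one of its members changes. A merger's r uses its own optimized triple for
p(D|H1) while the children contribute the tree marginals stored under their
own optima — the scheme is local by construction, which is what lets the
hierarchy be found in a single agglomeration pass.

The per-node optimizer is a damped Newton ascent in (log c, log a, log b):
the gradient involves digamma terms, the 3×3 Hessian adds trigamma terms,
and both are analytic; positivity is structural through the log
reparameterization, and a backtracking Armijo line search (falling back to
steepest ascent when the Newton direction is not an ascent direction)
guarantees the result is never worse than the starting point. Newton was
chosen over first-order ascent because the objective is cheap but called
~n² times: it reaches gradient norms of 1e−13 in about six iterations where
conjugate-gradient variants needed 30–70 evaluations and still missed the
1e−6 gradient tolerance on roughly one cluster in seven. The objective can
be non-convex, so only a local optimum is guaranteed; non-converged nodes
are counted and reported at debug level, and the best iterate is used.

Hyper-priors default to Gamma(shape 2, rate 2) on each of c, a, b — mode ½,
mean 1, weakly informative on the scale of z-scored data. This is a
committed default, configurable in `HyperPriorConfig`. Note the deliberate
consequence: the prior keeps the triple at O(1) and away from the degenerate
maximum-likelihood ray c, a, b → ∞ (precision collapsing to a point mass),
so the optimized predictive variance under the default prior is *not* an
unbiased variance estimate; in the flat-prior limit it tracks the empirical
variance essentially exactly (asserted by test). Initialization is
(1, 1, 1).

## Preprocessing

The committed pipeline order is log2 transform → Wilcoxon rank-sum filter →
z-score normalization. The filter keeps variables whose two-sided rank-sum
p-value between two observation groups falls below the significance level
(default 0.001), using the exact null distribution when both groups have at
most 15 members and the data are tie-free, and the tie-corrected normal
approximation otherwise (delegated to `scipy.stats.mannwhitneyu`; the exact
branch is cross-checked against full subset enumeration in the tests).
Multi-class designs are filtered by pooling (e.g. normal versus all cancer
subtypes). Z-scoring uses the n−1 variance convention; the choice is
immaterial after rescaling but fixed for reproducibility. Orientation is
explicit: variables are whatever the columns currently are, so clustering
probes instead of samples is a transpose, after which normalization applies
to the new columns.

## Synthetic benchmarks

Three generators produce labelled data that probe the assumptions from
different sides. Committed defaults: 1000 observations, 10 dimensions, 7
equally weighted components, component means on coordinate axes at distance
8 in raw space with unit component scales, a single integer seed driving one
documented stream (component assignments first, then coordinates,
component by component). Every generator ends by z-scoring columns, so the
output satisfies the normalization assumption to 1e−10; labels are returned
separately and no clustering code path ever sees them.

1. Diagonal-covariance Gaussians: every assumption holds. The separation
   (minimum centroid gap ≈ 11 raw-space standard deviations) is chosen so
   that exact recovery is the correct outcome for a sound implementation.
2. The same mixture with exchangeable within-component correlation ρ
   (default 0.5): the independence assumption fails and the model is
   expected to over-segment — a bigger correlated cluster is stronger
   evidence against the diagonal model, so the engine prefers sub-clusters.
3. Seven heterogeneous families — Gaussian, gamma(2), uniform, Student-t(5),
   Weibull(1.5), chi-squared(4), each standardized to zero mean and unit
   variance with independent dimensions, plus one correlated Gaussian:
   non-Gaussian marginals with mostly independent dimensions.

What the generators do not emulate: microarray noise structure, batch
effects, unequal cluster sizes, missing values, or the heavy probe-level
dependence of real expression matrices. Passing the synthetic benchmarks
therefore demonstrates correctness of the algorithm under its stated
assumptions and the documented failure direction when independence is
violated — not performance on any particular real dataset.

## Validation scale

The benchmark reproductions in the test suite and the acceptance script use
n = 300 observations per draw and five independent draws, a size at which
the separation regime of the default generators is unchanged and a full
two-scheme sweep stays comfortable on a single CPU. The correlated and
heterogeneous scenarios are checked for direction (over-segmentation;
ARI ≥ 0.8) on one draw each.

## Evaluation indices

The adjusted Rand index follows Hubert–Arabie from the contingency table,
with no clamping (small negative values are meaningful and preserved). The
biological homogeneity index averages, over clusters with at least two
annotated members, the fraction of annotated member pairs sharing at least
one functional class; items without annotations are excluded from pair
counts. Annotations are user-supplied two-column (id, class) text — no
ontology retrieval or propagation is performed.

## Known limitations

- Full-covariance components are out of scope; correlated variables cause
  over-segmentation by design of the model, and the package documents rather
  than fixes this (decorrelating transforms change the meaning of the
  variables).
- Both hyperparameter objectives are non-convex; results are locally optimal
  and deterministic, not global.
- The NODE scheme performs one small optimization per candidate pair: cost
  is O(n²) optimizations, fine to a few hundred observations; clustering
  thousands of probes is substantially slower.
- The DPM prior term π_k approaches 1 quickly with cluster size, so the
  likelihood must carry the evidence against merging at the top of the tree;
  this is intrinsic to the single-α recursion, not a bug.
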