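"""Greedy Bayesian hierarchical agglomeration.

The engine implements the BHC recursion: every candidate merger of two
clusters is scored by the posterior probability ``r`` that its members were
generated by a single mixture component, where the prior probability of the
merge hypothesis comes from a Dirichlet-process-mixture argument,

    d_k  = alpha * Gamma(n_k) + d_i * d_j,
    pi_k = alpha * Gamma(n_k) / d_k,

and the tree marginal likelihood is the recursive two-term mixture

    p(D_k | T_k) = pi_k p(D_k | H1) + (1 - pi_k) p(D_i | T_i) p(D_j | T_j).

All of this is carried in log space (``Gamma(n)`` overflows near n = 171
otherwise).  The final flat partition is obtained by descending from the root
and splitting every node whose merge probability ``r`` falls at or below the
cut threshold (default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model import ClusterStats, NGHyperparams, stats_marginal_loglik
from .partition import Partition

__all__ = [
    "DendroNode",
    "BHCConfig",
    "dpm_weights",
    "node_evidence",
    "build_tree",
    "cut_tree",
]


def _log1mexp(x: float) -> float:
    """log(1 - exp(x)) for x <= 0, numerically stable near both ends."""
    if x >= 0.0:
        return -math.inf
    if x > -math.log(2.0):
        return math.log(-math.expm1(x))
    return math.log1p(-math.exp(x))


@dataclass
class BHCConfig:
    """Engine settings: DPM concentration, cut level, optimization scheme.

    ``alpha`` tunes the expected number of clusters (larger alpha, more
    clusters).  ``scheme`` selects how hyperparameters are inferred: "tree"
    (one set for the whole dendrogram) or "node" (per-merger optimization).
    """

    alpha: float = 1.0
    cut_threshold: float = 0.5
    scheme: str = "tree"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0.0 < self.cut_threshold < 1.0:
            raise ValueError("cut_threshold must lie in (0, 1)")
        self.scheme = self.scheme.lower()
        if self.scheme not in ("tree", "node"):
            raise ValueError("scheme must be 'tree' or 'node'")


@dataclass
class DendroNode:
    """One node of the BHC dendrogram.

    Log-space fields: ``log_d`` is the DPM weight term, ``log_pi`` the merge
    prior, ``log_ml_h1`` the single-component marginal likelihood of the
    node's data and ``log_ml_tree`` the recursive tree marginal.  ``r`` is the
    posterior merge probability.  ``hp`` records the hyperparameters used at
    this node (one shared set in TREE mode, the node's own optimum in NODE
    mode).
    """

    members: np.ndarray
    stats: ClusterStats
    log_d: float
    log_pi: float = 0.0
    log_1mpi: float = -math.inf
    log_ml_h1: float = 0.0
    log_ml_tree: float = 0.0
    r: float = 1.0
    left: "DendroNode | None" = None
    right: "DendroNode | None" = None
    hp: NGHyperparams | None = None
    _uid: int = field(default=-1, repr=False)

    @property
    def n_k(self) -> int:
        return self.stats.n

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["DendroNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def nodes_postorder(self) -> list["DendroNode"]:
        out: list[DendroNode] = []
        stack: list[tuple[DendroNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if node.is_leaf or expanded:
                out.append(node)
            else:
                stack.append((node, True))
                stack.append((node.right, False))
                stack.append((node.left, False))
        return out


def make_leaf(index: int, stats: ClusterStats, alpha: float,
              hp: NGHyperparams) -> DendroNode:
    """Initial singleton cluster: d = alpha, pi = 1, r = 1."""
    log_ml = stats_marginal_loglik(stats, hp)
    return DendroNode(
        members=np.array([index]),
        stats=stats,
        log_d=math.log(alpha),
        log_pi=0.0,
        log_ml_h1=log_ml,
        log_ml_tree=log_ml,
        r=1.0,
        hp=hp,
        _uid=index,
    )


def dpm_weights(left: DendroNode, right: DendroNode,
                alpha: float) -> tuple[float, float]:
    """DPM weight ``log d_k`` and merge prior ``log pi_k`` for a candidate merger."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_k = left.n_k + right.n_k
    log_num = math.log(alpha) + gammaln(n_k)
    log_d = np.logaddexp(log_num, left.log_d + right.log_d)
    return float(log_d), float(log_num - log_d)


def _dpm_weights_full(left: DendroNode, right: DendroNode,
                      alpha: float) -> tuple[float, float, float]:
    """As :func:`dpm_weights` but also the exact log(1 - pi_k).

    Since ``1 - pi_k = d_i d_j / d_k`` identically, the complement is
    computed straight from the recursion; going through ``log1p(-exp(.))``
    would lose it to rounding once ``pi_k`` approaches 1, which happens
    routinely at large nodes where ``alpha*Gamma(n_k)`` dwarfs ``d_i d_j``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_k = left.n_k + right.n_k
    log_num = math.log(alpha) + gammaln(n_k)
    log_prod = left.log_d + right.log_d
    log_d = float(np.logaddexp(log_num, log_prod))
    return log_d, log_num - log_d, log_prod - log_d


def node_evidence(left: DendroNode, right: DendroNode, log_ml_h1: float,
                  log_pi: float,
                  log_1mpi: float | None = None) -> tuple[float, float]:
    """Tree marginal likelihood and posterior merge probability of a merger.

    ``log_ml_tree = logsumexp(log_pi + log_ml_h1,
    log(1 - pi) + left.log_ml_tree + right.log_ml_tree)`` and
    ``r = exp(log_pi + log_ml_h1 - log_ml_tree)``.  Callers that know the
    exact ``log(1 - pi)`` (the engine does, from the DPM recursion) should
    pass it; otherwise it is recovered from ``log_pi``, which is accurate
    only while pi is not too close to 1.  A merge prior of exactly one gives
    r = 1.
    """
    t_merge = log_pi + log_ml_h1
    if log_1mpi is None:
        log_1mpi = _log1mexp(log_pi)
    if log_1mpi == -math.inf:
        return t_merge, 1.0
    t_split = log_1mpi + left.log_ml_tree + right.log_ml_tree
    log_ml_tree = float(np.logaddexp(t_merge, t_split))
    r = math.exp(t_merge - log_ml_tree)
    return log_ml_tree, min(max(r, 0.0), 1.0)


def _score_pair(left: DendroNode, right: DendroNode, alpha: float,
                hp_provider) -> DendroNode:
    """Evaluate one candidate merger and return the (unattached) merged node."""
    stats = left.stats.merge(right.stats)
    hp = hp_provider(stats, left, right)
    log_ml_h1 = stats_marginal_loglik(stats, hp)
    log_d, log_pi, log_1mpi = _dpm_weights_full(left, right, alpha)
    log_ml_tree, r = node_evidence(left, right, log_ml_h1, log_pi, log_1mpi)
    return DendroNode(
        members=np.concatenate([left.members, right.members]),
        stats=stats,
        log_d=log_d,
        log_pi=log_pi,
        log_1mpi=log_1mpi,
        log_ml_h1=log_ml_h1,
        log_ml_tree=log_ml_tree,
        r=r,
        left=left,
        right=right,
        hp=hp,
    )


def build_tree(X: np.ndarray, config: BHCConfig, hp_provider) -> DendroNode:
    """Agglomerate all observations into one binary dendrogram.

    ``hp_provider(stats, left, right)`` supplies the hyperparameters for a
    cluster with the given pooled statistics; ``left``/``right`` are None for
    leaves.  Pair scores are cached, and after each merge only pairs
    involving the new cluster are evaluated, so the build performs O(n^2)
    score evaluations overall.  Ties in the merge probability are broken by
    the lexicographically smallest pair of cluster creation ids, which makes
    reruns deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot cluster an empty matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contain non-finite values")

    active: dict[int, DendroNode] = {}
    for i in range(n):
        stats = ClusterStats.from_data(X[i : i + 1])
        hp = hp_provider(stats, None, None)
        active[i] = make_leaf(i, stats, config.alpha, hp)
    next_uid = n

    cache: dict[tuple[int, int], DendroNode] = {}
    ids = sorted(active)
    for pos, i in enumerate(ids):
        for j in ids[pos + 1 :]:
            cache[(i, j)] = _score_pair(active[i], active[j], config.alpha,
                                        hp_provider)

    while len(active) > 1:
        best_key = None
        best_r = -1.0
        for key, cand in cache.items():
            if cand.r > best_r or (cand.r == best_r and key < best_key):
                best_r = cand.r
                best_key = key
        i, j = best_key
        merged = cache.pop(best_key)
        merged._uid = next_uid
        del active[i], active[j]
        for key in [k for k in cache if i in k or j in k]:
            del cache[key]
        for k, node in active.items():
            pair = (k, next_uid) if k < next_uid else (next_uid, k)
            left, right = (node, merged) if k < next_uid else (merged, node)
            cache[pair] = _score_pair(left, right, config.alpha, hp_provider)
        active[next_uid] = merged
        next_uid += 1

    return next(iter(active.values()))


def cut_tree(root: DendroNode, threshold: float = 0.5) -> Partition:
    """Flat partition from the dendrogram: split every node with r <= threshold.

    Clusters are the maximal subtrees whose root has merge probability above
    the threshold; they are labelled 1..K in order of their smallest member
    index.
    """
    groups: list[np.ndarray] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf or node.r > threshold:
            groups.append(node.members)
        else:
            stack.append(node.right)
            stack.append(node.left)
    groups.sort(key=lambda m: int(m.min()))
    n = sum(len(g) for g in groups)
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(groups, start=1):
        labels[members] = lab
    return Partition(labels)
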