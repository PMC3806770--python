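"""Empirical-Bayes inference of the normal-gamma hyperparameters.

Two schemes are provided, matching the two GBHC flavours:

TREE
    One hyperparameter triple ``(c, a, b)`` for the whole dendrogram, chosen
    to maximize the root's tree marginal likelihood.  Gradients of that
    objective are tractable only once the hierarchy is fixed, so the scheme
    alternates: build the tree greedily under the current hyperparameters,
    then (structure frozen) improve the hyperparameters on the root
    objective, and repeat until no further gain.

NODE
    A separate triple per merger, found by maximizing the hyperparameter
    posterior — the cluster's marginal likelihood times independent gamma
    hyper-priors on ``c``, ``a`` and ``b`` — by damped Newton ascent in
    ``(log c, log a, log b)`` with analytic digamma gradients and trigamma
    Hessian terms.  Because each candidate merger carries its own
    optimization, the best hierarchy is found in a single agglomeration
    pass.

The gamma hyper-priors default to shape 2, rate 2 on each hyperparameter
(mode 1/2, mean 1), weakly informative on the scale of z-normalized data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, polygamma, psi

from .engine import BHCConfig, DendroNode, build_tree, cut_tree
from .model import ClusterStats, NGHyperparams
from .partition import Partition

__all__ = [
    "HyperPriorConfig",
    "grid_search_alpha",
    "node_log_posterior",
    "node_gradient",
    "optimize_node",
    "optimize_tree",
    "run_gbhc",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class HyperPriorConfig:
    """Gamma hyper-priors on (c, a, b) plus optimizer settings.

    Each prior is a ``(shape, rate)`` pair.  ``init`` is the starting triple
    for every optimization.  Tolerances: ``grad_tol`` on the log-space
    gradient norm, ``obj_tol`` on objective change, ``max_iter`` ascent
    iterations per node, ``max_tree_rounds`` outer build/optimize
    alternations for the TREE scheme.
    """

    c_prior: tuple[float, float] = (2.0, 2.0)
    a_prior: tuple[float, float] = (2.0, 2.0)
    b_prior: tuple[float, float] = (2.0, 2.0)
    init: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_iter: int = 200
    grad_tol: float = 1e-6
    obj_tol: float = 1e-8
    max_tree_rounds: int = 20

    def __post_init__(self) -> None:
        for name in ("c_prior", "a_prior", "b_prior"):
            shape, rate = getattr(self, name)
            if not (shape > 0 and rate > 0):
                raise ValueError(f"{name} shape and rate must be positive")
        if not all(v > 0 for v in self.init):
            raise ValueError("initial hyperparameters must be positive")

    @property
    def shapes(self) -> np.ndarray:
        return np.array([self.c_prior[0], self.a_prior[0], self.b_prior[0]])

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.c_prior[1], self.a_prior[1], self.b_prior[1]])

    def init_hp(self) -> NGHyperparams:
        return NGHyperparams(*self.init)


def _log_gamma_pdf_sum(x: np.ndarray, shapes: np.ndarray,
                       rates: np.ndarray) -> float:
    return float(
        np.sum(shapes * np.log(rates) - gammaln(shapes)
               + (shapes - 1.0) * np.log(x) - rates * x)
    )


def _loglik_and_grad(stats: ClusterStats, c: float, a: float,
                     b: float) -> tuple[float, np.ndarray]:
    """Cluster log marginal likelihood and its gradient wrt (c, a, b)."""
    n = stats.n
    d = stats.n_dims
    c_n = c + n
    a_n = a + 0.5 * n
    b_n = b + 0.5 * stats.ssd + (c * n / (2.0 * c_n)) * stats.mean**2
    log_b_n = np.log(b_n)
    ll = d * (
        gammaln(a_n) - gammaln(a) + a * math.log(b)
        + 0.5 * (math.log(c) - math.log(c_n)) - 0.5 * n * _LOG_2PI
    ) - a_n * log_b_n.sum()
    inv_b_n = 1.0 / b_n
    # d b_n / d c = n^2 mean^2 / (2 (c+n)^2), by the quotient rule
    dbn_dc = (n * n / (2.0 * c_n * c_n)) * stats.mean**2
    g_c = d * 0.5 * (1.0 / c - 1.0 / c_n) - a_n * float((dbn_dc * inv_b_n).sum())
    g_a = d * (psi(a_n) - psi(a) + math.log(b)) - float(log_b_n.sum())
    g_b = d * a / b - a_n * float(inv_b_n.sum())
    return float(ll), np.array([g_c, g_a, g_b])


def node_log_posterior(stats: ClusterStats, hp: NGHyperparams,
                       prior: HyperPriorConfig) -> float:
    """Log posterior of the hyperparameters at one node (up to a constant).

    Decomposes exactly as cluster log marginal likelihood plus the sum of
    gamma-prior log densities over (c, a, b).
    """
    ll, _ = _loglik_and_grad(stats, hp.c, hp.a, hp.b)
    return ll + _log_gamma_pdf_sum(hp.as_array(), prior.shapes, prior.rates)


def node_gradient(stats: ClusterStats, hp: NGHyperparams,
                  prior: HyperPriorConfig) -> np.ndarray:
    """Analytic gradient of :func:`node_log_posterior` wrt (c, a, b).

    The likelihood part uses the digamma function for the shape coordinate;
    for an empty cluster it vanishes and only the prior gradient remains.
    """
    _, g = _loglik_and_grad(stats, hp.c, hp.a, hp.b)
    x = hp.as_array()
    return g + (prior.shapes - 1.0) / x - prior.rates


@dataclass
class OptimizeInfo:
    converged: bool
    n_iter: int
    objective: float
    grad_norm: float


def _objective_factory(stats: ClusterStats, prior: HyperPriorConfig):
    """Closure computing (objective, gradient, Hessian) at u = log (c, a, b).

    Gradient and Hessian are in log-parameter space (chain rule applied), so
    positivity of the hyperparameters is structural rather than constrained.
    All second derivatives are elementary apart from the trigamma terms in
    the shape coordinate.
    """
    n = stats.n
    d = stats.n_dims
    meansq = stats.mean**2
    half_ssd = 0.5 * stats.ssd
    shapes = prior.shapes
    rates = prior.rates
    prior_const = float(np.sum(shapes * np.log(rates) - gammaln(shapes)))

    def fgh(u: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        x = np.exp(u)
        c, a, b = x
        c_n = c + n
        a_n = a + 0.5 * n
        b_n = b + half_ssd + (c * n / (2.0 * c_n)) * meansq
        log_b_n = np.log(b_n)
        inv = 1.0 / b_n
        w = (n * n / (2.0 * c_n * c_n)) * meansq  # d b_n / d c
        f = d * (
            gammaln(a_n) - gammaln(a) + a * math.log(b)
            + 0.5 * (math.log(c) - math.log(c_n)) - 0.5 * n * _LOG_2PI
        ) - a_n * log_b_n.sum()
        f += prior_const + float(((shapes - 1.0) * u - rates * x).sum())
        B1 = inv.sum()
        B2 = (inv * inv).sum()
        Bw = (w * inv).sum()
        g_c = d * 0.5 * (1.0 / c - 1.0 / c_n) - a_n * Bw
        g_a = d * (psi(a_n) - psi(a) + math.log(b)) - log_b_n.sum()
        g_b = d * a / b - a_n * B1
        g_nat = np.array([g_c, g_a, g_b]) + (shapes - 1.0) / x - rates
        H = np.empty((3, 3))
        H[0, 0] = (d * 0.5 * (1.0 / (c_n * c_n) - 1.0 / (c * c))
                   + a_n * ((2.0 * w / c_n) * inv).sum()
                   + a_n * (w * w * inv * inv).sum())
        H[1, 1] = d * (polygamma(1, a_n) - polygamma(1, a))
        H[2, 2] = -d * a / (b * b) + a_n * B2
        H[0, 1] = H[1, 0] = -Bw
        H[1, 2] = H[2, 1] = d / b - B1
        H[0, 2] = H[2, 0] = a_n * (w * inv * inv).sum()
        H -= np.diag((shapes - 1.0) / (x * x))
        g_u = g_nat * x
        H_u = (x[:, None] * x[None, :]) * H + np.diag(g_u)
        return float(f), g_u, H_u

    return fgh


def _newton_maximize(fgh, u0: np.ndarray, grad_tol: float,
                     max_iter: int) -> tuple[np.ndarray, float, OptimizeInfo]:
    """Damped Newton ascent with Armijo backtracking.

    Falls back to a steepest-ascent step whenever the Newton direction is
    not an ascent direction (the objective can be non-convex away from the
    optimum).  Iterates are clamped to |log-parameter| < 50 so exp stays
    representable.
    """
    u = u0.copy()
    f, g, H = fgh(u)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(g))
        if gnorm < grad_tol:
            converged = True
            break
        try:
            direction = np.linalg.solve(-H, g)
            if float(direction @ g) <= 0.0:
                direction = g
        except np.linalg.LinAlgError:
            direction = g
        slope = float(direction @ g)
        t = 1.0
        accepted = False
        for _ in range(40):
            u_try = u + t * direction
            if float(np.abs(u_try).max()) < 50.0:
                f_try, g_try, H_try = fgh(u_try)
                if math.isfinite(f_try) and f_try >= f + 1e-4 * t * slope:
                    accepted = True
                    break
            t *= 0.5
        if not accepted:  # line search failed; gradient is unusable here
            break
        u, f, g, H = u_try, f_try, g_try, H_try
    return u, f, OptimizeInfo(converged, it, f, float(np.linalg.norm(g)))


def optimize_node(
    stats: ClusterStats,
    prior: HyperPriorConfig,
    init: NGHyperparams | None = None,
    return_info: bool = False,
):
    """Maximize the hyperparameter posterior of one cluster.

    Damped Newton ascent in ``(log c, log a, log b)`` keeps the parameters
    positive without bound constraints.  The objective can be non-convex; on
    non-convergence the best iterate found is returned and the info flag
    records the failure.
    """
    hp0 = init if init is not None else prior.init_hp()
    fgh = _objective_factory(stats, prior)
    u0 = np.log(hp0.as_array())
    f0, _, _ = fgh(u0)
    u, f, info = _newton_maximize(fgh, u0, prior.grad_tol, prior.max_iter)
    if f < f0:  # ascent contract: never return worse than the start
        u, f = u0, f0
        info = OptimizeInfo(False, info.n_iter, f, info.grad_norm)
    c, a, b = np.exp(u)
    hp = NGHyperparams(c=float(c), a=float(a), b=float(b))
    if return_info:
        return hp, info
    if not info.converged:
        logger.debug("node hyperparameter optimization did not converge "
                     "(n=%d, iter=%d)", stats.n, info.n_iter)
    return hp


class _FixedHpProvider:
    """Supplies one shared hyperparameter triple to every node (TREE scheme)."""

    def __init__(self, hp: NGHyperparams):
        self.hp = hp

    def __call__(self, stats, left, right) -> NGHyperparams:
        return self.hp


class NodeHyperOptProvider:
    """Per-merger hyperparameter optimization (NODE scheme).

    Every candidate cluster — leaves included — gets its own posterior-mode
    hyperparameters.  Candidate mergers are warm-started from the larger
    child's optimum, which substantially cuts ascent iterations.
    """

    def __init__(self, prior: HyperPriorConfig):
        self.prior = prior
        self.n_calls = 0
        self.n_failed = 0

    def __call__(self, stats, left, right) -> NGHyperparams:
        if left is None or left.hp is None:
            init = self.prior.init_hp()
        else:
            bigger = left if left.n_k >= right.n_k else right
            init = bigger.hp
        hp, info = optimize_node(stats, self.prior, init=init,
                                 return_info=True)
        self.n_calls += 1
        if not info.converged:
            self.n_failed += 1
        return hp


class _FrozenTree:
    """Root tree-marginal objective for a fixed hierarchy (TREE inner step).

    Caches every node's sufficient statistics and merge prior in postorder
    arrays so the root log marginal likelihood can be re-evaluated for any
    hyperparameter triple with vectorized array work plus one cheap pass of
    the two-term recursion.
    """

    def __init__(self, root: DendroNode):
        nodes = root.nodes_postorder()
        self.m = len(nodes)
        self.d = root.stats.n_dims
        self.N = np.array([nd.stats.n for nd in nodes], dtype=float)
        self.mean_sq = np.stack([nd.stats.mean**2 for nd in nodes])
        self.half_ssd = 0.5 * np.stack([nd.stats.ssd for nd in nodes])
        self.log_pi = np.array([nd.log_pi for nd in nodes])
        self.log_1mpi = np.array([nd.log_1mpi for nd in nodes])
        index = {id(nd): k for k, nd in enumerate(nodes)}
        self.left = np.array(
            [-1 if nd.is_leaf else index[id(nd.left)] for nd in nodes]
        )
        self.right = np.array(
            [-1 if nd.is_leaf else index[id(nd.right)] for nd in nodes]
        )

    def root_loglik(self, c: float, a: float, b: float) -> float:
        N = self.N
        c_n = c + N
        a_n = a + 0.5 * N
        b_n = b + self.half_ssd + ((c * N / (2.0 * c_n))[:, None] * self.mean_sq)
        log_ml_h1 = self.d * (
            gammaln(a_n) - gammaln(a) + a * math.log(b)
            + 0.5 * (math.log(c) - np.log(c_n)) - 0.5 * N * _LOG_2PI
        ) - a_n * np.log(b_n).sum(axis=1)
        tree = np.empty(self.m)
        for k in range(self.m):
            if self.left[k] < 0:
                tree[k] = log_ml_h1[k]
            else:
                t_merge = self.log_pi[k] + log_ml_h1[k]
                if self.log_1mpi[k] == -math.inf:
                    tree[k] = t_merge
                    continue
                t_split = (self.log_1mpi[k] + tree[self.left[k]]
                           + tree[self.right[k]])
                tree[k] = np.logaddexp(t_merge, t_split)
        return float(tree[-1])


def _optimize_frozen(frozen: _FrozenTree, hp0: NGHyperparams,
                     prior: HyperPriorConfig) -> tuple[NGHyperparams, float]:
    """Maximize the fixed-structure root objective (derivative-free).

    The root objective's gradient threads through every node of the
    recursion; a Nelder-Mead search on the log-parameters is accurate enough
    here and keeps the inner step simple.  The ascent contract (never worse
    than the start) is what the outer loop relies on.
    """

    def neg(u: np.ndarray) -> float:
        if np.any(np.abs(u) > 50.0):
            return np.inf
        c, a, b = np.exp(u)
        return -frozen.root_loglik(c, a, b)

    u0 = np.log(hp0.as_array())
    res = minimize(neg, u0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
    f0 = -neg(u0)
    if -res.fun <= f0:
        return hp0, f0
    c, a, b = np.exp(res.x)
    return NGHyperparams(c=float(c), a=float(a), b=float(b)), float(-res.fun)


def optimize_tree(
    X: np.ndarray,
    config: BHCConfig,
    prior: HyperPriorConfig,
) -> tuple[NGHyperparams, DendroNode]:
    """GBHC-TREE: alternate greedy builds with fixed-structure hyperparameter ascent.

    Returns the best (hyperparameters, root) pair seen; the root is always
    the tree actually built under the returned hyperparameters, and its root
    log marginal likelihood is non-decreasing over the outer rounds.
    """
    hp = prior.init_hp()
    best_hp, best_root, best_val = None, None, -np.inf
    for _ in range(prior.max_tree_rounds):
        root = build_tree(X, config, _FixedHpProvider(hp))
        if best_root is None or root.log_ml_tree > best_val:
            best_hp, best_root, best_val = hp, root, root.log_ml_tree
        frozen = _FrozenTree(root)
        hp_new, val_fixed = _optimize_frozen(frozen, hp, prior)
        gain = val_fixed - root.log_ml_tree
        if gain <= prior.obj_tol * (1.0 + abs(root.log_ml_tree)):
            break
        hp = hp_new
    return best_hp, best_root


def grid_search_alpha(
    X: np.ndarray,
    alphas,
    config: BHCConfig | None = None,
    prior: HyperPriorConfig | None = None,
) -> tuple[float, dict]:
    """Pick the DPM concentration by root tree-marginal-likelihood evidence.

    Runs the TREE scheme at each candidate ``alpha`` and returns the value
    whose optimized root log marginal likelihood is highest, together with
    the per-alpha evidence map.  Optional utility — the default workflow
    keeps ``alpha`` fixed at 1.
    """
    config = config if config is not None else BHCConfig()
    prior = prior if prior is not None else HyperPriorConfig()
    evidence: dict = {}
    for alpha in alphas:
        cfg = BHCConfig(alpha=float(alpha),
                        cut_threshold=config.cut_threshold, scheme="tree")
        _, root = optimize_tree(X, cfg, prior)
        evidence[float(alpha)] = root.log_ml_tree
    best = max(sorted(evidence), key=lambda a: evidence[a])
    return best, evidence


def _check_normalized(X: np.ndarray) -> None:
    if X.shape[0] < 2:
        return
    mean_dev = float(np.abs(X.mean(axis=0)).max())
    var_dev = float(np.abs(X.var(axis=0, ddof=1) - 1.0).max())
    if mean_dev > 1e-3 or var_dev > 0.05:
        warnings.warn(
            "input does not look z-score normalized (max |column mean| "
            f"{mean_dev:.3g}, max |column variance - 1| {var_dev:.3g}); "
            "the model assumes zero-mean, unit-variance variables",
            UserWarning,
            stacklevel=3,
        )


def run_gbhc(
    X: np.ndarray,
    config: BHCConfig | None = None,
    prior: HyperPriorConfig | None = None,
) -> tuple[DendroNode, Partition]:
    """Cluster a normalized observations x variables matrix with GBHC.

    Dispatches on ``config.scheme`` ("tree" or "node"), builds the
    dendrogram, and cuts it at the configured merge-probability threshold.
    Returns the dendrogram root and the flat partition.
    """
    config = config if config is not None else BHCConfig()
    prior = prior if prior is not None else HyperPriorConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_normalized(X)
    if config.scheme == "tree":
        _, root = optimize_tree(X, config, prior)
    else:
        provider = NodeHyperOptProvider(prior)
        root = build_tree(X, config, provider)
        if provider.n_failed:
            logger.info(
                "%d of %d node optimizations stopped before convergence",
                provider.n_failed, provider.n_calls,
            )
    partition = cut_tree(root, config.cut_threshold)
    return root, partition
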