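"""Synthetic mixture benchmarks with ground-truth labels.

Three scenarios probe the model assumptions from different directions:

1. a mixture of well-separated multivariate Gaussians with diagonal
   covariance — every assumption holds, and a sound implementation should
   recover the generating partition exactly;
2. the same mixture but with correlated variables inside each component —
   the independence assumption is violated, and the expected failure mode is
   over-segmentation of the true clusters;
3. a mixture of seven heterogeneous component families (Gaussian, gamma,
   uniform, Student's t, Weibull, chi-squared, and one correlated Gaussian)
   — marginals are non-Gaussian but mostly independent, probing robustness.

Defaults: 1000 observations, 10 dimensions, 7 equally weighted components
whose means sit on coordinate axes at distance 8 in raw space with unit
component scales (well separated).  Every generator finishes by z-scoring
the columns, so the output satisfies the normalization assumption; labels
are returned separately and are never consumed by any clustering code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_fn

from .preprocess import normalize_array

__all__ = [
    "ScenarioSpec",
    "generate_scenario1",
    "generate_scenario2",
    "generate_scenario3",
    "SCENARIO3_FAMILIES",
]

SCENARIO3_FAMILIES = (
    "gaussian",
    "gamma",
    "uniform",
    "t",
    "weibull",
    "chi2",
    "correlated_gaussian",
)

#: shape parameters of the skewed/heavy-tailed scenario-3 families
GAMMA_SHAPE = 2.0
T_DF = 5.0
WEIBULL_SHAPE = 1.5
CHI2_DF = 4.0


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic draw.

    ``means`` defaults to component ``j`` centred at ``separation * e_j``
    (requires k <= d); ``scales`` are per-component standard deviations in
    raw space.  ``rho`` is the exchangeable within-component correlation used
    by scenario 2 and by scenario 3's correlated-Gaussian component; a full
    correlation matrix can be supplied instead.
    """

    n: int = 1000
    d: int = 10
    k: int = 7
    weights: np.ndarray | None = None
    separation: float = 8.0
    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    rho: float = 0.5
    correlation: np.ndarray | None = None
    families: tuple[str, ...] = SCENARIO3_FAMILIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 1 or self.k < 1:
            raise ValueError("need n >= 2, d >= 1, k >= 1")
        if self.weights is None:
            self.weights = np.full(self.k, 1.0 / self.k)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.k,) or np.any(self.weights < 0):
                raise ValueError("weights must be k nonnegative numbers")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")
        if self.means is None:
            if self.k > self.d:
                raise ValueError(
                    "default axis-aligned means need k <= d; supply means"
                )
            self.means = np.zeros((self.k, self.d))
            for j in range(self.k):
                self.means[j, j] = self.separation
        else:
            self.means = np.asarray(self.means, dtype=float)
            if self.means.shape != (self.k, self.d):
                raise ValueError("means must have shape (k, d)")
        if self.scales is None:
            self.scales = np.ones(self.k)
        else:
            self.scales = np.asarray(self.scales, dtype=float)
            if self.scales.shape != (self.k,) or np.any(self.scales <= 0):
                raise ValueError("scales must be k positive numbers")

    def correlation_matrix(self) -> np.ndarray:
        """Within-component correlation (exchangeable rho unless supplied)."""
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            if R.shape != (self.d, self.d):
                raise ValueError("correlation must have shape (d, d)")
        else:
            R = np.full((self.d, self.d), self.rho)
            np.fill_diagonal(R, 1.0)
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        return R


def _assignments(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Component labels in 1..k, drawn before any coordinates."""
    return rng.choice(spec.k, size=spec.n, p=spec.weights) + 1


def _standardized_draw(family: str, rng: np.random.Generator,
                       size: tuple[int, int]) -> np.ndarray:
    """Draw i.i.d. values with mean 0 and variance 1 from the named family."""
    if family == "gaussian":
        return rng.standard_normal(size)
    if family == "gamma":
        return (rng.gamma(GAMMA_SHAPE, 1.0, size) - GAMMA_SHAPE) / math.sqrt(
            GAMMA_SHAPE)
    if family == "uniform":
        h = math.sqrt(3.0)
        return rng.uniform(-h, h, size)
    if family == "t":
        return rng.standard_t(T_DF, size) * math.sqrt((T_DF - 2.0) / T_DF)
    if family == "weibull":
        m1 = gamma_fn(1.0 + 1.0 / WEIBULL_SHAPE)
        m2 = gamma_fn(1.0 + 2.0 / WEIBULL_SHAPE)
        sd = math.sqrt(m2 - m1 * m1)
        return (rng.weibull(WEIBULL_SHAPE, size) - m1) / sd
    if family == "chi2":
        return (rng.chisquare(CHI2_DF, size) - CHI2_DF) / math.sqrt(
            2.0 * CHI2_DF)
    raise ValueError(f"unknown component family {family!r}")


def _fill_components(spec: ScenarioSpec, labels: np.ndarray,
                     draw) -> np.ndarray:
    """Assemble the raw matrix component by component, then z-score columns."""
    X = np.empty((spec.n, spec.d))
    for j in range(spec.k):
        rows = np.flatnonzero(labels == j + 1)
        Z = draw(j, len(rows))
        X[rows] = spec.means[j] + spec.scales[j] * Z
    return normalize_array(X)


def generate_scenario1(spec: ScenarioSpec | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mixture of diagonal-covariance Gaussians (all assumptions satisfied)."""
    spec = spec if spec is not None else ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    labels = _assignments(spec, rng)

    def draw(j: int, m: int) -> np.ndarray:
        return rng.standard_normal((m, spec.d))

    return _fill_components(spec, labels, draw), labels


def generate_scenario2(spec: ScenarioSpec | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian mixture with correlated variables inside each component."""
    spec = spec if spec is not None else ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.correlation_matrix())
    labels = _assignments(spec, rng)

    def draw(j: int, m: int) -> np.ndarray:
        return rng.standard_normal((m, spec.d)) @ L.T

    return _fill_components(spec, labels, draw), labels


def generate_scenario3(spec: ScenarioSpec | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mixture of heterogeneous families, one component with correlation."""
    spec = spec if spec is not None else ScenarioSpec()
    if len(spec.families) != spec.k:
        raise ValueError(
            f"scenario 3 needs exactly {spec.k} component families, "
            f"got {len(spec.families)}"
        )
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.correlation_matrix())
    labels = _assignments(spec, rng)

    def draw(j: int, m: int) -> np.ndarray:
        family = spec.families[j]
        if family == "correlated_gaussian":
            return rng.standard_normal((m, spec.d)) @ L.T
        return _standardized_draw(family, rng, (m, spec.d))

    return _fill_components(spec, labels, draw), labels
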