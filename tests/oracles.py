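"""Independent reference computations used to validate the closed forms.

Everything here deliberately avoids the package's own formulas: the marginal
likelihood is obtained by direct 2-D numerical integration of the
likelihood-times-prior integrand, the adjusted Rand index by exhaustive pair
counting, and the rank-sum p-value by enumerating subsets.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gamma as gamma_fn


def quadrature_marginal_loglik(values, c: float, a: float, b: float) -> float:
    """Log marginal likelihood by brute-force integration over (mu, tau).

    Integrates  prod_i N(x_i | mu, tau) * N(mu | 0, (c tau)^-1)
    * Gamma(tau | a, b)  with nested adaptive quadrature (inner over mu,
    outer over tau).  Intended for small samples only.
    """
    xs = [float(v) for v in values]
    n = len(xs)
    const = (b**a) / gamma_fn(a) * math.sqrt(c / (2.0 * math.pi))
    two_pi = 2.0 * math.pi

    def inner(tau: float) -> float:
        half_tau = 0.5 * tau
        amp = (tau / two_pi) ** (n / 2.0)

        def f(mu: float) -> float:
            s = 0.0
            for x in xs:
                d = x - mu
                s += d * d
            return amp * math.exp(-half_tau * s - 0.5 * c * tau * mu * mu)

        val, _ = integrate.quad(f, -np.inf, np.inf, epsabs=0, epsrel=1e-9,
                                limit=200)
        return const * tau ** (a - 0.5) * math.exp(-b * tau) * val

    val, _ = integrate.quad(inner, 0, np.inf, epsabs=0, epsrel=1e-9,
                            limit=200)
    return math.log(val)


def pair_counting_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index by explicit enumeration of all observation pairs."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n = len(labels_a)
    both = a_only = b_only = neither = 0
    for i, j in itertools.combinations(range(n), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        both += sa and sb
        a_only += sa and not sb
        b_only += sb and not sa
        neither += not sa and not sb
    total = both + a_only + b_only + neither
    sum_a = both + a_only
    sum_b = both + b_only
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p-value by enumerating all group assignments.

    Assumes tie-free data.  Under the null every assignment of the pooled
    ranks to the first group is equally likely; the p-value is the fraction
    of assignments whose rank sum is at least as extreme (two-sided, by
    distance from the null mean) as the observed one.
    """
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - mean)
    count = 0
    total = 0
    for subset in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(subset) - mean) >= obs_dev - 1e-9:
            count += 1
    return count / total
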