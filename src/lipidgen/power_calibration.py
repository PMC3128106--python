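"""Analytic power for additive quantitative-trait tests and
observed-versus-expected significance accounting.

For an additive model the coded allele at frequency ``caf`` with per-allele
effect ``beta`` explains v = 2*caf*(1-caf)*beta^2 of the trait variance. The
two-sided Wald test at level alpha on n individuals has non-centrality
lambda = n*v / (sd^2 - v) (residual variance by decomposition of the
marginal trait SD, the parameterization used by standard power tools for
quantitative traits; pass ``marginal_residual=True`` to use sd^2 directly)
and power

    1 - Phi(z_{1-alpha/2} - sqrt(lambda)) + Phi(-z_{1-alpha/2} - sqrt(lambda)).

Summing per-test powers over a panel gives the expected number of significant
associations; the observed count is compared with it by a one-sample binomial
test (p0 = E/m) or by the exact Poisson-binomial reference distribution of
the sum of unequal-probability Bernoullis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "PowerSpec",
    "ExpectedObserved",
    "analytic_power",
    "expected_significant",
    "binomial_test_observed",
    "poisson_binomial_pmf",
    "poisson_binomial_pvalue",
]

MAX_EXACT_TESTS = 40


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to one power calculation: reference beta, target-population CAF,
    sample size, trait SD (same units as beta), and significance level."""

    beta: float
    caf: float
    n: int
    trait_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.caf < 1.0:
            raise DomainError(f"caf must be in (0, 1), got {self.caf}")
        if self.n < 2:
            raise DomainError("n must be >= 2")
        if self.trait_sd <= 0:
            raise DomainError("trait_sd must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError("alpha must be in (0, 1)")
        if 2 * self.caf * (1 - self.caf) * self.beta**2 >= self.trait_sd**2:
            raise DomainError("genetic variance must be below the trait variance")


@dataclass
class ExpectedObserved:
    """One observed-vs-expected row: m tests, k observed significant,
    E expected (sum of powers), and the comparison p-value."""

    trait: str
    population: str
    m: int
    k: int
    expected: float
    p_value: float
    method: str


def analytic_power(spec: PowerSpec, marginal_residual: bool = False) -> float:
    """Two-sided power of the additive-dose Wald test under ``spec``."""
    v = 2.0 * spec.caf * (1.0 - spec.caf) * spec.beta**2
    denom = spec.trait_sd**2 if marginal_residual else spec.trait_sd**2 - v
    lam = spec.n * v / denom
    z = stats.norm.isf(spec.alpha / 2.0)
    root = np.sqrt(lam)
    return float(stats.norm.sf(z - root) + stats.norm.cdf(-z - root))


def expected_significant(powers: Sequence[float]) -> float:
    """Expected number of significant tests: the sum of per-test powers."""
    p = np.asarray(powers, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("powers must lie in [0, 1]")
    return float(p.sum())


def _one_sided_alternative(k: int, m: int, p0: float) -> str:
    return "less" if k <= m * p0 else "greater"


def binomial_test_observed(k: int, m: int, expected: float, sided: str = "two-sided") -> float:
    """Exact one-sample binomial test of k significant among m tests vs p0 = E/m.

    ``sided``: "two-sided" uses the point-probability method (sum of all
    outcome probabilities no larger than P(X=k)); "one-sided" takes the tail
    in the direction of the observed deviation from E.
    """
    if not 0 <= k <= m:
        raise DomainError(f"need 0 <= k <= m, got k={k}, m={m}")
    if not 0.0 <= expected <= m:
        raise DomainError(f"need 0 <= expected <= m, got {expected}")
    p0 = expected / m
    if p0 == 0.0:
        return 0.0 if k > 0 else 1.0
    if p0 == 1.0:
        return 0.0 if k < m else 1.0
    if sided == "two-sided":
        alternative = "two-sided"
    elif sided == "one-sided":
        alternative = _one_sided_alternative(k, m, p0)
    else:
        raise DomainError(f"sided must be 'two-sided' or 'one-sided', got {sided!r}")
    return float(stats.binomtest(k, m, p0, alternative=alternative).pvalue)


def poisson_binomial_pmf(powers: Sequence[float]) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli(powers).

    Dynamic-programming convolution: O(m^2), exact up to float rounding.
    """
    p = np.asarray(powers, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("powers must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


def poisson_binomial_pvalue(k: int, powers: Sequence[float], sided: str = "two-sided") -> float:
    """Exact tail probability of observing k under the Poisson-binomial reference.

    Two-sided by the point-probability method; one-sided takes the tail in
    the direction of the deviation from E = sum(powers). Exact mode is
    limited to m <= 40 tests.
    """
    p = np.asarray(powers, dtype=float)
    m = p.size
    if m > MAX_EXACT_TESTS:
        raise DomainError(
            f"m={m} too large for the exact Poisson-binomial mode (max {MAX_EXACT_TESTS}); "
            "use binomial_test_observed as the approximation"
        )
    if not 0 <= k <= m:
        raise DomainError(f"need 0 <= k <= m, got k={k}, m={m}")
    pmf = poisson_binomial_pmf(p)
    if sided == "two-sided":
        # include ties up to a relative fp tolerance, as exact tests do
        return float(min(1.0, pmf[pmf <= pmf[k] * (1.0 + 1e-10)].sum()))
    if sided == "one-sided":
        if k <= p.sum():
            return float(min(1.0, pmf[: k + 1].sum()))
        return float(min(1.0, pmf[k:].sum()))
    raise DomainError(f"sided must be 'two-sided' or 'one-sided', got {sided!r}")
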