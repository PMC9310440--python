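"""Bayesian machinery: uniform likelihood, Pareto conjugate prior, discrete
posteriors, and Monte-Carlo conditional-probability estimation.

Notes
-----
The continuous model is the classic conjugate pair: observations
``y_i ~ Uniform(0, a)`` with unknown upper bound ``a``, and prior
``a ~ Pareto(b, K)``.  The posterior is again Pareto with scale
``max(b, max(y))`` and shape ``K + n``.

Conditional probabilities over a simulated cohort are estimated by direct
counting (no Markov chain is involved); the accompanying Monte-Carlo error is
the binomial standard error of the estimated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import math

from .errors import DomainError, EvidenceError

__all__ = [
    "UniformModel",
    "ParetoParams",
    "ConditionalEstimate",
    "uniform_pdf",
    "likelihood",
    "pareto_pdf",
    "pareto_posterior_update",
    "posterior_from_likelihood",
    "estimate_conditional",
    "monte_carlo_error",
]


@dataclass(frozen=True)
class UniformModel:
    """Uniform(0, a) observation model; *a* is the unknown upper bound."""

    a: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise DomainError(f"uniform upper bound a={self.a} must be > 0")


@dataclass(frozen=True)
class ParetoParams:
    """Pareto(b, K) parameters: scale *b* > 0, shape *K* > 0."""

    b: float
    K: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise DomainError(f"Pareto scale b={self.b} must be > 0")
        if not self.K > 0:
            raise DomainError(f"Pareto shape K={self.K} must be > 0")


@dataclass(frozen=True)
class ConditionalEstimate:
    """Counting-based conditional probability with its Monte-Carlo error."""

    estimate: float
    n_evidence: int
    mc_error: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0:
            raise DomainError(f"estimate {self.estimate} outside [0, 1]")
        if self.n_evidence < 0:
            raise DomainError("n_evidence must be nonnegative")


def uniform_pdf(x: float, model: UniformModel) -> float:
    """Density of Uniform(0, a): ``1/a`` on ``[0, a]``, 0 elsewhere."""
    return 1.0 / model.a if 0.0 <= x <= model.a else 0.0


def likelihood(y: Sequence[float], model: UniformModel) -> float:
    """Product of uniform densities over all observations (1 for empty *y*)."""
    result = 1.0
    for value in y:
        result *= uniform_pdf(value, model)
        if result == 0.0:
            return 0.0
    return result


def pareto_pdf(a: float, prior: ParetoParams) -> float:
    """Density of Pareto(b, K): ``K b^K / a^(K+1)`` for ``a >= b``, else 0."""
    if a < prior.b:
        return 0.0
    return prior.K * prior.b ** prior.K / a ** (prior.K + 1.0)


def pareto_posterior_update(prior: ParetoParams, y: Sequence[float]) -> ParetoParams:
    """Closed-form conjugate update for uniform observations.

    Returns ``Pareto(max(b, max(y)), K + n)``; the prior unchanged for empty
    *y*.  Negative observations are outside the support and rejected.
    """
    if not y:
        return prior
    low = min(y)
    if low < 0:
        raise DomainError(f"observation {low} is negative; uniform support is [0, a]")
    return ParetoParams(b=max(prior.b, max(y)), K=prior.K + len(y))


def posterior_from_likelihood(
    prior: Mapping[object, float], lik: Mapping[object, float]
) -> dict[object, float]:
    """Normalized elementwise product of a discrete prior and likelihood.

    Raises
    ------
    DomainError
        Priors do not sum to 1, or a likelihood is negative.
    EvidenceError
        Every prior-times-likelihood product is zero.
    """
    if set(prior) != set(lik):
        raise DomainError("prior and likelihood must share the same hypothesis set")
    total_prior = sum(prior.values())
    if not math.isclose(total_prior, 1.0, rel_tol=0, abs_tol=1e-9):
        raise DomainError(f"priors sum to {total_prior}, expected 1")
    for h, l in lik.items():
        if l < 0:
            raise DomainError(f"likelihood of {h!r} is negative")
    unnormalized = {h: prior[h] * lik[h] for h in prior}
    z = sum(unnormalized.values())
    if z == 0.0:
        raise EvidenceError("degenerate evidence: all prior*likelihood products are zero")
    return {h: v / z for h, v in unnormalized.items()}


def estimate_conditional(
    cohort: Iterable,
    evidence: Callable[[object], bool],
    outcome: Callable[[object], bool],
) -> ConditionalEstimate:
    """P(outcome | evidence) over a cohort, by exhaustive counting.

    Raises
    ------
    EvidenceError
        If no record satisfies the evidence predicate.
    """
    n_evidence = 0
    n_joint = 0
    for record in cohort:
        if evidence(record):
            n_evidence += 1
            if outcome(record):
                n_joint += 1
    if n_evidence == 0:
        raise EvidenceError("no records match evidence")
    p = n_joint / n_evidence
    return ConditionalEstimate(
        estimate=p, n_evidence=n_evidence, mc_error=monte_carlo_error(p, n_evidence)
    )


def monte_carlo_error(p: float, n: int) -> float:
    """Binomial standard error ``sqrt(p (1-p) / n)`` of a proportion."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"proportion {p} outside [0, 1]")
    if n < 1:
        raise DomainError(f"sample size n={n} must be >= 1")
    return math.sqrt(p * (1.0 - p) / n)
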