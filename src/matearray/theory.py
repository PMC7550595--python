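"""Closed-form island-model and sampling-theory helpers.

Under a classical island model with partial selfing, the effective size of
a population of census size ``N`` and selfing rate ``alpha`` is
``N_e = N (1 - alpha/2)``, and the composite gene-flow term that the
Rousset isolation-by-distance regression ``F_st/(1-F_st) = a + b ln(d)``
equates (through its reciprocal) to is

    N (1 - alpha/2) (m_S + (1 - alpha) m_P / 2),

with ``m_S`` and ``m_P`` the seed and pollen migration rates.  Selfing
shrinks both factors: it reduces effective size and halves the effective
pollen flow of the selfed fraction, so the composite term is monotone
decreasing in ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize


@dataclass(frozen=True)
class IslandModelParams:
    """Census size, selfing rate and seed/pollen migration rates."""

    N: float
    alpha: float
    m_S: float
    m_P: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("population size must be positive")
        for name in ("alpha", "m_S", "m_P"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneFlowResult:
    effective_size: float
    composite: float
    reciprocal: float  # the quantity a + b ln(d) estimates


def composite_gene_flow(params: IslandModelParams) -> GeneFlowResult:
    """Effective size, composite gene-flow term and its reciprocal."""
    n_e = params.N * (1.0 - params.alpha / 2.0)
    composite = n_e * (params.m_S + (1.0 - params.alpha) * params.m_P / 2.0)
    reciprocal = math.inf if composite == 0.0 else 1.0 / composite
    return GeneFlowResult(n_e, composite, reciprocal)


def solve_alpha_from_ibd(
    a: float,
    b: float,
    distance: float,
    N: float,
    m_S: float,
    m_P: float,
) -> tuple[float, bool]:
    """Invert the island-model relation for the selfing rate.

    Solves ``1 / [N(1-α/2)(m_S + (1-α) m_P / 2)] = a + b ln(distance)``
    for ``α ∈ [0, 1]``.  Returns ``(alpha, interior)`` where ``interior``
    is False when the target lies outside the achievable range and the
    nearest boundary value is returned instead.
    """
    rhs = a + b * math.log(distance)
    if rhs <= 0.0:
        raise ValueError("a + b ln(distance) must be positive")

    def recip(alpha: float) -> float:
        return composite_gene_flow(IslandModelParams(N, alpha, m_S, m_P)).reciprocal

    lo, hi = recip(0.0), recip(1.0)  # reciprocal is increasing in alpha
    if rhs <= lo:
        return 0.0, False
    if rhs >= hi:
        return 1.0, False
    root = optimize.brentq(lambda al: recip(al) - rhs, 0.0, 1.0, xtol=1e-12)
    return float(root), True


def match_probability(allele_counts: list[int] | tuple[int, ...]) -> float:
    """Chance that two individuals share a full multilocus genotype.

    Assumes alleles at each locus are uniformly distributed, giving the
    product of reciprocals of the per-locus allele counts.  Appending a
    locus can only shrink the probability.
    """
    p = 1.0
    for c in allele_counts:
        if c < 1:
            raise ValueError("allele counts must be >= 1")
        p /= c
    return p


def binomial_se(t: float, n: int, printed_form: bool = False) -> float:
    """Binomial sampling error of an estimated rate.

    The default is the standard binomial standard error ``sqrt(t(1-t)/n)``.
    ``printed_form=True`` gives ``sqrt(t(1-t))/n`` instead, the alternative
    reading in which the root is taken before dividing by the sample size.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if printed_form:
        return math.sqrt(t * (1.0 - t)) / n
    return math.sqrt(t * (1.0 - t) / n)
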