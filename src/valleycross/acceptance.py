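"""Acceptance-probability rules: elitist, SSWM (Kimura fixation), Metropolis.

All three selection schemes share the scheme "mutate, then accept the mutant
with a probability depending only on the fitness difference ``delta_f``":

* elitist: accept iff ``delta_f >= 0`` (ties accepted);
* Metropolis: accept improvements and ties always, worsenings with
  probability ``exp(alpha * delta_f)`` (``alpha`` = inverse temperature);
* SSWM: accept with Kimura's fixation probability
  ``p_fix(delta_f) = (1 - exp(-2 beta delta_f)) / (1 - exp(-2 N beta delta_f))``,
  the probability that a mutant of selective advantage ``beta delta_f``
  initially present in one copy takes over a population of size ``N``.
  At ``delta_f = 0`` the defined limit is ``1/N``; for ``N = 1`` every mutant
  is accepted.  Unlike the other two rules, SSWM can reject improvements.

Evaluation is numerically stable in log space for exponents up to the
overflow edge of float64 (|2 N beta delta_f| ~ 700).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .longpath import OFF_PATH, OffPath

__all__ = [
    "AcceptanceRule",
    "accept_probability",
    "sswm_acceptance",
    "log_sswm_acceptance",
    "fixation_ratio",
    "fixation_bounds",
]

#: Below this magnitude of 2*N*beta*delta_f the delta_f = 0 limit is returned.
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class AcceptanceRule:
    """A selection rule and its parameters.

    Exactly the parameters of the chosen variant must be supplied:
    ``beta`` (selection strength > 0) and ``N`` (population-size parameter
    >= 1) for ``sswm``; ``alpha`` (inverse temperature > 0) for
    ``metropolis``; none for ``elitist``.
    """

    variant: str
    beta: Optional[float] = None
    N: Optional[int] = None
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant == "elitist":
            if self.beta is not None or self.N is not None or self.alpha is not None:
                raise ValueError("elitist rule takes no parameters")
        elif self.variant == "sswm":
            if self.beta is None or self.N is None or self.alpha is not None:
                raise ValueError("sswm rule takes exactly beta and N")
            if not self.beta > 0:
                raise ValueError(f"beta must be positive, got {self.beta}")
            if self.N < 1 or self.N != int(self.N):
                raise ValueError(f"N must be an integer >= 1, got {self.N}")
        elif self.variant == "metropolis":
            if self.alpha is None or self.beta is not None or self.N is not None:
                raise ValueError("metropolis rule takes exactly alpha")
            if not self.alpha > 0:
                raise ValueError(f"alpha must be positive, got {self.alpha}")
        else:
            raise ValueError(f"unknown variant {self.variant!r}")

    @classmethod
    def elitist(cls) -> "AcceptanceRule":
        return cls("elitist")

    @classmethod
    def sswm(cls, beta: float, N: int) -> "AcceptanceRule":
        return cls("sswm", beta=beta, N=N)

    @classmethod
    def metropolis(cls, alpha: float) -> "AcceptanceRule":
        return cls("metropolis", alpha=alpha)

    @property
    def lam(self) -> float:
        """Exponential-ratio constant: ``p_acc(df)/p_acc(-df) = exp(lam*df)``.

        ``lam = 2*beta*(N-1)`` for SSWM and ``lam = alpha`` for Metropolis;
        undefined for the elitist rule.
        """
        if self.variant == "sswm":
            return 2.0 * self.beta * (self.N - 1)
        if self.variant == "metropolis":
            return self.alpha
        raise ValueError("elitist rule has no exponential acceptance ratio")

    def __call__(self, delta_f: Union[float, OffPath]) -> float:
        return accept_probability(self, delta_f)


def log_sswm_acceptance(beta: float, N: int, delta_f: float) -> float:
    """``log p_fix(delta_f)``, stable for exponents far beyond float range."""
    a = 2.0 * beta * delta_f
    b = N * a
    if abs(b) < _ZERO_TOL:
        return -math.log(N)  # defined limit 1/N
    if a > 0:
        # both 1-e^{-a} and 1-e^{-b} in (0, 1]; -expm1 keeps precision near 0
        return math.log(-math.expm1(-a)) - math.log(-math.expm1(-b))
    # a < 0: p = (e^{-a} - 1)/(e^{-b} - 1); factor the dominant exponentials
    # (-expm1 rather than 1 - exp: no cancellation for small |a|)
    return (N - 1) * a + math.log(-math.expm1(a)) - math.log(-math.expm1(b))


def sswm_acceptance(beta: float, N: int, delta_f: float) -> float:
    """Kimura fixation probability ``p_fix(delta_f)`` (SSWM acceptance)."""
    return math.exp(log_sswm_acceptance(beta, N, delta_f))


def accept_probability(
    rule: AcceptanceRule, delta_f: Union[float, OffPath]
) -> float:
    """Acceptance probability of a fitness difference under ``rule``.

    The :data:`~valleycross.longpath.OFF_PATH` sentinel is rejected with
    probability exactly 0 by every rule.
    """
    if delta_f is OFF_PATH:
        return 0.0
    df = float(delta_f)
    if rule.variant == "elitist":
        return 1.0 if df >= 0 else 0.0
    if rule.variant == "metropolis":
        return 1.0 if df >= 0 else math.exp(rule.alpha * df)
    return sswm_acceptance(rule.beta, rule.N, df)


def fixation_ratio(beta: float, N: int, delta_f: float) -> float:
    """``p_fix(-delta_f) / p_fix(+delta_f)``, computed in log space.

    Algebraically this equals ``exp(-2 (N-1) beta delta_f)``: self-cancelling
    exponential factors make the backward/forward acceptance ratio depend
    only on ``(N-1) beta delta_f``.
    """
    return math.exp(
        log_sswm_acceptance(beta, N, -delta_f) - log_sswm_acceptance(beta, N, delta_f)
    )


def fixation_bounds(beta: float, N: int, delta_f: float) -> tuple[float, float]:
    """Elementary lower/upper bounds bracketing ``p_fix(delta_f)``.

    For ``delta_f >= 0``::

        2 b df / (1 + 2 b df)  <=  p_fix  <=  2 b df / (1 - e^{-2 N b df})

    and for ``delta_f <= 0``::

        (-2 b df) e^{2 N b df}  <=  p_fix  <=  e^{-2 b df} / (e^{-2 N b df} - 1).

    At ``delta_f = 0`` the limits give ``(0, 1/N)``.
    """
    a = 2.0 * beta * delta_f
    b = N * a
    if abs(b) < _ZERO_TOL:
        return 0.0, 1.0 / N
    if delta_f > 0:
        lower = a / (1.0 + a)
        upper = a / (-math.expm1(-b))
        return lower, upper
    lower = (-a) * math.exp(b)
    # upper = e^{-a} / (e^{-b} - 1) in log space to survive large -b
    log_den = -b if -b > 700 else math.log(math.expm1(-b))
    upper = math.exp(-a - log_den)
    return lower, upper
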