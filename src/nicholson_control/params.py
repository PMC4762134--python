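"""Model parameters, equilibrium, and stability-regime classification.

The delayed Nicholson's blowflies equation

    x'(t) = a x(t - tau) exp(-b x(t - tau)) - c x(t)

models an adult blowfly population with delayed recruitment and linear
mortality: ``a`` is the maximum per-capita daily egg production rate,
``1/b`` the population size at which reproduction is maximal, ``c`` the
per-capita daily death rate, and ``tau`` the generation time.  For
``a > c`` there is a unique positive equilibrium ``x* = (1/b) ln(a/c)``.

Hybrid control rescales the vector field by a gain ``alpha`` in (0, 1]
and adds the state feedback ``(1 - alpha) tau (u(t-1) - u*)`` (in scaled
time, where the delay is normalized to 1).  The equilibrium is
unchanged, but the stability boundary moves: the equilibrium is stable
for every delay whenever

    (1 - alpha)/(alpha c)  <  b u*  <  2 + (1 - alpha)/(alpha c),

and loses stability at a finite critical delay when ``b u*`` exceeds the
upper threshold.  ``alpha = 1`` recovers the uncontrolled system, whose
thresholds are 0 and 2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "BlowfliesParams",
    "ControlSetup",
    "Regime",
    "RegimeVerdict",
    "equilibrium",
    "classify_regime",
]


@dataclass(frozen=True)
class BlowfliesParams:
    """Biological rates of the blowflies model.

    Parameters
    ----------
    a : float
        Maximum per-capita daily egg production rate (1/day), > 0.
    b : float
        Inverse of the population size at maximal reproduction, > 0.
    c : float
        Per-capita daily adult death rate (1/day), > 0.

    A positive equilibrium requires ``a > c``; this is validated eagerly
    because every downstream formula uses ``ln(a/c)``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a positive finite real, got {value!r}")
        if self.a <= self.c:
            raise ValueError(
                f"no positive equilibrium: need a > c, got a={self.a}, c={self.c}"
            )

    @property
    def u_star(self) -> float:
        """Positive equilibrium (1/b) ln(a/c)."""
        return equilibrium(self)

    @property
    def b_u_star(self) -> float:
        """The dimensionless product b*u* = ln(a/c) that governs stability."""
        return math.log(self.a / self.c)


@dataclass(frozen=True)
class ControlSetup:
    """Hybrid-control gain and delay.

    ``alpha`` in (0, 1] is the parameter-perturbation gain (1 = no
    control); ``tau`` >= 0 is the delay, the bifurcation parameter.
    """

    alpha: float
    tau: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha!r}")
        if not (math.isfinite(self.tau) and self.tau >= 0):
            raise ValueError(f"tau must be a nonnegative real, got {self.tau!r}")


class Regime(enum.Enum):
    """Stability regime of the controlled equilibrium."""

    STABLE_ALL_TAU = "stable_all_tau"
    CONDITIONAL_STABILITY = "conditional_stability"
    OUT_OF_THEORY = "out_of_theory"


@dataclass(frozen=True)
class RegimeVerdict:
    """Outcome of the threshold comparison for given (params, alpha).

    ``lower_threshold = (1-alpha)/(alpha c)`` and ``upper_threshold =
    lower_threshold + 2``.  Strictly between them the equilibrium is
    asymptotically stable for every delay; strictly above the upper
    threshold it is stable only up to a finite critical delay.  Values
    at or below the lower threshold (including exact boundary hits) are
    outside the theory and labelled accordingly.
    """

    regime: Regime
    lower_threshold: float
    upper_threshold: float
    b_u_star: float


def equilibrium(params: BlowfliesParams) -> float:
    """Positive equilibrium u* = (1/b) ln(a/c) of the blowflies model.

    The returned value satisfies the fixed-point identity
    ``c = a exp(-b u*)`` to machine precision.
    """
    return math.log(params.a / params.c) / params.b


def classify_regime(params: BlowfliesParams, alpha: float) -> RegimeVerdict:
    """Classify the stability regime of the hybrid-controlled equilibrium.

    Compares ``b u* = ln(a/c)`` with the control-dependent thresholds
    ``(1-alpha)/(alpha c)`` and ``2 + (1-alpha)/(alpha c)``.  Exact
    boundary hits are classified ``OUT_OF_THEORY`` (the stability
    theorems use strict inequalities and make no claim at equality), as
    is the region at or below the lower threshold.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha!r}")
    lower = (1.0 - alpha) / (alpha * params.c)
    upper = 2.0 + lower
    bu = params.b_u_star
    if lower < bu < upper:
        regime = Regime.STABLE_ALL_TAU
    elif bu > upper:
        regime = Regime.CONDITIONAL_STABILITY
    else:
        regime = Regime.OUT_OF_THEORY
    return RegimeVerdict(
        regime=regime, lower_threshold=lower, upper_threshold=upper, b_u_star=bu
    )
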