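"""Hopf analysis of the hybrid-controlled continuous-time model.

In scaled time (``u(t) = x(tau t)``, delay normalized to 1) the
controlled equation linearized at the equilibrium has characteristic
equation

    lambda = alpha c tau [(1 - b u*) e^{-lambda} - 1] + (1 - alpha) tau e^{-lambda}.

Writing ``beta = alpha c (1 - b u*) + (1 - alpha)`` for the delayed-term
coefficient (per unit tau), a purely imaginary root ``lambda = i omega``
requires

    beta tau cos(omega) =  alpha c tau,
    beta tau sin(omega) = -omega,

so the crossing angle ``theta0`` solves ``cos theta0 = alpha c / beta``
with ``sin theta0 = -rate/beta`` where ``rate = sqrt(beta^2 - (alpha c)^2)``
is the angular rate of the crossing frequency in tau (``omega = tau * rate``).
A crossing exists iff the radicand is positive, i.e. iff
``b u* > 2 + (1 - alpha)/(alpha c)``.  The critical delays are

    tau_k = (theta0 + 2 k pi) / rate,   k = 0, 1, 2, ...

and at each the eigenvalue pair crosses the imaginary axis with positive
speed (transversality), so a Hopf bifurcation occurs at tau_0.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

from .params import BlowfliesParams, Regime, classify_regime

__all__ = [
    "ContinuousCharacteristic",
    "ContinuousHopfResult",
    "characteristic_value",
    "hopf_points",
    "verify_transversality",
    "track_root",
]


@dataclass(frozen=True)
class ContinuousCharacteristic:
    """Coefficients of the scalar transcendental characteristic equation.

    ``decay_coeff = alpha*c`` multiplies the instantaneous term;
    ``feedback_coeff`` is beta = alpha*c*(1 - b u*) + (1 - alpha), the
    coefficient of the delayed exponential term per unit tau.  In the
    conditionally stable regime beta < -alpha*c < 0, which is exactly
    what makes the crossing radicand beta^2 - (alpha c)^2 positive.
    """

    alpha_c: float
    feedback_coeff: float
    decay_coeff: float

    @classmethod
    def from_params(cls, params: BlowfliesParams, alpha: float) -> "ContinuousCharacteristic":
        ac = alpha * params.c
        beta = ac * (1.0 - params.b_u_star) + (1.0 - alpha)
        return cls(alpha_c=ac, feedback_coeff=beta, decay_coeff=ac)


@dataclass(frozen=True)
class ContinuousHopfResult:
    """First crossing structure of the controlled characteristic equation.

    ``theta0`` is the crossing angle in (pi/2, pi); ``angular_rate`` the
    rate sqrt(beta^2 - (alpha c)^2) such that the crossing frequency is
    omega = tau * angular_rate; ``tau_k`` the increasing sequence of
    critical delays, spaced by 2 pi / angular_rate; ``transversality``
    the eigenvalue crossing speeds d(Re lambda)/dtau at each tau_k, all
    positive.
    """

    beta: float
    alpha_c: float
    theta0: float
    angular_rate: float
    tau_k: tuple[float, ...]
    transversality: tuple[float, ...]

    def to_report(self) -> dict:
        return {
            "beta": self.beta,
            "angular_rate": self.angular_rate,
            "theta0": self.theta0,
            "tau_k": list(self.tau_k),
            "transversality": list(self.transversality),
        }


def characteristic_value(
    chi: ContinuousCharacteristic, tau: float, lam: complex
) -> complex:
    """Residual of the characteristic equation at ``lam``.

    Returns ``lam - alpha c tau [(1 - b u*) e^{-lam} - 1]
    - (1 - alpha) tau e^{-lam}``; a characteristic root gives 0.  Using
    beta, this is ``lam + alpha c tau - beta tau e^{-lam}``.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return lam + chi.alpha_c * tau - chi.feedback_coeff * tau * cmath.exp(-lam)


def _transversality_closed_form(
    chi: ContinuousCharacteristic, theta0: float, tau_k: float
) -> float:
    """d(Re lambda)/dtau at the crossing, from implicit differentiation.

    With F(lam, tau) = lam + alpha c tau - beta tau e^{-lam}, the root
    derivative is (beta e^{-lam} - alpha c)/(1 + beta tau e^{-lam});
    imposing the crossing conditions beta cos(theta) = alpha c and
    beta sin(theta) = -theta/tau leaves

        Re(dlam/dtau) = tau_k (beta^2 - (alpha c)^2) / Delta,

    where Delta = [1 + tau_k beta cos(theta)]^2 + [tau_k beta sin(theta)]^2.
    Strictly positive whenever a crossing exists.
    """
    beta = chi.feedback_coeff
    ac = chi.alpha_c
    delta = (1.0 + tau_k * beta * math.cos(theta0)) ** 2 + (
        tau_k * beta * math.sin(theta0)
    ) ** 2
    return tau_k * (beta * beta - ac * ac) / delta


def hopf_points(
    params: BlowfliesParams, alpha: float, k_max: int = 3
) -> ContinuousHopfResult:
    """Critical delays and crossing data of the controlled model.

    Requires the conditionally stable regime
    ``b u* > 2 + (1 - alpha)/(alpha c)``; otherwise no purely imaginary
    characteristic root exists and a ``ValueError`` is raised.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    verdict = classify_regime(params, alpha)
    if verdict.regime is not Regime.CONDITIONAL_STABILITY:
        raise ValueError(
            "no Hopf point: crossing requires b*u_star > 2 + (1-alpha)/(alpha c) "
            f"(regime is {verdict.regime.value})"
        )
    chi = ContinuousCharacteristic.from_params(params, alpha)
    beta, ac = chi.feedback_coeff, chi.alpha_c
    radicand = beta * beta - ac * ac
    if radicand <= 0:
        raise ValueError("no Hopf point: crossing radicand is nonpositive")
    rate = math.sqrt(radicand)
    # cos(theta0) = ac/beta < 0 and sin(theta0) = -rate/beta > 0 (beta < 0),
    # so the quadrant-correct angle lies in (pi/2, pi).
    theta0 = math.atan2(-rate / beta, ac / beta)
    tau_k = tuple((theta0 + 2.0 * math.pi * k) / rate for k in range(k_max + 1))
    trans = tuple(_transversality_closed_form(chi, theta0, t) for t in tau_k)
    return ContinuousHopfResult(
        beta=beta,
        alpha_c=ac,
        theta0=theta0,
        angular_rate=rate,
        tau_k=tau_k,
        transversality=trans,
    )


def verify_transversality(
    params: BlowfliesParams, alpha: float, tau_k_index: int = 0
) -> float:
    """Closed-form crossing speed d(Re lambda)/dtau at tau_k (positive)."""
    result = hopf_points(params, alpha, k_max=max(tau_k_index, 0))
    return result.transversality[tau_k_index]


def track_root(
    chi: ContinuousCharacteristic,
    tau: float,
    lam_guess: complex,
    tol: float = 1e-13,
    max_iter: int = 100,
) -> complex:
    """Refine a characteristic root by damped complex Newton iteration.

    Used to continue a root lambda(tau) across a crossing, e.g. for
    finite-difference checks of the transversality closed form.  The
    derivative of the residual is ``1 + beta tau e^{-lam}``.
    """
    lam = complex(lam_guess)
    for _ in range(max_iter):
        f = characteristic_value(chi, tau, lam)
        if abs(f) < tol:
            return lam
        df = 1.0 + chi.feedback_coeff * tau * cmath.exp(-lam)
        if df == 0:
            raise ArithmeticError("degenerate Newton step while tracking root")
        step = f / df
        # damp oversized steps to stay on the tracked branch
        if abs(step) > 0.5:
            step *= 0.5 / abs(step)
        lam -= step
    raise ArithmeticError(f"root tracking did not converge at tau={tau}")
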