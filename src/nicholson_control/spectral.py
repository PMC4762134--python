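"""Linear stability of the discrete schemes and Neimark-Sacker detection.

Linearizing either scheme at the fixed point ``v = 0`` and stacking the
delayed states ``V_n = (v_n, ..., v_{n-m})`` gives ``V_{n+1} = A V_n``
with the sparse companion-like matrix ``A`` whose characteristic
polynomial is the trinomial

    lambda^{m+1} - a0~ lambda^m - a1~ = 0,

with, for the NSFD scheme (``s = alpha c tau h``),

    a0~ = e^{-s},     a1~ = (1 - e^{-s}) (1 + (1-alpha)/(alpha c) - b u*),

and for the Euler scheme

    a0~ = 1 - s,      a1~ = tau h [alpha c (1 - b u*) + (1 - alpha)].

The fixed point is asymptotically stable while all roots lie strictly
inside the unit circle.  In the conditionally stable regime the
dominant complex pair reaches the unit circle at a finite critical
delay tau_0 — a Neimark-Sacker bifurcation — located here by scanning
and bisecting the spectral radius.  At a crossing the angle satisfies

    cos(omega) = 1 + (1 - e^{-s})^2 (b u* - L)(2 + L - b u*) / (2 e^{-s}),

with ``L = (1-alpha)/(alpha c)`` (NSFD), which exceeds 1 throughout the
stable-for-all-delays regime — no crossing can occur there.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import BlowfliesParams, Regime, classify_regime
from .schemes import SchemeKind, StepGrid

__all__ = [
    "CharPoly",
    "CriticalPoint",
    "char_poly",
    "companion_matrix",
    "poly_roots",
    "dominant_root",
    "spectral_radius",
    "crossing_angle",
    "critical_tau",
    "nsfd_radius_slope",
    "eigen_derivative_check",
    "zero_delay_slope",
]


@dataclass(frozen=True)
class CharPoly:
    """The trinomial characteristic polynomial lambda^{m+1} - a0~ lambda^m - a1~."""

    m: int
    a0_tilde: float
    a1_tilde: float
    scheme_kind: SchemeKind

    @property
    def degree(self) -> int:
        return self.m + 1

    def __call__(self, lam: complex) -> complex:
        return lam ** (self.m + 1) - self.a0_tilde * lam**self.m - self.a1_tilde


def char_poly(
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    grid: StepGrid,
    scheme_kind: SchemeKind,
) -> CharPoly:
    """Characteristic polynomial of the linearized scheme at v = 0."""
    s = alpha * params.c * tau * grid.h
    bu = params.b_u_star
    lower = (1.0 - alpha) / (alpha * params.c)
    if scheme_kind is SchemeKind.NSFD:
        e = math.exp(-s)
        a0, a1 = e, (1.0 - e) * (1.0 + lower - bu)
    else:
        a0 = 1.0 - s
        a1 = tau * grid.h * (alpha * params.c * (1.0 - bu) + (1.0 - alpha))
    return CharPoly(m=grid.m, a0_tilde=a0, a1_tilde=a1, scheme_kind=scheme_kind)


def companion_matrix(poly: CharPoly) -> np.ndarray:
    """Matrix with first row (a0~, 0, ..., 0, a1~) and unit subdiagonal.

    Its characteristic polynomial is exactly ``poly``; its eigenvalues
    govern local stability of the fixed point.
    """
    n = poly.m + 1
    mat = np.zeros((n, n))
    mat[0, 0] = poly.a0_tilde
    mat[0, -1] = poly.a1_tilde
    for i in range(1, n):
        mat[i, i - 1] = 1.0
    return mat


def poly_roots(poly: CharPoly) -> np.ndarray:
    """All roots of the characteristic polynomial (companion eigenvalues)."""
    return np.linalg.eigvals(companion_matrix(poly))


def dominant_root(poly: CharPoly) -> complex:
    """Root of maximal modulus; the positive-imaginary representative
    is returned for a complex pair."""
    roots = poly_roots(poly)
    lam = roots[int(np.argmax(np.abs(roots)))]
    return lam.conjugate() if lam.imag < 0 else complex(lam)


def spectral_radius(poly: CharPoly) -> float:
    """Maximum root modulus; stability of the map requires < 1."""
    return float(np.max(np.abs(poly_roots(poly))))


def crossing_angle(
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    grid: StepGrid,
    k: int = 0,
) -> float:
    """Unit-circle crossing angle of the NSFD characteristic polynomial.

    Evaluates the closed-form expression for ``cos(omega)`` implied by a
    root on the unit circle; raises if its magnitude exceeds 1 (no
    crossing angle exists at this tau — always the case in the
    stable-for-all-delays regime, where the right-hand side exceeds 1).
    ``k`` applies the conventional 2*k*pi shift, valid for
    k <= (m-1)//2.
    """
    if not 0 <= k <= (grid.m - 1) // 2:
        raise ValueError(f"k must lie in [0, (m-1)//2], got {k}")
    s = alpha * params.c * tau * grid.h
    e = math.exp(-s)
    bu = params.b_u_star
    lower = (1.0 - alpha) / (alpha * params.c)
    rhs = 1.0 + (1.0 - e) ** 2 * (bu - lower) * (2.0 + lower - bu) / (2.0 * e)
    if abs(rhs) > 1.0:
        raise ValueError(f"no real crossing angle: cos(omega) = {rhs:.6g}")
    return math.acos(rhs) + 2.0 * math.pi * k


def nsfd_radius_slope(
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    omega: float,
    grid: StepGrid,
) -> float:
    """Closed-form d(r^2)/dtau of the NSFD crossing pair at (tau, omega).

    Positive at every Neimark-Sacker crossing, for any step-size: the
    eigenvalue pair leaves the unit disc with nonzero speed.
    """
    m, h = grid.m, grid.h
    e = math.exp(-alpha * params.c * tau * h)
    num = 2.0 * alpha * params.c * h * e * (m + 1 + m * e) * (1.0 - math.cos(omega))
    den = (1.0 - e) * (
        ((m + 1) * math.cos(omega) - m * e) ** 2 + ((m + 1) * math.sin(omega)) ** 2
    )
    return num / den


@dataclass(frozen=True)
class CriticalPoint:
    """First unit-circle crossing of the dominant eigenvalue pair."""

    tau0: float
    omega0: float
    crossing_eigenvalue: complex
    transversality: float
    k_index: int
    scheme_kind: SchemeKind
    grid: StepGrid
    alpha: float

    def to_report(self) -> dict:
        return {
            "scheme": self.scheme_kind.value,
            "alpha": self.alpha,
            "h": self.grid.h,
            "m": self.grid.m,
            "tau0": self.tau0,
            "omega0": self.omega0,
            "transversality": self.transversality,
            "crossing_eigenvalue": [
                self.crossing_eigenvalue.real,
                self.crossing_eigenvalue.imag,
            ],
        }


def _fd_radius_slope(
    params: BlowfliesParams,
    alpha: float,
    tau0: float,
    grid: StepGrid,
    scheme_kind: SchemeKind,
    step: float = 1e-5,
) -> float:
    """Two-sided finite difference of r^2 of the dominant root across tau0."""
    r_plus = spectral_radius(char_poly(params, alpha, tau0 + step, grid, scheme_kind))
    r_minus = spectral_radius(char_poly(params, alpha, tau0 - step, grid, scheme_kind))
    return (r_plus**2 - r_minus**2) / (2.0 * step)


def critical_tau(
    params: BlowfliesParams,
    alpha: float,
    grid: StepGrid,
    scheme_kind: SchemeKind = SchemeKind.NSFD,
    tau_max: float = 10.0,
    tol: float = 1e-8,
    scan_step: float = 0.01,
    tau_min: float = 1e-6,
    unit_tol: float = 1e-8,
) -> CriticalPoint:
    """Locate the first Neimark-Sacker crossing by spectral-radius bisection.

    Scans tau upward from ``tau_min`` (the scan cannot start at 0, where
    the polynomial degenerately carries the root lambda = 1) for the
    first sign change of ``spectral_radius(tau) - 1`` and bisects to
    ``tol``.  Verifies that the crossing eigenvalue is a genuine complex
    pair; a real crossing raises ("flip crossing"), which the theory
    does not cover.  The transversality value is the closed-form
    d(r^2)/dtau for the NSFD scheme and a finite-difference estimate for
    the Euler scheme.
    """
    verdict = classify_regime(params, alpha)
    if verdict.regime is not Regime.CONDITIONAL_STABILITY:
        raise ValueError(
            "critical delay requires the conditionally stable regime "
            f"(b u* > 2 + (1-alpha)/(alpha c)); regime is {verdict.regime.value}"
        )

    def excess(tau: float) -> float:
        return spectral_radius(char_poly(params, alpha, tau, grid, scheme_kind)) - 1.0

    tau_prev, f_prev = tau_min, excess(tau_min)
    tau0 = None
    tau = tau_min + scan_step
    while tau <= tau_max + scan_step / 2:
        f = excess(min(tau, tau_max))
        if f_prev < 0.0 <= f:
            tau0 = brentq(excess, tau_prev, min(tau, tau_max), xtol=tol)
            break
        tau_prev, f_prev = min(tau, tau_max), f
        tau += scan_step
    if tau0 is None:
        raise ValueError(
            f"no crossing in (0, {tau_max}]: spectral radius stays below 1 "
            "(stable for all scanned delays)"
        )

    lam = dominant_root(char_poly(params, alpha, tau0, grid, scheme_kind))
    if abs(abs(lam) - 1.0) > max(unit_tol, 10 * tol):
        raise ArithmeticError(
            f"crossing eigenvalue modulus {abs(lam):.3e} is off the unit circle"
        )
    if abs(lam.imag) < 1e-8:
        raise ValueError(
            f"flip crossing: dominant eigenvalue {lam:.6g} at tau0={tau0:.6g} is real"
        )
    omega0 = abs(cmath.phase(lam))
    if scheme_kind is SchemeKind.NSFD:
        trans = nsfd_radius_slope(params, alpha, tau0, omega0, grid)
    else:
        trans = _fd_radius_slope(params, alpha, tau0, grid, scheme_kind)
    return CriticalPoint(
        tau0=tau0,
        omega0=omega0,
        crossing_eigenvalue=lam,
        transversality=trans,
        k_index=0,
        scheme_kind=scheme_kind,
        grid=grid,
        alpha=alpha,
    )


def eigen_derivative_check(
    params: BlowfliesParams,
    alpha: float,
    grid: StepGrid,
    scheme_kind: SchemeKind,
    cp: CriticalPoint,
    step: float = 1e-5,
) -> float:
    """Finite-difference d(r^2)/dtau of the dominant root across tau0.

    Independent of the closed form used by :func:`critical_tau`; must be
    positive at a genuine Neimark-Sacker crossing.
    """
    return _fd_radius_slope(params, alpha, cp.tau0, grid, scheme_kind, step=step)


def zero_delay_slope(params: BlowfliesParams, alpha: float, grid: StepGrid) -> float:
    """d|lambda|^2/dtau at tau = 0 for the root departing lambda = 1.

    Closed form ``2 h (1 - alpha - b u* alpha c)``; negative whenever
    ``b u* > (1-alpha)/(alpha c)``, so the unit root at zero delay moves
    strictly into the unit disc and the fixed point is stable for small
    delays.
    """
    return 2.0 * grid.h * (1.0 - alpha - params.b_u_star * alpha * params.c)
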