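"""Direction and stability of the Neimark-Sacker bifurcation (NSFD map).

At the critical delay tau_0 the NSFD map restricted to its
two-dimensional center manifold reduces, after the standard
complex-coordinate change, to

    z -> lambda0 z + sum g_jk z^j zbar^k / (j! k!) + ...,

with ``lambda0 = e^{i omega0}``.  The quadratic and cubic terms of the
map act only on the delayed coordinate; their Taylor coefficients are

    b~ = (1 - e^{-s}) (b^2 u* - 2 b),
    c~ = (1 - e^{-s}) (3 b^2 - b^3 u*),        s = alpha c tau0 h,

and enter through the multilinear forms B(phi, psi) = (b~ phi_m psi_m,
0, ..., 0) and C(phi, psi, chi) = (c~ phi_m psi_m chi_m, 0, ..., 0).
Projection onto the critical eigenspace uses the right eigenvector
``q = (e^{i m w0}, ..., e^{i w0}, 1)`` and the adjoint eigenvector
``q*``, normalized so that <q*, q> = sum conj(q*_i) q_i = 1 via the
constant

    K = [e^{i m w0} + m a1~ e^{-i w0}]^{-1}.

The first Lyapunov-type coefficient c1(tau0) then decides the
bifurcation scenario: an attracting (repelling) invariant closed curve
exists for tau just above tau0 iff Re[e^{-i omega0} c1(tau0)] < 0 (> 0).
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .params import BlowfliesParams
from .schemes import SchemeKind, StepGrid
from .spectral import CharPoly, CriticalPoint, char_poly, critical_tau

__all__ = [
    "EigenPair",
    "NormalFormResult",
    "eigen_pair",
    "taylor_coefficients",
    "multilinear_forms",
    "critical_coefficient",
]

#: guard below which divisions in the projection formulas are declared
#: resonant (lambda0 too close to a low root of unity)
RESONANCE_TOL = 1e-10


class ResonanceError(ArithmeticError):
    """Raised when lambda0 is too close to a low root of unity for the
    normal-form divisions to be well conditioned."""


def _p(xi: complex, m: int) -> np.ndarray:
    """Vandermonde-type eigenvector candidate (xi^m, xi^{m-1}, ..., 1)."""
    return np.array([xi ** (m - k) for k in range(m + 1)], dtype=complex)


@dataclass(frozen=True)
class EigenPair:
    """Critical right/adjoint eigenvectors of the linearized NSFD map."""

    q: np.ndarray
    q_star: np.ndarray
    K: complex
    lambda0: complex

    def inner(self, x: np.ndarray) -> complex:
        """Projection <q*, x> = sum conj(q*_i) x_i."""
        return complex(np.vdot(self.q_star, x))


def eigen_pair(poly: CharPoly, omega0: float, root_tol: float = 1e-8) -> EigenPair:
    """Eigenvector pair of the companion matrix at lambda0 = e^{i omega0}.

    ``q`` follows from the Vandermonde structure of the companion
    matrix; ``q*`` is the explicit adjoint eigenvector, scaled by the
    normalization constant K so that <q*, q> = 1 exactly.  Raises if
    e^{i omega0} is not a root of ``poly`` to within ``root_tol``.
    """
    m = poly.m
    lam0 = cmath.exp(1j * omega0)
    if abs(poly(lam0)) > root_tol:
        raise ValueError(
            f"e^(i omega0) is not a characteristic root: residual {abs(poly(lam0)):.3e}"
        )
    q = _p(lam0, m)
    a1 = poly.a1_tilde
    K = 1.0 / (cmath.exp(1j * m * omega0) + m * a1 * cmath.exp(-1j * omega0))
    q_star = np.empty(m + 1, dtype=complex)
    q_star[0] = 1.0
    for k in range(1, m + 1):
        q_star[k] = a1 * cmath.exp(1j * (m - k + 1) * omega0)
    q_star *= np.conj(K)
    return EigenPair(q=q, q_star=q_star, K=K, lambda0=lam0)


def taylor_coefficients(
    params: BlowfliesParams, alpha: float, tau: float, grid: StepGrid
) -> tuple[float, float]:
    """Quadratic and cubic Taylor coefficients (b~, c~) of the NSFD map
    nonlinearity in the delayed coordinate at v = 0."""
    import math

    e = math.exp(-alpha * params.c * tau * grid.h)
    b, u = params.b, params.u_star
    b_tilde = (1.0 - e) * (b * b * u - 2.0 * b)
    c_tilde = (1.0 - e) * (3.0 * b * b - b**3 * u)
    return b_tilde, c_tilde


def multilinear_forms(
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    grid: StepGrid,
    phi: np.ndarray,
    psi: np.ndarray,
    chi: np.ndarray | None = None,
) -> tuple[complex, complex]:
    """Scalar bilinear/trilinear forms (b0(phi,psi), c0(phi,psi,chi)).

    Both act only on the delayed (last) coordinate: b0 = b~ phi_m psi_m
    and c0 = c~ phi_m psi_m chi_m (symmetric polarization of the
    diagonal forms).  ``chi`` defaults to ``psi``.
    """
    m = grid.m
    if chi is None:
        chi = psi
    b_tilde, c_tilde = taylor_coefficients(params, alpha, tau, grid)
    b0 = b_tilde * phi[m] * psi[m]
    c0 = c_tilde * phi[m] * psi[m] * chi[m]
    return complex(b0), complex(c0)


def _B(b_tilde: float, phi: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    out = np.zeros(m + 1, dtype=complex)
    out[0] = b_tilde * phi[m] * psi[m]
    return out


def _C(
    c_tilde: float, phi: np.ndarray, psi: np.ndarray, chi: np.ndarray, m: int
) -> np.ndarray:
    out = np.zeros(m + 1, dtype=complex)
    out[0] = c_tilde * phi[m] * psi[m] * chi[m]
    return out


@dataclass(frozen=True)
class NormalFormResult:
    """Normal-form data of the Neimark-Sacker point of the NSFD map.

    ``c1`` is the critical coefficient assembled from the g-coefficients
    and center-manifold corrections; ``c1_closed`` the equivalent
    compact expression; both agree to rounding.  The invariant curve
    bifurcating for tau > tau0 is attracting iff
    ``stability_indicator = Re[e^{-i omega0} c1] < 0``.
    """

    critical_point: CriticalPoint
    eigen: EigenPair
    b_tilde: float
    c_tilde: float
    g20: complex
    g11: complex
    g02: complex
    g21: complex
    w20: np.ndarray
    w11: np.ndarray
    c1: complex
    c1_closed: complex
    stability_indicator: float
    classification: str

    def to_report(self) -> dict:
        ri = lambda z: [z.real, z.imag]  # noqa: E731
        return {
            "tau0": self.critical_point.tau0,
            "omega0": self.critical_point.omega0,
            "g20": ri(self.g20),
            "g11": ri(self.g11),
            "g02": ri(self.g02),
            "g21": ri(self.g21),
            "c1": ri(self.c1),
            "c1_closed": ri(self.c1_closed),
            "stability_indicator": self.stability_indicator,
            "classification": self.classification,
        }


def critical_coefficient(
    params: BlowfliesParams,
    alpha: float,
    grid: StepGrid,
    critical_point: CriticalPoint | None = None,
    tau_max: float = 10.0,
    tol: float = 1e-12,
) -> NormalFormResult:
    """Normal-form classification of the NSFD Neimark-Sacker point.

    Locates the crossing (unless a precomputed ``critical_point`` is
    supplied), builds the critical eigenpair, evaluates the
    g-coefficients and the center-manifold correction vectors w20/w11,
    and assembles c1(tau0) both from the general projection formula and
    from the compact closed form.  Divisions are guarded: a lambda0 too
    close to a low root of unity raises :class:`ResonanceError`.
    """
    if critical_point is None:
        critical_point = critical_tau(
            params, alpha, grid, SchemeKind.NSFD, tau_max=tau_max, tol=tol
        )
    elif critical_point.scheme_kind is not SchemeKind.NSFD:
        raise ValueError("normal form is implemented for the NSFD scheme only")
    tau0, omega0 = critical_point.tau0, critical_point.omega0
    m = grid.m
    poly = char_poly(params, alpha, tau0, grid, SchemeKind.NSFD)
    pair = eigen_pair(poly, omega0)
    lam0 = pair.lambda0
    q, qbar = pair.q, np.conj(pair.q)

    for denom, what in (
        (lam0**2 - lam0, "lambda0^2 - lambda0"),
        (1.0 - lam0, "1 - lambda0"),
        (poly(lam0**2), "a(lambda0^2)"),
        (poly(1.0), "a(1)"),
    ):
        if abs(denom) < RESONANCE_TOL:
            raise ResonanceError(f"resonant denominator {what} = {denom:.3e}")

    b_tilde, c_tilde = taylor_coefficients(params, alpha, tau0, grid)
    B_qq = _B(b_tilde, q, q, m)
    B_qqb = _B(b_tilde, q, qbar, m)
    B_qbqb = _B(b_tilde, qbar, qbar, m)

    g20 = pair.inner(B_qq)
    g11 = pair.inner(B_qqb)
    g02 = pair.inner(B_qbqb)

    # <qbar*, x> = sum q*_i x_i (conjugate projection)
    conj_inner = lambda x: complex(np.dot(pair.q_star, x))  # noqa: E731

    w20 = (
        (b_tilde * q[m] ** 2 / poly(lam0**2)) * _p(lam0**2, m)
        - g20 / (lam0**2 - lam0) * q
        - conj_inner(B_qq) / (lam0**2 - np.conj(lam0)) * qbar
    )
    w11 = (
        (b_tilde * q[m] * qbar[m] / poly(1.0)) * _p(1.0, m)
        - g11 / (1.0 - lam0) * q
        - conj_inner(B_qqb) / (1.0 - np.conj(lam0)) * qbar
    )

    g21 = (
        pair.inner(_B(b_tilde, qbar, w20, m))
        + 2.0 * pair.inner(_B(b_tilde, q, w11, m))
        + pair.inner(_C(c_tilde, q, q, qbar, m))
    )

    c1 = (
        g20 * g11 * (1.0 - 2.0 * lam0) / (2.0 * (lam0**2 - lam0))
        + abs(g11) ** 2 / (1.0 - np.conj(lam0))
        + abs(g02) ** 2 / (2.0 * (lam0**2 - np.conj(lam0)))
        + g21 / 2.0
    )
    c1_closed = (pair.K / 2.0) * (
        b_tilde**2 / poly(lam0**2) + 2.0 * b_tilde**2 / poly(1.0) + c_tilde
    )
    indicator = float((cmath.exp(-1j * omega0) * c1).real)
    classification = "attracting" if indicator < 0 else "repelling"
    return NormalFormResult(
        critical_point=critical_point,
        eigen=pair,
        b_tilde=b_tilde,
        c_tilde=c_tilde,
        g20=g20,
        g11=g11,
        g02=g02,
        g21=complex(g21),
        w20=w20,
        w11=w11,
        c1=complex(c1),
        c1_closed=complex(c1_closed),
        stability_indicator=indicator,
        classification=classification,
    )
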