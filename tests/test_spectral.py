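"""Companion matrices, spectral radii, and Neimark-Sacker detection."""

import cmath
import math

import numpy as np
import pytest

from nicholson_control import (
    BlowfliesParams,
    CharPoly,
    SchemeKind,
    StepGrid,
    char_poly,
    companion_matrix,
    critical_tau,
    crossing_angle,
    dominant_root,
    eigen_derivative_check,
    hopf_points,
    nsfd_radius_slope,
    spectral_radius,
    zero_delay_slope,
)


def test_companion_matrix_m1_quadratic():
    poly = CharPoly(m=1, a0_tilde=0.5, a1_tilde=0.25, scheme_kind=SchemeKind.NSFD)
    mat = companion_matrix(poly)
    assert np.array_equal(mat, [[0.5, 0.25], [1.0, 0.0]])
    eigs = sorted(np.linalg.eigvals(mat))
    disc = math.sqrt(0.5**2 + 4 * 0.25)
    assert eigs == pytest.approx(sorted([(0.5 - disc) / 2, (0.5 + disc) / 2]), abs=1e-12)


def test_zero_constant_term_spectrum():
    poly = CharPoly(m=4, a0_tilde=0.7, a1_tilde=0.0, scheme_kind=SchemeKind.NSFD)
    assert spectral_radius(poly) == pytest.approx(0.7, abs=1e-12)


def test_zero_delay_degenerate_roots(std_params, grid_m2):
    """At tau = 0 the NSFD polynomial has an m-fold zero root and a
    simple root at one."""
    poly = char_poly(std_params, 1.0, 0.0, grid_m2, SchemeKind.NSFD)
    assert (poly.a0_tilde, poly.a1_tilde) == (1.0, 0.0)
    roots = sorted(np.abs(np.linalg.eigvals(companion_matrix(poly))))
    assert roots == pytest.approx([0.0, 0.0, 1.0], abs=1e-12)


def test_roots_against_multiprecision_solver():
    """Companion eigenvalues vs mpmath's polynomial solver on random
    trinomials (independent oracle)."""
    import mpmath

    rng = np.random.default_rng(20240917)
    for _ in range(60):
        m = int(rng.integers(1, 6))
        a0, a1 = rng.uniform(-1.5, 1.5, size=2)
        poly = CharPoly(m=m, a0_tilde=a0, a1_tilde=a1, scheme_kind=SchemeKind.NSFD)
        coeffs = [1.0, -a0] + [0.0] * (m - 1) + [-a1]
        ref = mpmath.polyroots(coeffs[::-1], maxsteps=200, extraprec=80, asc=True)
        ref_radius = max(abs(complex(r)) for r in ref)
        assert spectral_radius(poly) == pytest.approx(ref_radius, abs=1e-10)


@pytest.mark.parametrize(
    "kind, alpha, m, expected",
    [
        (SchemeKind.NSFD, 1.0, 1, 0.4403),
        (SchemeKind.NSFD, 0.6, 2, 1.5058),
        (SchemeKind.EULER, 1.0, 1, 0.2927),
        (SchemeKind.EULER, 0.9, 2, 0.5160),
    ],
)
def test_critical_tau_reference_values(std_params, kind, alpha, m, expected):
    cp = critical_tau(std_params, alpha, StepGrid(m), kind)
    assert cp.tau0 == pytest.approx(expected, abs=5e-4)
    assert abs(abs(cp.crossing_eigenvalue) - 1.0) < 1e-7
    assert cp.crossing_eigenvalue.imag > 0
    assert cp.transversality > 0


@pytest.mark.parametrize("kind", [SchemeKind.NSFD, SchemeKind.EULER])
@pytest.mark.parametrize("alpha", [1.0, 0.9, 0.6])
def test_m1_closed_form_oracle(std_params, kind, alpha):
    """For h = 1 the crossing condition reduces to |root product| = 1,
    solvable in closed form; bisection must agree to 1e-8."""
    bu = std_params.b_u_star
    ac = alpha * std_params.c
    lower = (1.0 - alpha) / ac
    gamma = bu - 1.0 - lower  # -a1~ = (1 - e^{-ac tau}) * gamma  (NSFD)
    if kind is SchemeKind.NSFD:
        tau_exact = -math.log(1.0 - 1.0 / gamma) / ac
    else:
        tau_exact = 1.0 / (ac * (bu - 1.0) - (1.0 - alpha))
    cp = critical_tau(std_params, alpha, StepGrid(1), kind, tol=1e-12)
    assert cp.tau0 == pytest.approx(tau_exact, abs=1e-8)


def test_crossing_angle_matches_eigen_argument(std_params, grid_m2):
    for alpha in (1.0, 0.6):
        cp = critical_tau(std_params, alpha, grid_m2, SchemeKind.NSFD, tol=1e-12)
        omega = crossing_angle(std_params, alpha, cp.tau0, grid_m2)
        assert omega == pytest.approx(cp.omega0, abs=1e-6)
        assert omega == pytest.approx(
            abs(cmath.phase(cp.crossing_eigenvalue)), abs=1e-6
        )


def test_crossing_angle_impossible_in_stable_regime(std_params, grid_m2):
    """In the stable-for-all-delays regime the cosine condition exceeds 1."""
    for tau in (0.5, 2.0, 8.0):
        with pytest.raises(ValueError, match="no real crossing angle"):
            crossing_angle(std_params, 0.4, tau, grid_m2)


def test_stable_regime_radius_below_one(std_params, grid_m2):
    """alpha = 0.4 puts b u* below the upper threshold: the NSFD
    spectral radius never reaches 1 on a delay grid to 10 (the
    stable-for-all-delays guarantee is specific to the NSFD scheme)."""
    for tau in np.arange(0.05, 10.01, 0.05):
        poly = char_poly(std_params, 0.4, float(tau), grid_m2, SchemeKind.NSFD)
        assert spectral_radius(poly) < 1.0
    with pytest.raises(ValueError, match="critical delay requires"):
        critical_tau(std_params, 0.4, grid_m2, SchemeKind.NSFD)


@pytest.mark.parametrize("alpha,m", [(1.0, 1), (0.6, 2), (0.9, 2)])
def test_nsfd_transversality_closed_form_vs_fd(std_params, alpha, m):
    grid = StepGrid(m)
    cp = critical_tau(std_params, alpha, grid, SchemeKind.NSFD, tol=1e-12)
    closed = nsfd_radius_slope(std_params, alpha, cp.tau0, cp.omega0, grid)
    fd = eigen_derivative_check(std_params, alpha, grid, SchemeKind.NSFD, cp)
    assert closed > 0
    assert closed == pytest.approx(fd, rel=1e-4)


@pytest.mark.parametrize("alpha,m", [(1.0, 1), (0.6, 2)])
def test_euler_transversality_positive(std_params, alpha, m):
    grid = StepGrid(m)
    cp = critical_tau(std_params, alpha, grid, SchemeKind.EULER, tol=1e-12)
    fd = eigen_derivative_check(std_params, alpha, grid, SchemeKind.EULER, cp)
    assert fd > 0
    assert cp.transversality == pytest.approx(fd, rel=1e-6)


def test_zero_delay_slope_closed_form_and_fd(std_params):
    """Departure slope of the unit root at zero delay: closed form
    2h(1 - alpha - b u* alpha c), checked against a Richardson-improved
    finite difference of the dominant-root modulus."""
    for alpha, m in ((1.0, 1), (0.6, 2)):
        grid = StepGrid(m)
        closed = zero_delay_slope(std_params, alpha, grid)
        assert closed < 0  # b u* > (1-alpha)/(alpha c) here

        def r2(tau):
            poly = char_poly(std_params, alpha, tau, grid, SchemeKind.NSFD)
            return abs(dominant_root(poly)) ** 2

        d = 1e-6
        f1 = (r2(d) - 1.0) / d
        f2 = (r2(d / 2) - 1.0) / (d / 2)
        fd = 2.0 * f2 - f1  # Richardson extrapolation of the one-sided slope
        assert closed == pytest.approx(fd, rel=1e-4)
    # uncontrolled h=1 value: 2h(1 - alpha - b u* alpha c) with alpha=1
    assert zero_delay_slope(std_params, 1.0, StepGrid(1)) == pytest.approx(
        -2.0 * 2.0 * std_params.b_u_star, rel=1e-12
    )


def test_zero_delay_slope_vanishes_at_lower_boundary():
    params = BlowfliesParams(30.0, 2.0, 2.0)
    # choose alpha with 1 - alpha = b u* alpha c  ->  alpha = 1/(1 + b u* c)
    alpha = 1.0 / (1.0 + params.b_u_star * params.c)
    assert zero_delay_slope(params, alpha, StepGrid(1)) == pytest.approx(0.0, abs=1e-15)


def test_tau0_alpha_monotonicity_and_scheme_ordering(std_params):
    """Stronger control (smaller alpha) postpones the bifurcation, and
    the Euler scheme loses stability earlier than NSFD at every printed
    configuration."""
    for m in (1, 2):
        grid = StepGrid(m)
        tau_nsfd = {}
        tau_euler = {}
        for alpha in (1.0, 0.9, 0.6):
            tau_nsfd[alpha] = critical_tau(std_params, alpha, grid, SchemeKind.NSFD).tau0
            tau_euler[alpha] = critical_tau(std_params, alpha, grid, SchemeKind.EULER).tau0
        assert tau_nsfd[0.6] > tau_nsfd[0.9] > tau_nsfd[1.0]
        assert tau_euler[0.6] > tau_euler[0.9] > tau_euler[1.0]
        for alpha in (1.0, 0.9, 0.6):
            assert tau_euler[alpha] < tau_nsfd[alpha]


@pytest.mark.parametrize("kind", [SchemeKind.NSFD, SchemeKind.EULER])
def test_tau0_converges_to_continuous_limit(std_params, kind):
    """As h -> 0 the discrete critical delay approaches the continuous
    Hopf delay, with strictly decreasing error."""
    tau_cont = hopf_points(std_params, 1.0, k_max=0).tau_k[0]
    errors = []
    for m in (2, 4, 8, 16):
        cp = critical_tau(std_params, 1.0, StepGrid(m), kind)
        errors.append(abs(cp.tau0 - tau_cont))
    assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))
    # NSFD is closer than Euler at the same resolution
    assert errors[-1] < (0.05 if kind is SchemeKind.NSFD else 0.1)
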