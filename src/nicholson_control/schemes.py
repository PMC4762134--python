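"""Hybrid-control discretizations: NSFD and explicit-Euler step maps.

Both schemes discretize the scaled-time controlled equation in the
deviation coordinate ``v = u - u*`` with step ``h = 1/m``, so the unit
delay spans exactly ``m`` steps.  The nonstandard finite-difference
(NSFD) scheme replaces the step-size in the derivative's denominator by
the denominator function

    psi(h) = (1 - exp(-alpha c tau h)) / (alpha c tau) = h + O(h^2),

chosen so that the linear decay subproblem ``dv/dt = -alpha c tau v``
is integrated exactly.  The resulting update is

    v_{n+1} = e^{-s} v_n + (e^{-s} - 1) u*
              + (1 - e^{-s}) (v_{n-m} + u*) e^{-b v_{n-m}}
              + (1 - e^{-s}) (1 - alpha)/(alpha c) * v_{n-m},

with ``s = alpha c tau h``.  The Euler scheme applies the forward-Euler
rule directly.  ``v = 0`` (i.e. ``u = u*``) is a fixed point of both.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .params import BlowfliesParams

__all__ = [
    "SchemeKind",
    "StepGrid",
    "SchemeSpec",
    "Trajectory",
    "DivergenceError",
    "nsfd_step",
    "euler_step",
    "simulate",
    "classify_trajectory",
]

#: default bound beyond which a trajectory is declared divergent;
#: e^{-b v} overflows long before |v| reaches this.
DIVERGENCE_BOUND = 1e6


class DivergenceError(ArithmeticError):
    """Raised when a simulated trajectory leaves the divergence bound."""


class SchemeKind(enum.Enum):
    NSFD = "nsfd"
    EULER = "euler"


@dataclass(frozen=True)
class StepGrid:
    """Uniform grid with step h = 1/m; the unit delay spans m steps."""

    m: int

    def __post_init__(self) -> None:
        if not (isinstance(self.m, int) and self.m >= 1):
            raise ValueError(f"m must be a positive integer, got {self.m!r}")

    @property
    def h(self) -> float:
        return 1.0 / self.m

    @classmethod
    def from_step(cls, h: float, rel_tol: float = 1e-9) -> "StepGrid":
        """Build a grid from a step-size that must be of the form 1/m."""
        if not (0 < h <= 1):
            raise ValueError(f"step-size must lie in (0, 1], got {h!r}")
        m = round(1.0 / h)
        if m < 1 or abs(m * h - 1.0) > rel_tol:
            raise ValueError(f"step-size must equal 1/m for integer m, got {h!r}")
        return cls(m)


@dataclass(frozen=True)
class SchemeSpec:
    """Identity of a discretization: scheme kind plus step grid."""

    kind: SchemeKind
    grid: StepGrid

    def denominator(self, params: BlowfliesParams, alpha: float, tau: float) -> float:
        """Denominator function: psi(h) for NSFD, h for Euler.

        Both satisfy denominator = h + O(h^2), the consistency
        requirement for the derivative approximation.
        """
        h = self.grid.h
        if self.kind is SchemeKind.EULER:
            return h
        act = alpha * params.c * tau
        return -math.expm1(-act * h) / act


def nsfd_step(
    v_now: float,
    v_delayed: float,
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    grid: StepGrid,
) -> float:
    """One NSFD update of the deviation coordinate v = u - u*."""
    s = alpha * params.c * tau * grid.h
    e = math.exp(-s)
    u = params.u_star
    decay = 1.0 - e
    try:
        recruit = (v_delayed + u) * math.exp(-params.b * v_delayed)
    except OverflowError as exc:
        raise DivergenceError(
            f"recruitment term overflowed at v_delayed={v_delayed!r}"
        ) from exc
    feedback = (1.0 - alpha) / (alpha * params.c) * v_delayed
    return e * v_now + (e - 1.0) * u + decay * recruit + decay * feedback


def euler_step(
    v_now: float,
    v_delayed: float,
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    grid: StepGrid,
) -> float:
    """One forward-Euler update of the deviation coordinate."""
    h = grid.h
    u = params.u_star
    try:
        recruit = params.a * (v_delayed + u) * math.exp(-params.b * (v_delayed + u))
    except OverflowError as exc:
        raise DivergenceError(
            f"recruitment term overflowed at v_delayed={v_delayed!r}"
        ) from exc
    drift = alpha * tau * h * (recruit - params.c * (v_now + u))
    return v_now + drift + (1.0 - alpha) * tau * h * v_delayed


_STEP_FUNCS = {SchemeKind.NSFD: nsfd_step, SchemeKind.EULER: euler_step}


@dataclass(frozen=True)
class Trajectory:
    """A simulated orbit in deviation coordinates.

    ``history`` holds the m+1 initial values v_{-m}..v_0; ``steps`` the
    computed values v_1..v_N.  ``values`` concatenates both, indexed by
    n = -m..N; scaled time is t = n h, original time t * tau.
    """

    scheme: SchemeSpec
    params: BlowfliesParams
    alpha: float
    tau: float
    history: np.ndarray
    steps: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.history, self.steps])

    @property
    def indices(self) -> np.ndarray:
        m = self.scheme.grid.m
        return np.arange(-m, self.n_steps + 1)

    def to_frame(self, original_time: bool = False):
        """Trajectory as a DataFrame with columns n, t_scaled, u.

        ``u = v + u*`` is the population variable.  With
        ``original_time=True`` an extra column ``t`` = t_scaled * tau is
        included.
        """
        import pandas as pd

        n = self.indices
        t_scaled = n * self.scheme.grid.h
        data = {"n": n, "t_scaled": t_scaled, "u": self.values + self.params.u_star}
        if original_time:
            data["t"] = t_scaled * self.tau
        return pd.DataFrame(data)

    def write_csv(self, path, original_time: bool = False) -> None:
        self.to_frame(original_time).to_csv(path, index=False, lineterminator="\n")


def simulate(
    scheme: SchemeSpec,
    params: BlowfliesParams,
    alpha: float,
    tau: float,
    history,
    n_steps: int,
    bound: float = DIVERGENCE_BOUND,
) -> Trajectory:
    """Iterate the step map from a given initial history.

    ``history`` must contain m+1 finite values v_{-m}..v_0.  Raises
    :class:`DivergenceError` if any iterate exceeds ``bound`` in
    magnitude.  The method is fully deterministic.
    """
    grid = scheme.grid
    hist = np.asarray(history, dtype=float)
    if hist.shape != (grid.m + 1,):
        raise ValueError(
            f"history must have length m+1 = {grid.m + 1}, got shape {hist.shape}"
        )
    if not np.all(np.isfinite(hist)):
        raise ValueError("history contains non-finite values")
    step_func = _STEP_FUNCS[scheme.kind]
    buf = np.empty(grid.m + 1 + n_steps)
    buf[: grid.m + 1] = hist
    for i in range(n_steps):
        j = grid.m + i  # index of v_n in buf
        v_next = step_func(buf[j], buf[j - grid.m], params, alpha, tau, grid)
        if not math.isfinite(v_next) or abs(v_next) > bound:
            raise DivergenceError(
                f"trajectory exceeded bound {bound:g} at step {i + 1} "
                f"(scheme={scheme.kind.value}, alpha={alpha}, tau={tau}, h=1/{grid.m})"
            )
        buf[j + 1] = v_next
    return Trajectory(
        scheme=scheme,
        params=params,
        alpha=alpha,
        tau=tau,
        history=buf[: grid.m + 1].copy(),
        steps=buf[grid.m + 1 :].copy(),
    )


def constant_history(grid: StepGrid, eta: float = 0.1) -> np.ndarray:
    """Constant initial segment v = eta on the delay interval."""
    return np.full(grid.m + 1, float(eta))


def classify_trajectory(
    traj: Trajectory,
    tail_fraction: float = 0.1,
    converge_tol: float = 1e-3,
    oscillate_tol: float = 1e-2,
) -> str:
    """Qualitative verdict from the trailing segment of a trajectory.

    Returns ``"converges"`` if max |v| over the last ``tail_fraction``
    of steps is below ``converge_tol`` (orbit settles onto the
    equilibrium), ``"oscillates"`` if it exceeds ``oscillate_tol``
    (sustained oscillation, e.g. on a bifurcated invariant curve), and
    ``"indeterminate"`` in between.
    """
    tail_len = max(1, int(round(tail_fraction * traj.n_steps)))
    tail = np.abs(traj.steps[-tail_len:])
    peak = float(tail.max())
    if peak < converge_tol:
        return "converges"
    if peak > oscillate_tol:
        return "oscillates"
    return "indeterminate"
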