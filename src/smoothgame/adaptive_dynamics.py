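"""Adaptive dynamics of smoothed branch-payoff games.

In a monomorphic resident population at strategy ``x``, the growth rate of a
rare mutant ``u`` is the invasion fitness ``S_x(u) = E(u, x) - E(x, x)``.
Gradual evolution follows the selection gradient

    D(x) = dS_x(u)/du at u = x,

via the canonical equation ``dx/dt = D(x)``. For a branch-payoff game
``E(u, x) = h(u, x) + (g(u, x) - h(u, x)) * f_k(x - u)``, differentiating in
the mutant direction and evaluating on the diagonal gives the closed form

    D(x) = d1h(x, x) + (d1g(x, x) - d1h(x, x)) * f_k(0)
           - (g(x, x) - h(x, x)) * f_k'(0),

with ``f_k(0) = 1/2``. For the Traveler's Dilemma this is the constant
``1/2 - 2 R f_k'(0)`` (sign flips at ``R = 1/(4 f_k'(0))``, i.e. ``R = 1/k``
for the logistic family); for Minimum Effort Coordination it is ``1/2 - c``,
independent of the smoothing function altogether. Neither game has singular
strategies; strategies simply evolve to an endpoint of [0, 1]. Custom games
can have interior zeros of ``D``, which are located by bracketed bisection and
classified as attractors/repellers, ESSs, or branching points from the two
standard second-order quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .games import GameSpec, smoothed_payoff
from .smoothing import smoothing_slope_at_zero, smoothing_value

__all__ = [
    "GradientProfile",
    "SingularPoint",
    "DegenerateGradientWarning",
    "invasion_fitness",
    "selection_gradient",
    "gradient_profile",
    "find_singular_strategies",
    "classify_singular",
    "integrate_adaptive_dynamics",
]


class DegenerateGradientWarning(UserWarning):
    """The selection gradient vanishes identically: every strategy is neutral."""


@dataclass(frozen=True)
class GradientProfile:
    """Selection gradient D(x) tabulated on a strategy grid."""

    grid: np.ndarray
    values: np.ndarray
    game_name: str
    game_param: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("gradient grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gradient values must be finite")


@dataclass(frozen=True)
class SingularPoint:
    """A zero of the selection gradient with its stability classification.

    ``convergence_stable``: the adaptive dynamics is attracted to the point
    (D decreasing through zero). ``ess``: invasion fitness has a local maximum
    in the mutant direction, so the point is an evolutionary end state.
    ``branching``: convergence stable but a fitness minimum — the population
    splits into diverging strategy clusters. ``indeterminate`` flags
    second-order quantities too close to zero to call.
    """

    x: float
    convergence_stable: bool
    ess: bool
    branching: bool
    dD_dx: float
    mutant_curvature: float
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if not self.indeterminate and self.branching != (
            self.convergence_stable and not self.ess
        ):
            raise ValueError("branching iff convergence stable and not ESS")


def invasion_fitness(game: GameSpec, mutant: float, resident: float) -> float:
    """Growth rate ``S_x(u) = E(u, x) - E(x, x)`` of a rare mutant ``u``."""
    return float(
        smoothed_payoff(game, mutant, resident)
        - smoothed_payoff(game, resident, resident)
    )


def _d1(fn, dfn, x: float, y: float, h: float = 1e-6) -> float:
    """Partial derivative of a branch wrt the focal strategy; closed-form if given."""
    if dfn is not None:
        return float(np.asarray(dfn(np.float64(x), np.float64(y))))
    return float((fn(x + h, y) - fn(x - h, y)) / (2 * h))


def selection_gradient(game: GameSpec, resident: float) -> float:
    """Selection gradient ``D(x)`` at the resident strategy.

    Uses the closed form for the branch-payoff class; requires finite ``k``
    (the gradient of the discontinuous game is undefined).
    """
    if not 0.0 <= resident <= 1.0:
        raise ValueError("resident strategy must lie in [0, 1]")
    if game.smoothing.is_heaviside:
        raise ValueError("selection gradient is undefined in the Heaviside limit")
    x = float(resident)
    br = game.branch
    g = float(np.asarray(br.g(np.float64(x), np.float64(x))))
    h = float(np.asarray(br.h(np.float64(x), np.float64(x))))
    d1g = _d1(br.g, br.dg_dx, x, x)
    d1h = _d1(br.h, br.dh_dx, x, x)
    f0 = float(smoothing_value(game.smoothing, 0.0))
    fp0 = smoothing_slope_at_zero(game.smoothing)
    return d1h + (d1g - d1h) * f0 - (g - h) * fp0


def gradient_profile(game: GameSpec, grid_size: int = 101) -> GradientProfile:
    """Tabulate D(x) on a uniform grid over [0, 1]."""
    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([selection_gradient(game, float(x)) for x in grid])
    return GradientProfile(grid, vals, game.name, game.param)


def find_singular_strategies(
    game: GameSpec, grid_size: int = 101, *, tol: float = 1e-10
) -> list[float]:
    """Zeros of the selection gradient in [0, 1].

    Scans D on a uniform grid, brackets sign changes, and refines each
    bracket by bisection to ``|D| < tol`` or a bracket below 1e-12. Grid
    points where D vanishes exactly are returned as-is. When D vanishes
    identically (e.g. mec at c = 1/2) the whole interval is neutral: a
    :class:`DegenerateGradientWarning` is issued and no roots are returned,
    since a root list cannot represent a continuum.
    """
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")
    prof = gradient_profile(game, grid_size)
    grid, vals = prof.grid, prof.values

    if np.all(np.abs(vals) < 1e-12):
        warnings.warn(
            "selection gradient vanishes identically; every strategy is "
            "neutrally stable (degenerate line, not isolated roots)",
            DegenerateGradientWarning,
            stacklevel=2,
        )
        return []

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = float(grid[i]), float(grid[i + 1])
        fa, fb = float(vals[i]), float(vals[i + 1])
        if abs(fa) < tol:
            roots.append(a)
            continue
        if fa * fb < 0:
            for _ in range(200):
                m = 0.5 * (a + b)
                fm = selection_gradient(game, m)
                if abs(fm) < tol or (b - a) < 1e-12:
                    break
                if fa * fm < 0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
    if abs(vals[-1]) < tol:
        roots.append(float(grid[-1]))

    # merge near-duplicates from adjacent brackets
    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 1e-9:
            merged.append(r)
    return merged


def classify_singular(
    game: GameSpec,
    x_star: float,
    *,
    step: float = 1e-5,
    zero_tol: float = 1e-7,
) -> SingularPoint:
    """Classify a singular strategy by its two second-order quantities.

    ``dD/dx < 0`` at the point makes it convergence stable (an attractor of
    the adaptive dynamics); a negative second derivative of invasion fitness
    in the mutant direction makes it an ESS; convergence stable but not ESS
    is an evolutionary branching point. Central differences with step 1e-5;
    quantities within ``zero_tol`` of zero are flagged indeterminate.
    """
    if abs(selection_gradient(game, x_star)) > 1e-8:
        raise ValueError(f"{x_star} is not a singular strategy (|D| > 1e-8)")

    lo = max(0.0, x_star - step)
    hi = min(1.0, x_star + step)
    dD = (selection_gradient(game, hi) - selection_gradient(game, lo)) / (hi - lo)

    # second derivative of S_x(u) along the mutant axis at u = x*
    su = lambda u: invasion_fitness(game, u, x_star)
    curv = (su(hi) - 2.0 * su(x_star) + su(lo)) / ((0.5 * (hi - lo)) ** 2)

    indet = abs(dD) < zero_tol or abs(curv) < zero_tol
    cs = dD < 0
    ess = curv < 0
    return SingularPoint(
        x=float(x_star),
        convergence_stable=bool(cs),
        ess=bool(ess),
        branching=bool(cs and not ess) if not indet else False,
        dD_dx=float(dD),
        mutant_curvature=float(curv),
        indeterminate=bool(indet),
    )


def integrate_adaptive_dynamics(
    game: GameSpec, x0: float, horizon: float, step: float = 0.01
) -> pd.DataFrame:
    """Integrate ``dx/dt = D(x)`` with fixed-step classical Runge-Kutta.

    The state is clipped to [0, 1] after every stage and every step; the
    endpoints are absorbing, matching evolution on a closed strategy
    interval. Returns a DataFrame with columns ``time`` and ``strategy``.
    """
    if not 0.0 <= x0 <= 1.0:
        raise ValueError("x0 must lie in [0, 1]")
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be positive")

    D = lambda x: selection_gradient(game, min(1.0, max(0.0, x)))
    n = int(np.ceil(horizon / step))
    times = np.empty(n + 1)
    xs = np.empty(n + 1)
    t, x = 0.0, float(x0)
    times[0], xs[0] = t, x
    for i in range(1, n + 1):
        h = min(step, horizon - t)
        k1 = D(x)
        k2 = D(x + 0.5 * h * k1)
        k3 = D(x + 0.5 * h * k2)
        k4 = D(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        x = min(1.0, max(0.0, x))
        t += h
        times[i], xs[i] = t, x
    return pd.DataFrame({"time": times, "strategy": xs})
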