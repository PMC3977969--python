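"""One-parameter sigmoid families that smooth a discontinuous payoff step.

A smoothing function ``f_k`` stands in for the Heaviside step in the payoff
of a continuous-strategy game with a payoff discontinuity across the diagonal.
Its value at ``x = y_opp - y_focal`` is the probability that perception or
implementation errors award the focal player the "lower-strategy" payoff
branch; the complement ``1 - f_k`` is the probability of the other branch.
The sharpness ``k`` controls how concentrated the error distribution is:
``k -> infinity`` recovers the error-free, discontinuous game.

The default family is the logistic sigmoid in ``k*x``,

    f_k(x) = 1 / (1 + exp(-k*x)),

which is smooth, non-decreasing, has midpoint ``f_k(0) = 1/2``, satisfies the
complementarity ``f_k(x) + f_k(-x) = 1`` and converges pointwise to the
Heaviside step (with the tie value 1/2 at 0) as ``k -> infinity``. Its slope
at the origin, ``f_k'(0) = k/4``, is the only feature of the family that the
evolutionary analysis of the Traveler's Dilemma depends on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "INFINITY",
    "SmoothingSpec",
    "ValidationReport",
    "smoothing_value",
    "smoothing_slope_at_zero",
    "validate_family",
]

#: Symbolic sharpness for the exact Heaviside limit (not a huge float).
INFINITY = math.inf


@dataclass(frozen=True)
class SmoothingSpec:
    """A member of a one-parameter smoothing family.

    Parameters
    ----------
    k : float
        Sharpness. Positive and finite, or ``INFINITY`` for the exact
        Heaviside step with tie value ``H(0) = 1/2``.
    family : str
        ``"logistic"`` (default) or ``"custom"``.
    func : callable, optional
        For a custom family: ``func(k, x) -> value``, vectorized over ``x``.
    slope_at_zero_fn : callable, optional
        For a custom family: closed-form ``k -> f_k'(0)``. When absent the
        slope is obtained by an adaptive central finite difference.
    """

    k: float
    family: str = "logistic"
    func: Callable[[float, np.ndarray], np.ndarray] | None = field(
        default=None, compare=False
    )
    slope_at_zero_fn: Callable[[float], float] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if not (self.k == INFINITY or (math.isfinite(self.k) and self.k > 0)):
            raise ValueError(
                f"sharpness k must be positive and finite or INFINITY, got {self.k!r}"
            )
        if self.family == "custom" and self.func is None:
            raise ValueError("custom family requires a `func` callable")
        if self.family not in ("logistic", "custom"):
            raise ValueError(f"unknown smoothing family {self.family!r}")

    @property
    def is_heaviside(self) -> bool:
        return self.k == INFINITY

    # convenience aliases so game code can call the spec directly
    def __call__(self, x):
        return smoothing_value(self, x)

    def slope_at_zero(self) -> float:
        return smoothing_slope_at_zero(self)


def _heaviside(x):
    """Heaviside step with H(0) = 1/2 (the smoothed game's tie value)."""
    return np.heaviside(np.asarray(x, dtype=float), 0.5)


def smoothing_value(spec: SmoothingSpec, x):
    """Evaluate ``f_k(x)``; vectorized over ``x``.

    For ``k = INFINITY`` this is the exact step with ``H(0) = 1/2``. The
    logistic family is evaluated through :func:`scipy.special.expit`, which is
    overflow-safe for arbitrarily large ``k*x``.
    """
    x = np.asarray(x, dtype=float)
    if spec.is_heaviside:
        out = _heaviside(x)
    elif spec.family == "logistic":
        out = expit(spec.k * x)
    else:
        out = np.asarray(spec.func(spec.k, x), dtype=float)
    return out if out.ndim else float(out)


def smoothing_slope_at_zero(spec: SmoothingSpec) -> float:
    """Return ``f_k'(0)``.

    Closed form ``k/4`` for the logistic family. A custom family may supply
    its own closed form; otherwise a central difference is used, halving the
    step until the two half-step estimates agree to 1e-8 relative.

    Raises
    ------
    ValueError
        If ``k = INFINITY`` (the step has no derivative at 0).
    """
    if spec.is_heaviside:
        raise ValueError("slope at zero is undefined in the Heaviside limit")
    if spec.family == "logistic":
        return spec.k / 4.0
    if spec.slope_at_zero_fn is not None:
        return float(spec.slope_at_zero_fn(spec.k))

    # adaptive central difference; scale the initial step to the sharpness
    h = 0.1 / spec.k
    prev = (smoothing_value(spec, h) - smoothing_value(spec, -h)) / (2 * h)
    for _ in range(60):
        h /= 2.0
        cur = (smoothing_value(spec, h) - smoothing_value(spec, -h)) / (2 * h)
        if abs(cur - prev) <= 1e-8 * max(abs(cur), 1e-300):
            return float(cur)
        prev = cur
    raise ArithmeticError("finite-difference slope did not converge")


@dataclass
class ValidationReport:
    """Outcome of the family sanity checks on a grid."""

    monotone: bool
    midpoint_ok: bool
    midpoint_value: float
    in_range: bool
    max_step_deviation_at_extremes: float
    messages: list[str]

    @property
    def ok(self) -> bool:
        return self.monotone and self.midpoint_ok and self.in_range


def validate_family(spec: SmoothingSpec, grid: Sequence[float]) -> ValidationReport:
    """Check the defining sigmoid properties of ``f_k`` on a grid.

    The grid must be sorted, contain 0, and span negative and positive values.
    Flags monotonicity violations, deviation of ``f(0)`` from 1/2, values
    outside [0, 1], and reports the worst deviation from the Heaviside step at
    the two grid extremes (informative for large ``k``).
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("validation grid is empty")
    if np.any(np.diff(g) < 0):
        raise ValueError("validation grid must be sorted ascending")
    if not (g[0] < 0 < g[-1]) or not np.any(g == 0):
        raise ValueError("grid must contain 0 and span negative and positive values")

    vals = np.asarray(smoothing_value(spec, g), dtype=float)
    msgs: list[str] = []

    monotone = bool(np.all(np.diff(vals) >= -1e-15))
    if not monotone:
        msgs.append("f_k is not non-decreasing on the grid")

    mid = float(vals[np.nonzero(g == 0)[0][0]])
    midpoint_ok = abs(mid - 0.5) < 1e-12
    if not midpoint_ok:
        msgs.append(f"f_k(0) = {mid!r} deviates from 1/2")

    in_range = bool(np.all((vals >= -1e-15) & (vals <= 1 + 1e-15)))
    if not in_range:
        msgs.append("f_k leaves [0, 1] on the grid")

    step = _heaviside(np.array([g[0], g[-1]]))
    dev = float(np.max(np.abs(vals[[0, -1]] - step)))

    return ValidationReport(
        monotone=monotone,
        midpoint_ok=midpoint_ok,
        midpoint_value=mid,
        in_range=in_range,
        max_step_deviation_at_extremes=dev,
        messages=msgs,
    )
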