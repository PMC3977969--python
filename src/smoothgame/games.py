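"""Branch-payoff games: Traveler's Dilemma, Minimum Effort Coordination, custom.

A branch-payoff game on the unit strategy interval is given by two affine
branches: the focal player receives ``g(x, y)`` when its strategy ``x`` lies
below the opponent's ``y``, and ``h(x, y)`` when it lies above. Written with
the Heaviside step the payoff is ``h + (g - h) * H(y - x)``; the smoothed game
replaces ``H`` with a sigmoid ``f_k`` so that

    E_k(x, y) = h(x, y) + (g(x, y) - h(x, y)) * f_k(y - x).

Because ``f_k(0) = 1/2``, the diagonal payoff is the branch average
``(g + h) / 2``, which reproduces the original games' tie payoffs.

Concrete games (parameter in [0, 1]):

* Traveler's Dilemma (``td``), reward/punishment ``R``:
  ``g = x + R`` (lower claimant gets own claim plus the transfer),
  ``h = y - R`` (higher claimant pays the lower claim minus the transfer).
* Minimum Effort Coordination (``mec``), effort cost ``c``:
  ``g = x - c*x``, ``h = y - c*x`` (minimum effort minus own effort cost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable

import numpy as np

from .smoothing import INFINITY, SmoothingSpec, smoothing_value

__all__ = [
    "BranchPayoff",
    "GameSpec",
    "td_game",
    "mec_game",
    "custom_game",
    "smoothed_payoff",
    "heaviside_payoff",
    "payoff_bounds",
    "discrete_payoff",
    "enumerate_pure_nash",
]

Payoff2 = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class BranchPayoff:
    """The two payoff branches of a game discontinuous across the diagonal.

    ``g(x, y)`` is the focal payoff when ``x < y``; ``h(x, y)`` when
    ``x > y``. ``dg_dx`` / ``dh_dx`` are the partial derivatives with respect
    to the focal strategy (first argument); they may be omitted for custom
    games, in which case downstream analysis falls back to finite differences.
    """

    g: Payoff2
    h: Payoff2
    dg_dx: Payoff2 | None = field(default=None, compare=False)
    dh_dx: Payoff2 | None = field(default=None, compare=False)


@dataclass(frozen=True)
class GameSpec:
    """A smoothed branch-payoff game on the unit strategy interval.

    Attributes
    ----------
    name : str
        ``"td"``, ``"mec"`` or ``"custom"``.
    param : float
        Reward/punishment ``R`` for td; effort cost ``c`` for mec; unused for
        custom games. Must lie in [0, 1] for the named games.
    smoothing : SmoothingSpec
        The attached smoothing family member.
    branch : BranchPayoff
        The two payoff branches.
    bounds : tuple of float, optional
        Tight payoff bounds for a custom game (required for the replicator
        update rule normalization).
    """

    name: str
    param: float
    smoothing: SmoothingSpec
    branch: BranchPayoff
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        # R >= 0 admits the discrete game's conventional integer rewards
        # (e.g. R = 2 on claims 180..300); the continuous game uses R in [0, 1].
        if self.name == "td" and self.param < 0:
            raise ValueError(f"td reward/punishment R must be >= 0, got {self.param}")
        if self.name == "mec" and not 0.0 <= self.param <= 1.0:
            raise ValueError(f"mec effort cost c must be in [0, 1], got {self.param}")

    def with_smoothing(self, smoothing: SmoothingSpec) -> "GameSpec":
        """Same game, different smoothing."""
        return GameSpec(self.name, self.param, smoothing, self.branch, self.bounds)


def td_game(R: float, smoothing: SmoothingSpec) -> GameSpec:
    """Traveler's Dilemma with reward/punishment parameter ``R`` in [0, 1]."""
    branch = BranchPayoff(
        g=lambda x, y: x + R,
        h=lambda x, y: y - R,
        dg_dx=lambda x, y: np.ones_like(np.asarray(x, dtype=float)),
        dh_dx=lambda x, y: np.zeros_like(np.asarray(x, dtype=float)),
    )
    return GameSpec("td", R, smoothing, branch)


def mec_game(c: float, smoothing: SmoothingSpec) -> GameSpec:
    """Minimum Effort Coordination with effort cost ``c`` in [0, 1]."""
    branch = BranchPayoff(
        g=lambda x, y: x - c * x,
        h=lambda x, y: y - c * x,
        dg_dx=lambda x, y: np.full_like(np.asarray(x, dtype=float), 1.0 - c),
        dh_dx=lambda x, y: np.full_like(np.asarray(x, dtype=float), -c),
    )
    return GameSpec("mec", c, smoothing, branch)


def custom_game(
    branch: BranchPayoff,
    smoothing: SmoothingSpec,
    bounds: tuple[float, float] | None = None,
) -> GameSpec:
    """A user-supplied branch-payoff game (e.g. to exercise singular points)."""
    return GameSpec("custom", float("nan"), smoothing, branch, bounds)


def _check_strategies(*vals) -> None:
    for v in vals:
        a = np.asarray(v, dtype=float)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("strategies must lie in [0, 1]")


def smoothed_payoff(game: GameSpec, x, y):
    """Payoff ``E_k(x, y)`` to an x-strategist meeting a y-strategist.

    Vectorized over ``x`` and ``y``. With ``k = INFINITY`` this is the
    discontinuous payoff with the tie value ``(g + h) / 2`` on the diagonal.
    """
    _check_strategies(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = game.branch.g(x, y)
    h = game.branch.h(x, y)
    out = h + (g - h) * smoothing_value(game.smoothing, y - x)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def heaviside_payoff(game: GameSpec, x, y):
    """The discontinuous payoff (exact ``k = INFINITY`` limit, tie value (g+h)/2)."""
    return smoothed_payoff(game.with_smoothing(SmoothingSpec(INFINITY)), x, y)


def payoff_bounds(game: GameSpec) -> tuple[float, float]:
    """Tight lower/upper payoff bounds over the unit strategy square.

    td: ``(-R, 1 + R)``; mec: ``(-c, 1 - c)`` (the discontinuous game's
    range). Custom games must carry explicit bounds.
    """
    if game.name == "td":
        return (-game.param, 1.0 + game.param)
    if game.name == "mec":
        return (-game.param, 1.0 - game.param)
    if game.bounds is not None:
        return game.bounds
    raise ValueError("custom game without supplied payoff bounds")


def discrete_payoff(game: GameSpec, i: int, j: int, strategy_range: tuple[int, int]) -> float:
    """Payoff in the original integer-strategy game on ``[lo, hi]``.

    td: equal claims are paid in full; otherwise both are paid the lower
    claim, with the transfer ``R`` from the higher to the lower claimant.
    mec: ``min(i, j) - c * i``.
    """
    lo, hi = strategy_range
    if not (lo <= i <= hi and lo <= j <= hi):
        raise ValueError(f"strategy outside range [{lo}, {hi}]")
    if game.name == "td":
        R = game.param
        if i == j:
            return float(i)
        return float(min(i, j) + R) if i < j else float(min(i, j) - R)
    if game.name == "mec":
        return float(min(i, j) - game.param * i)
    raise ValueError("discrete payoff is defined for td and mec only")


def enumerate_pure_nash(
    game: GameSpec, strategy_range: tuple[int, int]
) -> set[tuple[int, int]]:
    """All pure-strategy Nash pairs of the integer game, by exhaustive search.

    A pair ``(i, j)`` is Nash when no unilateral integer deviation strictly
    improves the deviator's payoff. The search is a full double loop over all
    profiles and all deviations, so the range is capped at 200 strategies.
    """
    lo, hi = strategy_range
    if hi - lo > 200:
        raise ValueError("range too large for exhaustive search (max 200)")
    strategies = range(lo, hi + 1)
    pay = {(i, j): discrete_payoff(game, i, j, strategy_range)
           for i, j in product(strategies, strategies)}
    nash: set[tuple[int, int]] = set()
    for i, j in product(strategies, strategies):
        # symmetric game: the j-player's payoff in profile (i, j) is pay[(j, i)]
        if any(pay[(d, j)] > pay[(i, j)] for d in strategies if d != i):
            continue
        if any(pay[(d, i)] > pay[(j, i)] for d in strategies if d != j):
            continue
        nash.add((i, j))
    return nash
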