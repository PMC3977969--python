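"""Parameter sweeps, strategy histograms, and cross-network comparisons.

These drivers reproduce the study design of the simulation figures: the game
parameter (reward/punishment R for the Traveler's Dilemma, effort cost c for
Minimum Effort Coordination) is swept from 0 to 1 for several smoothing
sharpness values k (including the Heaviside limit), with multiple
independently seeded runs per point; each point reports the average of the
per-run tail-mean strategies. Per-cell seeds are derived deterministically
from one master seed, so an entire sweep is reproducible from a single
integer.

Two problem-size presets are provided: ``test`` (N=200, T=2000 generations),
sized so a full sweep finishes in minutes, and ``paper`` (N=900 on lattices,
N=1000 elsewhere, T=20000), the scale of the published sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .abm import SimulationConfig, run_simulation, summary_mean_strategy
from .games import GameSpec, mec_game, td_game
from .graphs import KINDS, GraphSpec
from .smoothing import INFINITY, SmoothingSpec

__all__ = [
    "SCALES",
    "SweepSpec",
    "SweepResult",
    "make_config",
    "run_sweep",
    "strategy_histogram_experiment",
    "compare_networks",
]

#: Problem-size presets: (N for lattice graphs, N for other graphs, generations)
SCALES = {
    "test": {"n_lattice": 196, "n_other": 200, "generations": 2000},
    "paper": {"n_lattice": 900, "n_other": 1000, "generations": 20000},
}


def make_config(
    game_name: str,
    value: float,
    k: float,
    graph_kind: str = "complete",
    *,
    scale: str = "test",
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Assemble a :class:`SimulationConfig` for one sweep cell.

    ``k`` may be ``INFINITY`` for the discontinuous-game series. Keyword
    overrides pass through to :class:`SimulationConfig`.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    preset = SCALES[scale]
    n = preset["n_lattice"] if graph_kind.startswith("lattice") else preset["n_other"]
    smoothing = SmoothingSpec(k)
    game = td_game(value, smoothing) if game_name == "td" else mec_game(value, smoothing)
    overrides.setdefault("generations", preset["generations"])
    return SimulationConfig(
        game=game,
        graph=GraphSpec(graph_kind, n),
        seed=seed,
        **overrides,
    )


@dataclass(frozen=True)
class SweepSpec:
    """A sweep of the game parameter across smoothing values.

    ``values`` defaults to 0..1 inclusive in steps of 0.05 (21 points);
    ``k_values`` may mix finite sharpness values with ``INFINITY``.
    """

    game_name: str
    graph_kind: str = "complete"
    values: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 21), 10))
    k_values: tuple[float, ...] = (5.0, 20.0, INFINITY)
    runs: int = 10
    scale: str = "test"
    master_seed: int = 0
    config_overrides: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("swept values must lie in [0, 1]")
        if self.runs < 1:
            raise ValueError("need at least one run per point")
        if self.game_name not in ("td", "mec"):
            raise ValueError("sweeps support the td and mec games")


def _cell_seed(master: int, ki: int, vi: int, run: int, kind_idx: int = 0) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(kind_idx, ki, vi, run))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepResult:
    """Tidy per-run rows plus per-(k, value) aggregates."""

    rows: pd.DataFrame
    aggregates: pd.DataFrame
    spec: SweepSpec

    def to_csv(self, path: str) -> None:
        self.rows.to_csv(path, index=False)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Execute every (k, value, run) cell and aggregate the tail means."""
    records = []
    for ki, k in enumerate(spec.k_values):
        for vi, value in enumerate(spec.values):
            for run in range(spec.runs):
                seed = _cell_seed(spec.master_seed, ki, vi, run)
                cfg = make_config(
                    spec.game_name, float(value), k, spec.graph_kind,
                    scale=spec.scale, seed=seed, **spec.config_overrides,
                )
                try:
                    rec = run_simulation(cfg)
                except Exception as exc:  # noqa: BLE001 - annotate the failing cell
                    raise RuntimeError(
                        f"sweep cell failed: k={k}, value={value}, run={run}"
                    ) from exc
                records.append(
                    {
                        "graph_kind": spec.graph_kind,
                        "k": float(k),
                        "value": float(value),
                        "run": run,
                        "seed": seed,
                        "tail_mean_strategy": summary_mean_strategy(rec),
                    }
                )
    rows = pd.DataFrame.from_records(records)
    agg = (
        rows.groupby(["graph_kind", "k", "value"], as_index=False)
        .agg(mean_tail_strategy=("tail_mean_strategy", "mean"))
    )
    return SweepResult(rows=rows, aggregates=agg, spec=spec)


def strategy_histogram_experiment(
    config_low: SimulationConfig, config_high: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Final-generation strategy histograms for a low/high parameter pair.

    The two configurations must differ only in the game parameter; both
    histograms share the same fixed bin edges and each sums to N.
    """
    if config_low.game.name != config_high.game.name:
        raise ValueError("histogram configs must use the same game")
    if config_low.graph != config_high.graph:
        raise ValueError("histogram configs must share the graph spec")
    low = run_simulation(config_low)
    high = run_simulation(config_high)
    return low.histogram_frame(), high.histogram_frame()


def compare_networks(spec: SweepSpec, kinds: Sequence[str]) -> pd.DataFrame:
    """Run the same sweep on several graph kinds; report cross-kind spread.

    Returns one row per (k, value) with each kind's aggregate tail mean and
    the spread (max - min) across kinds — small spreads support the claim
    that network structure barely affects the evolutionary outcome.
    """
    # validate all graph specs up front so a bad kind fails before any run
    for kind in kinds:
        make_config(spec.game_name, float(spec.values[0]), 20.0, kind, scale=spec.scale)

    frames = []
    for kind in kinds:
        # seed by the kind's global index so a repeated kind repeats its seeds
        kind_idx = KINDS.index(kind) if kind in KINDS else len(KINDS)
        sub = replace(spec, graph_kind=kind)
        records = []
        for ki, k in enumerate(sub.k_values):
            for vi, value in enumerate(sub.values):
                for run in range(sub.runs):
                    seed = _cell_seed(sub.master_seed, ki, vi, run, kind_idx)
                    cfg = make_config(
                        sub.game_name, float(value), k, kind,
                        scale=sub.scale, seed=seed, **sub.config_overrides,
                    )
                    records.append(
                        {
                            "graph_kind": kind,
                            "k": float(k),
                            "value": float(value),
                            "tail_mean_strategy": summary_mean_strategy(
                                run_simulation(cfg)
                            ),
                        }
                    )
        frames.append(pd.DataFrame.from_records(records))
    rows = pd.concat(frames, ignore_index=True)
    agg = (
        rows.groupby(["graph_kind", "k", "value"], as_index=False)
        .agg(mean_tail_strategy=("tail_mean_strategy", "mean"))
    )
    wide = agg.pivot_table(
        index=["k", "value"], columns="graph_kind", values="mean_tail_strategy"
    )
    wide["spread"] = wide.max(axis=1) - wide.min(axis=1)
    return wide.reset_index()
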