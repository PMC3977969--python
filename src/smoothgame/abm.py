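"""Stochastic agent-based evolutionary dynamics on a population graph.

One generation is a round of N asynchronous game interactions followed by a
round of N asynchronous strategy updates, both sampling the population with
replacement. In an interaction step a focal individual plays a uniformly
drawn neighbor and its stored payoff is overwritten with the payoff it just
received; individuals not sampled keep their stale payoff. In an update step
a focal individual i compares payoffs with a uniformly drawn neighbor j and
adopts j's strategy with a probability given by the Fermi rule

    p = 1 / (1 + exp(-beta * (pi_j - pi_i)))

(selection strength beta), or by the replicator rule
``max(0, pi_j - pi_i) / delta_max``. When adoption occurs, with probability
``mu`` the adopted value is instead drawn from a normal distribution centered
on j's strategy with standard deviation ``sigma`` and clamped to [0, 1]
(mutation). The population starts monomorphic at a strategy drawn once,
uniformly from [0, 1].

All randomness flows from one master seed through labeled sub-streams
(graph, initialization, dynamics), so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .games import GameSpec, payoff_bounds, smoothed_payoff
from .graphs import GraphSpec, PopulationGraph, build_graph

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "TrajectoryRecord",
    "initialize_population",
    "interaction_round",
    "fermi_probability",
    "replicator_probability",
    "update_round",
    "run_simulation",
    "summary_mean_strategy",
]

HISTOGRAM_BINS = 30  # resolves the bimodal extremes at N >= 200


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one simulation run.

    ``record_fraction`` is the tail fraction of generations averaged by
    :func:`summary_mean_strategy`. ``accumulate_payoffs`` switches the
    interaction step from overwrite to accumulate semantics (off by
    default: the payoff is the one received in the latest interaction).
    """

    game: GameSpec
    graph: GraphSpec
    generations: int
    mutation_rate: float = 0.01
    mutation_sd: float = 0.05
    selection_strength: float = 10.0
    update_rule: str = "fermi"
    seed: int = 0
    record_fraction: float = 0.1
    accumulate_payoffs: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.mutation_sd <= 0:
            raise ValueError("mutation standard deviation must be positive")
        if self.selection_strength < 0:
            raise ValueError("selection strength must be non-negative")
        if self.update_rule not in ("fermi", "replicator"):
            raise ValueError("update rule must be 'fermi' or 'replicator'")
        if not 0.0 < self.record_fraction <= 1.0:
            raise ValueError("record fraction must be in (0, 1]")
        if self.generations < 1:
            raise ValueError("need at least one generation")

    @property
    def n(self) -> int:
        return self.graph.n


@dataclass
class PopulationState:
    """Per-vertex strategy in [0, 1] and last-received payoff."""

    strategies: np.ndarray
    payoffs: np.ndarray
    generation: int = 0

    def validate(self) -> None:
        if np.any(self.strategies < 0) or np.any(self.strategies > 1):
            raise ValueError("strategies left [0, 1]")
        if not np.all(np.isfinite(self.payoffs)):
            raise ValueError("non-finite payoff")


@dataclass
class TrajectoryRecord:
    """Per-generation summary of one run plus the final-state histogram."""

    mean: np.ndarray
    sd: np.ndarray
    final_strategies: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    config: SimulationConfig
    seed: int
    graph_kind: str = ""
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a tidy table: generation, mean_strategy, sd_strategy."""
        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self.mean) + 1),
                "mean_strategy": self.mean,
                "sd_strategy": self.sd,
            }
        )

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.hist_edges[:-1],
                "bin_right": self.hist_edges[1:],
                "count": self.hist_counts,
            }
        )


def initialize_population(config: SimulationConfig, rng: np.random.Generator) -> PopulationState:
    """Monomorphic start: one uniform draw assigned to every vertex; payoffs 0."""
    s0 = float(rng.uniform(0.0, 1.0))
    n = config.n
    return PopulationState(
        strategies=np.full(n, s0, dtype=float),
        payoffs=np.zeros(n, dtype=float),
        generation=0,
    )


def _padded(graph: PopulationGraph) -> tuple[np.ndarray, np.ndarray]:
    cached = getattr(graph, "_padded_cache", None)
    if cached is None:
        cached = graph.padded_adjacency()
        graph._padded_cache = cached
    return cached


def interaction_round(
    state: PopulationState,
    game: GameSpec,
    graph: PopulationGraph,
    rng: np.random.Generator,
    *,
    accumulate: bool = False,
) -> PopulationState:
    """N interaction steps, sampling focal individuals with replacement.

    Each step overwrites the focal's stored payoff with the payoff from a
    single game against a uniformly drawn neighbor (later steps win when a
    vertex is sampled twice). With ``accumulate=True`` payoffs add up
    instead.
    """
    n = graph.n
    if int(graph.degrees.min()) == 0:
        raise ValueError("graph has an isolated vertex; no co-player available")
    adj, deg = _padded(graph)
    focal = rng.integers(0, n, size=n)
    partner = adj[focal, (rng.random(n) * deg[focal]).astype(np.int64)]
    pay = np.asarray(
        smoothed_payoff(game, state.strategies[focal], state.strategies[partner])
    )
    if accumulate:
        np.add.at(state.payoffs, focal, pay)
    else:
        # keep only the last interaction of each sampled focal vertex
        last = (n - 1) - np.unique(focal[::-1], return_index=True)[1]
        state.payoffs[focal[last]] = pay[last]
    return state


def fermi_probability(payoff_focal: float, payoff_model: float, beta: float) -> float:
    """Fermi (pairwise-comparison) imitation probability; overflow-guarded."""
    if beta < 0:
        raise ValueError("selection strength must be non-negative")
    z = beta * (payoff_model - payoff_focal)
    if z > 700.0:
        return 1.0
    if z < -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


def replicator_probability(payoff_focal: float, payoff_model: float, delta_max: float) -> float:
    """Proportional imitation: positive payoff difference over its maximum."""
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    return min(1.0, max(0.0, payoff_model - payoff_focal) / delta_max)


def update_round(
    state: PopulationState,
    graph: PopulationGraph,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """N asynchronous update steps with imitation and clamped Gaussian mutation.

    Strategy changes within the round are visible to later steps (the
    sampling is sequential, with replacement). Payoffs are not recomputed
    within the round.

    Mutation semantics differ by rule. Under the Fermi rule a mutation
    replaces the adopted strategy (probability ``mu`` conditional on
    adoption). Under the replicator rule the mutation fires with
    probability ``mu`` per update step, whether or not imitation occurs:
    proportional imitation never copies at payoff ties, so a monomorphic
    population (all payoffs equal) would otherwise freeze permanently,
    with no channel left for variation to enter.
    """
    n = graph.n
    adj, deg = _padded(graph)
    s = state.strategies
    pi = state.payoffs
    beta = config.selection_strength
    mu = config.mutation_rate
    sigma = config.mutation_sd
    use_fermi = config.update_rule == "fermi"
    if not use_fermi:
        lo, hi = payoff_bounds(config.game)
        delta_max = hi - lo

    focal = rng.integers(0, n, size=n)
    pick = rng.random(n)
    accept = rng.random(n)
    mut = rng.random(n)
    z = rng.standard_normal(n)

    exp = math.exp
    for t in range(n):
        i = int(focal[t])
        j = int(adj[i, int(pick[t] * deg[i])])
        if use_fermi:
            w = beta * (pi[j] - pi[i])
            if w > 700.0:
                p = 1.0
            elif w < -700.0:
                p = 0.0
            else:
                p = 1.0 / (1.0 + exp(-w))
        else:
            p = min(1.0, max(0.0, pi[j] - pi[i]) / delta_max)
        if use_fermi:
            if accept[t] < p:
                if mut[t] < mu:
                    v = s[j] + sigma * z[t]
                    s[i] = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
                else:
                    s[i] = s[j]
        else:
            if mut[t] < mu:
                v = s[j] + sigma * z[t]
                s[i] = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
            elif accept[t] < p:
                s[i] = s[j]
    return state


def run_simulation(config: SimulationConfig) -> TrajectoryRecord:
    """Run the full evolutionary dynamics and record the trajectory.

    The master seed spawns three labeled sub-streams — graph construction,
    initialization, and the interleaved interaction/update dynamics — so the
    whole record is reproducible from ``config`` alone.
    """
    ss = np.random.SeedSequence(config.seed)
    graph_ss, init_ss, dyn_ss = ss.spawn(3)

    graph_seed = int(graph_ss.generate_state(1)[0] % (2**31))
    graph = build_graph(replace(config.graph, seed=graph_seed))

    state = initialize_population(config, np.random.default_rng(init_ss))
    rng = np.random.default_rng(dyn_ss)

    T = config.generations
    mean = np.empty(T)
    sd = np.empty(T)
    for gen in range(T):
        interaction_round(state, config.game, graph, rng,
                          accumulate=config.accumulate_payoffs)
        update_round(state, graph, config, rng)
        state.generation = gen + 1
        mean[gen] = state.strategies.mean()
        sd[gen] = state.strategies.std()

    state.validate()
    edges = np.linspace(0.0, 1.0, HISTOGRAM_BINS + 1)
    counts, _ = np.histogram(state.strategies, bins=edges)
    return TrajectoryRecord(
        mean=mean,
        sd=sd,
        final_strategies=state.strategies.copy(),
        hist_counts=counts,
        hist_edges=edges,
        config=config,
        seed=config.seed,
        graph_kind=graph.kind,
    )


def summary_mean_strategy(record: TrajectoryRecord, fraction: float | None = None) -> float:
    """Mean population strategy over the final ``ceil(fraction * T)`` generations."""
    if fraction is None:
        fraction = record.config.record_fraction
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    T = len(record.mean)
    if T == 0:
        raise ValueError("empty trajectory record")
    w = int(math.ceil(fraction * T))
    return float(record.mean[-w:].mean())
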