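"""The stochastic agent-based dynamics: rounds, update rules, full runs."""

import numpy as np
import pytest

from smoothgame import (
    BranchPayoff,
    GraphSpec,
    SimulationConfig,
    SmoothingSpec,
    build_graph,
    custom_game,
    fermi_probability,
    initialize_population,
    interaction_round,
    mec_game,
    replicator_probability,
    run_simulation,
    summary_mean_strategy,
    td_game,
    update_round,
)
from smoothgame.abm import TrajectoryRecord


def small_config(game=None, graph=None, **kw):
    game = game or mec_game(0.1, SmoothingSpec(20.0))
    graph = graph or GraphSpec("complete", 50)
    kw.setdefault("generations", 50)
    return SimulationConfig(game=game, graph=graph, **kw)


class TestInitialization:
    def test_monomorphic_start(self, rng):
        state = initialize_population(small_config(), rng)
        assert state.strategies.max() - state.strategies.min() == 0.0
        assert np.all(state.payoffs == 0.0)

    def test_same_seed_same_initial_strategy(self):
        cfg = small_config()
        s1 = initialize_population(cfg, np.random.default_rng(5)).strategies[0]
        s2 = initialize_population(cfg, np.random.default_rng(5)).strategies[0]
        assert s1 == s2


class TestInteractionRound:
    def test_equal_strategies_receive_diagonal_payoff(self, rng):
        graph = build_graph(GraphSpec("complete", 30))
        game = td_game(0.3, SmoothingSpec(20.0))
        cfg = small_config(game=game, graph=GraphSpec("complete", 30))
        state = initialize_population(cfg, np.random.default_rng(0))
        s0 = state.strategies[0]
        interaction_round(state, game, graph, rng)
        touched = state.payoffs != 0.0
        assert touched.any()
        np.testing.assert_allclose(state.payoffs[touched], s0)

    def test_two_vertex_partner_is_the_other(self, rng):
        from smoothgame.smoothing import INFINITY

        graph = build_graph(GraphSpec("complete", 2))
        game = mec_game(0.0, SmoothingSpec(INFINITY))  # payoff = min(x, y)
        state = initialize_population(small_config(game=game, graph=GraphSpec("complete", 2)),
                                      np.random.default_rng(0))
        state.strategies[:] = [0.2, 0.6]
        interaction_round(state, game, graph, rng)
        # both focals meet the other vertex: min(0.2, 0.6) = 0.2; a self-play
        # by vertex 1 would instead leave 0.6
        assert set(np.round(state.payoffs[state.payoffs != 0], 10)) <= {0.2}

    def test_distinct_focal_count_matches_occupancy(self):
        """Sampling N focals with replacement touches ~N(1-(1-1/N)^N) vertices."""
        n = 100
        graph = build_graph(GraphSpec("complete", n))
        game = td_game(0.3, SmoothingSpec(20.0))
        rng = np.random.default_rng(77)
        counts = []
        for _ in range(200):
            cfg = small_config(game=game, graph=GraphSpec("complete", n))
            state = initialize_population(cfg, np.random.default_rng(1))
            interaction_round(state, game, graph, rng)
            counts.append(int((state.payoffs != 0).sum()))
        expected = n * (1 - (1 - 1 / n) ** n)  # 63.4
        assert abs(np.mean(counts) - expected) < 1.5


class TestImitationProbabilities:
    def test_fermi_symmetry_and_limits(self):
        assert fermi_probability(0.3, 0.3, 5.0) == 0.5
        assert fermi_probability(1.0, 0.0, 0.0) == 0.5
        assert fermi_probability(0.0, 0.1, 1e6) == pytest.approx(1.0, abs=1e-9)

    def test_replicator_positive_part_normalized(self):
        assert replicator_probability(0.5, 0.3, 2.0) == 0.0
        assert replicator_probability(0.0, 2.0, 2.0) == 1.0
        # td R=0.5 bounds give delta_max = 2
        assert replicator_probability(0.0, 0.5, 2.0) == 0.25

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            replicator_probability(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            fermi_probability(0.0, 1.0, -1.0)


class TestUpdateRound:
    def test_strong_selection_loser_adopts_winner(self):
        graph = build_graph(GraphSpec("complete", 2))
        cfg = small_config(graph=GraphSpec("complete", 2),
                           mutation_rate=0.0, selection_strength=1e6)
        state = initialize_population(cfg, np.random.default_rng(0))
        state.strategies[:] = [0.1, 0.9]
        state.payoffs[:] = [0.0, 1.0]
        update_round(state, graph, cfg, np.random.default_rng(3))
        assert state.strategies[0] == 0.9  # loser copied the winner
        assert state.strategies[1] == 0.9  # winner kept (never adopts downhill)

    def test_certain_mutation_with_tiny_sd_copies_model(self):
        graph = build_graph(GraphSpec("complete", 20))
        cfg = small_config(graph=GraphSpec("complete", 20),
                           mutation_rate=1.0, mutation_sd=1e-12)
        state = initialize_population(cfg, np.random.default_rng(0))
        state.payoffs[:] = np.linspace(0, 1, 20)
        before = state.strategies.copy()
        update_round(state, graph, cfg, np.random.default_rng(4))
        np.testing.assert_allclose(state.strategies, before[0], atol=1e-9)

    def test_mutation_clamped_to_unit_interval(self):
        graph = build_graph(GraphSpec("complete", 40))
        cfg = small_config(graph=GraphSpec("complete", 40),
                           mutation_rate=1.0, mutation_sd=0.5)
        state = initialize_population(cfg, np.random.default_rng(0))
        state.strategies[:] = 0.99
        state.payoffs[:] = np.linspace(0, 1, 40)
        for seed in range(5):
            update_round(state, graph, cfg, np.random.default_rng(seed))
        assert state.strategies.max() <= 1.0 and state.strategies.min() >= 0.0


class TestRunSimulation:
    def test_neutral_game_is_frozen_without_mutation(self):
        const = BranchPayoff(
            g=lambda x, y: np.full_like(np.asarray(x, dtype=float), 0.3),
            h=lambda x, y: np.full_like(np.asarray(x, dtype=float), 0.3),
        )
        game = custom_game(const, SmoothingSpec(10.0), bounds=(0.3, 0.3))
        rec = run_simulation(small_config(game=game, mutation_rate=0.0, generations=30))
        assert np.all(rec.mean == rec.mean[0])
        assert np.all(rec.sd == 0.0)

    def test_seed_determinism_of_full_record(self):
        cfg = small_config(seed=11)
        r1, r2 = run_simulation(cfg), run_simulation(cfg)
        np.testing.assert_array_equal(r1.mean, r2.mean)
        np.testing.assert_array_equal(r1.final_strategies, r2.final_strategies)
        np.testing.assert_array_equal(r1.hist_counts, r2.hist_counts)

    def test_strategies_stay_in_unit_interval(self):
        cfg = small_config(mutation_rate=0.5, mutation_sd=0.4, generations=100, seed=3)
        rec = run_simulation(cfg)
        assert rec.final_strategies.min() >= 0.0
        assert rec.final_strategies.max() <= 1.0

    def test_histogram_counts_sum_to_population(self):
        cfg = small_config(seed=2)
        rec = run_simulation(cfg)
        assert rec.hist_counts.sum() == cfg.n

    @pytest.mark.parametrize("c,direction", [(0.1, 1), (0.9, -1)])
    def test_drift_direction_matches_selection_gradient(self, c, direction):
        """Tail mean moves from s0 in the direction of sign(1/2 - c)."""
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(
                game=mec_game(c, SmoothingSpec(20.0)),
                graph=GraphSpec("complete", 100),
                generations=400,
                seed=seed,
            )
            rec = run_simulation(cfg)
            s0 = rec.mean[0]
            hits += np.sign(summary_mean_strategy(rec) - s0) == direction
        assert hits >= 4

    def test_update_rule_validation(self):
        with pytest.raises(ValueError):
            small_config(update_rule="moran")


class TestSummary:
    def make_record(self, means):
        means = np.asarray(means, dtype=float)
        cfg = small_config(generations=len(means))
        return TrajectoryRecord(
            mean=means, sd=np.zeros_like(means),
            final_strategies=np.zeros(3), hist_counts=np.zeros(30, dtype=int),
            hist_edges=np.linspace(0, 1, 31), config=cfg, seed=0,
        )

    def test_constant_trajectory(self):
        assert summary_mean_strategy(self.make_record([0.4] * 10), 0.3) == pytest.approx(0.4)

    def test_tail_window_arithmetic(self):
        rec = self.make_record([0.0] * 8 + [1.0, 1.0])
        assert summary_mean_strategy(rec, 0.2) == 1.0

    def test_full_fraction_is_grand_mean(self):
        rec = self.make_record([0.0, 0.5, 1.0])
        assert summary_mean_strategy(rec, 1.0) == pytest.approx(0.5)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            summary_mean_strategy(self.make_record([0.1]), 0.0)
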