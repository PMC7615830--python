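import numpy as np
import pytest

from prospect.behavior import (
    DegenerateFitError,
    ReversalEnvironment,
    build_motor_schedule,
    fit_scale,
    grid_search_fit,
    motor_network,
    softmax_choice,
)
from prospect.behavior.schedule import TEST_COMBINATIONS


class TestMotorSchedule:
    @pytest.mark.parametrize("seed,participant", [(0, 0), (1, 1), (7, 5)])
    def test_block_structure(self, seed, participant):
        sched = build_motor_schedule(seed, participant)
        training = [t for t in sched.trials if t.session in ("training", "washout") and t.block >= 0]
        # every training block holds exactly two triplets with exposures {B+, R-}
        for block in range(24):
            exposures = [
                t.name
                for t in sched.trials
                if t.session == "training" and t.role == "triplet_exposure" and t.block == block
            ]
            assert sorted(exposures) == ["B+", "R-"]

    def test_perturbation_balance_within_eights(self):
        sched = build_motor_schedule(3, 0)
        for block in range(24):
            pert = [
                t.name
                for t in sched.trials
                if t.session == "training" and t.role == "standard" and t.block == block and t.perturbation != "0"
            ]
            assert len(pert) == 32
            for start in range(0, 32, 8):
                chunk = pert[start : start + 8]
                assert chunk.count("B+") == 4 and chunk.count("R-") == 4

    def test_testing_stage_has_32_triplets(self):
        sched = build_motor_schedule(5, 2)
        exposures = [t for t in sched.trials if t.session == "testing" and t.role == "triplet_exposure"]
        assert len(exposures) == 32
        for combo in TEST_COMBINATIONS:
            assert sum(t.combination == combo for t in exposures) == 8

    def test_washout_sampling_without_replacement(self):
        """Washout lengths come from replenished bags, so over 24 blocks each
        value of {14,16,18} appears exactly 8 times."""
        sched = build_motor_schedule(11, 0)
        lengths = []
        for block in range(24):  # training blocks only (testing blocks are 100+)
            n = sum(
                1
                for t in sched.trials
                if t.session == "washout" and t.block == block and t.role == "standard"
            )
            lengths.append(n)  # long + short washout per block
        # each block's washout total = one of {14,16,18} + one of {6,8,10}
        assert all(20 <= n <= 28 for n in lengths)
        assert sum(lengths) == 24 * (16 + 8)  # bag means over full cycles

    def test_washout_trials_have_no_perturbation(self):
        sched = build_motor_schedule(13, 1)
        assert all(t.perturbation == "0" for t in sched.trials if t.session == "washout")


class TestMotorNetwork:
    def test_diagonal_structure_survives_training(self):
        from prospect import pcn

        net = motor_network(seed=0, init_sd=0.1)
        assert net.weights[0][0, 1] == 0.0 and net.weights[0][1, 0] == 0.0
        rng = np.random.default_rng(1)
        for _ in range(5):
            net = pcn.learn(net, rng.normal(size=2), rng.normal(size=2), alpha=0.1)
        assert net.weights[0][0, 1] == 0.0 and net.weights[0][1, 0] == 0.0

    def test_init_sd_scales_weights(self):
        big = motor_network(seed=2, init_sd=0.1)
        small = motor_network(seed=2, init_sd=0.01)
        assert np.allclose(np.diag(big.weights[0]) / 10, np.diag(small.weights[0]))


class TestReversalEnvironment:
    def test_deterministic_limit(self):
        env = ReversalEnvironment(1.0, 0.0, reversal_period=10, seed=0)
        for _ in range(9):
            assert env.sample(0) == 1

    def test_probability_sum_conserved(self):
        env = ReversalEnvironment(0.8, 0.2, reversal_period=3, seed=1)
        for _ in range(50):
            env.sample(0)
            assert env.probabilities.sum() == pytest.approx(1.0)

    def test_empirical_rate_tracks_schedule(self):
        env = ReversalEnvironment(0.8, 0.2, reversal_period=10_000_000, seed=2)
        n = 50_000
        wins = sum(env.sample(0) == 1 for _ in range(n))
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(wins / n - 0.8) < 2 * se + 1e-9


class TestSoftmaxChoice:
    def test_closed_form_frequency(self):
        rng = np.random.default_rng(3)
        n = 100_000
        p1 = np.e / (1 + np.e)  # values (1, 0), T=1
        draws = sum(softmax_choice(np.array([1.0, 0.0]), 1.0, rng) == 0 for _ in range(n))
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(draws / n - p1) < 3 * se

    def test_equal_values_balanced(self):
        rng = np.random.default_rng(4)
        n = 20_000
        draws = sum(softmax_choice(np.zeros(2), 1.0, rng) for _ in range(n))
        assert abs(draws / n - 0.5) < 0.02


class TestFitScale:
    def test_identity_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_scale(x, x)
        assert fit.a == pytest.approx(1.0)
        fit_b = fit_scale(x, x, with_bias=True)
        assert fit_b.a == pytest.approx(1.0) and fit_b.b == pytest.approx(0.0, abs=1e-12)

    def test_positivity_clip(self):
        fit = fit_scale(np.ones(4), -np.ones(4))
        assert fit.a == 0.0
        fit_b = fit_scale(np.array([1.0, 2.0, 3.0, 4.0]), np.array([4.0, 3.0, 2.0, 1.0]), with_bias=True)
        assert fit_b.a == 0.0
        assert fit_b.b == pytest.approx(2.5)  # refit bias at a = 0

    def test_matches_dense_grid_minimization(self):
        """The analytic scale agrees with brute-force 1-D minimization."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=4)
            d = rng.normal(size=4)
            fit = fit_scale(x, d)
            grid = np.linspace(0, 5, 500_001)
            objs = ((grid[:, None] * x[None, :] - d[None, :]) ** 2).sum(axis=1)
            assert fit.a == pytest.approx(grid[np.argmin(objs)], abs=1e-4)

    def test_degenerate_signal(self):
        with pytest.raises(DegenerateFitError):
            fit_scale(np.zeros(4), np.ones(4))


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        data = {"punish_stay": 0.15, "stay": 0.05, "punish_switch": 0.05, "switch": 0.15}
        best, frame = grid_search_fit(
            "bp", "reversal", data,
            {"init_sd": [0.1], "alpha": [0.05]},
            n_participants=2, seed=0, n_trials=16,
        )
        assert best.params == {"init_sd": 0.1, "alpha": 0.05}
        assert len(frame) == 1

    def test_argmin_contract(self):
        data = {"punish_stay": 0.15, "stay": 0.05, "punish_switch": 0.05, "switch": 0.15}
        best, frame = grid_search_fit(
            "bp", "reversal", data,
            {"init_sd": [0.01, 0.1], "alpha": [0.05, 0.1]},
            n_participants=2, seed=0, n_trials=16,
        )
        assert best.objective == pytest.approx(frame.objective.min())
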