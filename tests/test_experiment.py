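import numpy as np
import pytest
from scipy import stats as sps

from opcond import default_config
from opcond.config import ConfigurationError
from opcond.experiment import (
    Trajectory,
    TrialOutcome,
    performance_curve,
    run_ensemble,
    run_model,
    scale_to_anchor,
    session_summaries,
    smooth,
    stage_criteria,
    tune_parameters,
    windowed_performance,
)


def outcome(correct=True, forced=False, latency=5, plast=0.01):
    return TrialOutcome(
        response=0 if correct else 1,
        correct=correct,
        reward=1.0 if correct else 0.0,
        latency_steps=latency,
        forced=forced,
        plasticity=plast,
        plasticity_bg=0.0,
    )


class TestRunModel:
    def test_deterministic_given_config_and_seed(self, fast_config):
        a = run_model(fast_config, 11)
        b = run_model(fast_config, 11)
        assert a == b

    def test_different_seeds_differ(self, fast_config):
        a = run_model(fast_config, 11)
        b = run_model(fast_config, 12)
        assert a != b

    def test_invalid_config_reports_field(self):
        bad = default_config()
        bad.td.alpha = -1.0
        with pytest.raises(ConfigurationError, match="td.alpha"):
            run_model(bad, 1)

    def test_vanishing_learning_rates_stay_at_chance(self):
        cfg = default_config().replace(
            **{
                "learning.nu_pfc": 1e-12,
                "learning.nu_bgpmc": 1e-12,
                "protocol.n_trials": 400,
                "protocol.steps_lever_out": 10,
                "protocol.steps_iti": 3,
            }
        )
        outs = run_model(cfg, 2)
        assert all(o.forced for o in outs)
        frac = np.mean([o.correct for o in outs])
        assert frac == pytest.approx(1 / 3, abs=0.08)

    def test_latency_in_seconds_and_trial_bound(self, fast_config):
        outs = run_model(fast_config, 4)
        L = fast_config.protocol.steps_lever_out
        for o in outs:
            assert 0 <= o.latency_steps <= L
            assert o.latency_s == pytest.approx(o.latency_steps * 0.1)
            assert o.plasticity >= 0


class TestEnsemble:
    def test_single_model_has_zero_sem(self, fast_config):
        traj = run_ensemble(fast_config, n_models=1, base_seed=3)
        assert (traj.sem_perf == 0).all() and (traj.sem_plast == 0).all()

    def test_mean_performance_bounded(self, fast_config):
        traj = run_ensemble(fast_config, n_models=5, base_seed=3)
        assert ((0 <= traj.mean_perf) & (traj.mean_perf <= 1)).all()
        assert (traj.sem_perf >= 0).all()

    def test_sem_shrinks_with_ensemble_size(self):
        cfg = default_config().replace(
            **{
                "protocol.n_trials": 40,
                "protocol.steps_lever_out": 15,
                "protocol.steps_iti": 4,
            }
        )
        small = run_ensemble(cfg, n_models=8, base_seed=1)
        large = run_ensemble(cfg, n_models=32, base_seed=1)
        # mean SEM should scale roughly like 1/sqrt(n)
        ratio = small.sem_perf.mean() / large.sem_perf.mean()
        assert 1.3 < ratio < 3.2

    def test_default_learning_is_monotone_in_session_bins(self):
        cfg = default_config().replace(**{"protocol.n_trials": 125})
        traj = run_ensemble(cfg, n_models=10, base_seed=20)
        bins = traj.mean_perf.reshape(5, 25).mean(axis=1)
        rho, _ = sps.spearmanr(np.arange(len(bins)), bins)
        assert rho > 0


class TestPerformanceCurve:
    def test_all_correct(self):
        curve = performance_curve([outcome(True)] * 50, bin_size=25)
        np.testing.assert_allclose(curve, [1.0, 1.0])

    def test_fifteen_of_twentyfive(self):
        outs = [outcome(i < 15) for i in range(25)]
        assert performance_curve(outs, 25)[0] == pytest.approx(0.60)

    def test_forced_random_near_chance(self):
        rng = np.random.default_rng(0)
        outs = [outcome(rng.integers(3) == 0, forced=True) for _ in range(900)]
        assert performance_curve(outs, 900)[0] == pytest.approx(1 / 3, abs=0.05)


class TestStageCriteria:
    def test_first_session_in_band_marks_incomplete_stage(self):
        labels = stage_criteria([(0.3, 40.0), (0.55, 30.0), (0.9, 10.0)])
        assert labels["fifty_cr_session"] == 2

    def test_three_consecutive_perfect_sessions_mark_learned_stage(self):
        summaries = [(0.6, 20.0)] + [(1.0, 4.0)] * 3
        labels = stage_criteria(summaries)
        assert labels["hundred_cr_session"] == 4

    def test_streak_broken_by_slow_session(self):
        summaries = [(1.0, 4.0), (1.0, 6.0), (1.0, 4.0), (1.0, 4.0), (1.0, 4.0)]
        assert stage_criteria(summaries)["hundred_cr_session"] == 5

    def test_never_in_band_gives_no_label(self):
        labels = stage_criteria([(0.2, 50.0), (0.9, 10.0)])
        assert labels["fifty_cr_session"] is None

    def test_session_summaries_shapes(self, fast_config):
        outs = run_model(fast_config, 1)
        sums = session_summaries(outs, trials_per_session=10)
        assert len(sums) == 3
        for frac, lat in sums:
            assert 0 <= frac <= 1 and lat >= 0


class TestScaleToAnchor:
    def traj(self, plast):
        plast = np.asarray(plast, dtype=float)
        n = len(plast)
        return Trajectory(
            mean_perf=np.zeros(n), sem_perf=np.zeros(n),
            mean_plast=plast, sem_plast=np.zeros(n),
            n_models=1, seeds=np.array([0]),
        )

    def test_identity_when_anchor_matches_current_value(self):
        plast = np.linspace(1, 2, 100)
        traj = self.traj(plast)
        ref = smooth(plast, 11)[69]
        scaled = scale_to_anchor(traj, anchor_value=ref, anchor_trial=70)
        np.testing.assert_allclose(scaled, smooth(plast, 11))

    def test_anchor_value_attained_and_shape_preserved(self):
        traj = self.traj(np.linspace(1, 2, 100))
        scaled = scale_to_anchor(traj, anchor_value=131.9, anchor_trial=70)
        assert scaled[69] == pytest.approx(131.9)
        sm = smooth(traj.mean_plast, 11)
        np.testing.assert_allclose(scaled / scaled[69], sm / sm[69])

    def test_doubling_anchor_doubles_series(self):
        traj = self.traj(np.linspace(1, 2, 100))
        s1 = scale_to_anchor(traj, anchor_value=10.0, anchor_trial=70)
        s2 = scale_to_anchor(traj, anchor_value=20.0, anchor_trial=70)
        np.testing.assert_allclose(s2, 2 * s1)

    def test_zero_anchor_plasticity_rejected(self):
        traj = self.traj(np.zeros(100))
        with pytest.raises(ValueError):
            scale_to_anchor(traj, anchor_value=1.0, anchor_trial=70)


class TestWindowedPerformance:
    def test_window_average(self):
        n = 50
        traj = Trajectory(
            mean_perf=np.arange(n, dtype=float), sem_perf=np.zeros(n),
            mean_plast=np.zeros(n), sem_plast=np.zeros(n),
            n_models=1, seeds=np.array([0]),
        )
        # centered 10-trial window at trial 20 -> trials 15..24 (values 14..23)
        assert windowed_performance(traj, 20, 10) == pytest.approx(np.mean(np.arange(14, 24)))

    def test_window_clipped_at_edges(self):
        n = 20
        traj = Trajectory(
            mean_perf=np.arange(n, dtype=float), sem_perf=np.zeros(n),
            mean_plast=np.zeros(n), sem_plast=np.zeros(n),
            n_models=1, seeds=np.array([0]),
        )
        assert windowed_performance(traj, 20, 10) == pytest.approx(np.mean(np.arange(10, 20)))


class TestTuneParameters:
    def small_cfg(self):
        return default_config().replace(
            **{
                "protocol.n_trials": 40,
                "protocol.steps_lever_out": 12,
                "protocol.steps_iti": 4,
            }
        )

    def test_single_point_grid_returns_that_point(self):
        cfg = self.small_cfg()
        best, report = tune_parameters(
            cfg, {"learning.nu_bgpmc": [0.002]},
            targets=((20, 0.5),), n_models=2, base_seed=1,
        )
        assert best.learning.nu_bgpmc == 0.002
        assert len(report) == 1

    def test_best_point_minimizes_reported_loss(self):
        cfg = self.small_cfg()
        best, report = tune_parameters(
            cfg, {"learning.nu_bgpmc": [0.0005, 0.002, 0.008]},
            targets=((20, 0.5), (38, 1.0)), n_models=3, base_seed=1,
        )
        losses = {r["params"]["learning.nu_bgpmc"]: r["loss"] for r in report}
        assert losses[best.learning.nu_bgpmc] == min(losses.values())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_parameters(self.small_cfg(), {})
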