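"""Generator-level checks: behaviour occupancy, dwell distributions,
trajectory bounds, latent linearity, indicator kernel, and determinism."""

import numpy as np
import pytest
from scipy import stats

from achdyn import simulate as sim
from achdyn.kinematics import log2_with_floor


class TestBehavior:
    def test_degenerate_single_state(self):
        cfg = sim.SynthConfig(
            session_duration=60.0,
            occupancy_targets={"still": 1.0},
        )
        labels = sim.simulate_behavior(cfg, 0)
        assert np.all(labels.states == sim.STATE_INDEX["still"])

    def test_occupancy_matches_targets_over_two_hours(self):
        """Realized occupancies converge to the configured open-field
        fractions (70.4% run / 26.2% walk / 2.1% rear / 1.4% groom)
        within 2 percentage points over a 2 h corpus."""
        cfg = sim.SynthConfig(session_duration=7200.0)
        labels = sim.simulate_behavior(cfg, 123)
        occ = labels.occupancy()
        for state, target in cfg.occupancy_targets.items():
            assert abs(occ[state] - target) < 0.02, (state, occ[state], target)

    def test_dwell_distribution_matches_configured_law(self):
        """Drawn dwell times agree with direct draws from the configured
        log-normal dwell law (two-sample KS, ~1e4 bouts each)."""
        cfg = sim.SynthConfig(
            session_duration=40000.0,
            occupancy_targets={"run": 1.0},
        )
        labels = sim.simulate_behavior(cfg, 5)
        realized = np.array([n for _, n in labels.drawn_bouts[:-1]]) / cfg.frame_rate
        oracle = sim.sample_dwell_times(cfg, "run", 10_000, 99)
        # frame rounding: quantize the oracle the same way
        oracle_q = np.maximum(1, np.round(oracle * cfg.frame_rate)) / cfg.frame_rate
        assert len(realized) > 5000
        stat, p = stats.ks_2samp(realized, oracle_q)
        assert p > 0.01

    def test_occupancy_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sim.SynthConfig(occupancy_targets={"run": 0.5, "walk": 0.2})

    def test_positive_occupancy_requires_speed_range(self):
        with pytest.raises(ValueError, match="speed range"):
            sim.SynthConfig(
                occupancy_targets={"run": 1.0},
                speed_ranges={"walk": (3.0, 10.0)},
            )


class TestTrajectory:
    def test_still_labels_give_stationary_speed(self, small_config):
        cfg = sim.SynthConfig(
            session_duration=120.0, occupancy_targets={"still": 1.0}
        )
        labels = sim.simulate_behavior(cfg, 1)
        _, speed = sim.simulate_trajectory(labels, cfg, 2)
        assert np.all(speed < 3.0)

    def test_positions_within_arena(self):
        cfg = sim.SynthConfig(
            session_duration=300.0, tracking_jitter_sd=0.0, dropout_prob=0.0
        )
        labels = sim.simulate_behavior(cfg, 3)
        pose, _ = sim.simulate_trajectory(labels, cfg, 4)
        w, h = cfg.arena_size
        assert pose.neck_x.min() >= 0 and pose.neck_x.max() <= w
        assert pose.neck_y.min() >= 0 and pose.neck_y.max() <= h

    def test_run_state_mean_speed_in_configured_range(self):
        cfg = sim.SynthConfig(
            session_duration=120.0, occupancy_targets={"run": 1.0}
        )
        lo, hi = cfg.speed_ranges["run"]
        means = []
        for seed in range(20):
            labels = sim.simulate_behavior(cfg, seed)
            _, speed = sim.simulate_trajectory(labels, cfg, 100 + seed)
            means.append(speed.mean())
        assert lo < np.mean(means) < hi

    def test_zero_arena_rejected(self):
        with pytest.raises(ValueError, match="arena"):
            sim.SynthConfig(arena_size=(0.0, 40.0))


class TestLatent:
    def test_constant_speed_closed_form(self):
        cfg = sim.SynthConfig(
            session_duration=10.0,
            noise=sim.NoiseParams(0.9, 0.0),
            coeffs=sim.Coefficients(
                beta0=0.5, beta_speed=0.3, beta_rear=0.0, beta_groom=0.0
            ),
            occupancy_targets={"walk": 1.0},
        )
        labels = sim.simulate_behavior(cfg, 0)
        speed = np.full(len(labels), 2 * cfg.speed_floor)
        latent = sim.simulate_latent(speed, labels, cfg, seed=0)
        expected = 0.5 + 0.3 * np.log2(2 * cfg.speed_floor)
        np.testing.assert_allclose(latent, expected, atol=1e-12)

    def test_zero_noise_ols_recovers_coefficients_exactly(self):
        cfg = sim.SynthConfig(
            session_duration=300.0,
            noise=sim.NoiseParams(0.9, 0.0),
            occupancy_targets={"run": 0.4, "walk": 0.3, "groom": 0.15, "rear": 0.15},
        )
        rng = np.random.default_rng(8)
        labels = sim.simulate_behavior(cfg, rng)
        _, speed = sim.simulate_trajectory(labels, cfg, rng)
        latent = sim.simulate_latent(speed, labels, cfg, seed=rng)
        ls = log2_with_floor(speed, cfg.speed_floor)
        X = np.column_stack(
            [
                np.ones(len(ls)),
                ls,
                labels.indicator("rear"),
                labels.indicator("groom"),
            ]
        )
        beta, *_ = np.linalg.lstsq(X, latent, rcond=None)
        c = cfg.coeffs
        np.testing.assert_allclose(
            beta, [c.beta0, c.beta_speed, c.beta_rear, c.beta_groom], atol=1e-9
        )

    def test_default_coefficients_are_the_fitted_open_field_values(self):
        c = sim.Coefficients()
        assert c.beta_speed == pytest.approx(0.221)
        assert c.beta_rear == pytest.approx(0.277)


class TestKernel:
    @pytest.mark.parametrize("half_decay", [0.5, 1.69, 3.0])
    def test_measured_half_decay_matches_config(self, half_decay):
        rate = 30.0
        k = sim.calcium_kernel(rate, 0.2, half_decay)
        measured = sim.kernel_half_decay(k, rate)
        assert abs(measured - half_decay) <= 1.0 / rate

    def test_kernel_is_causal_and_normalised(self):
        k = sim.calcium_kernel(30.0, 0.2, 1.69)
        assert k[0] == 0.0 or k[0] >= 0
        assert np.all(k >= 0)
        assert k.sum() == pytest.approx(1.0)


class TestRender:
    def test_zero_signal_gives_pure_bleach_and_flat_dff(self):
        from achdyn.photometry import process_session

        cfg = sim.SynthConfig(
            session_duration=60.0,
            photometry_noise_sd=0.0,
            dff_offset=0.0,
            artifact=sim.ArtifactParams(rate_per_min=0.0, amplitude=0.0),
        )
        latent = np.zeros(cfg.n_frames)
        raw, truth = sim.render_photometry(latent, cfg, 0)
        np.testing.assert_allclose(raw.f470, truth.bleach_470, atol=1e-12)
        trace = process_session(raw)
        assert abs(np.mean(trace.dff)) < 1e-6

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            sim.SynthConfig(bleach_470=sim.BleachParams(-1.0, 600.0))

    def test_isosbestic_channel_has_no_calcium_component(self):
        """Regressing detrended F405 on detrended true dF/F must give a
        slope indistinguishable from zero (alpha = 0.01, 20 seeds)."""
        cfg = sim.SynthConfig(session_duration=60.0)
        n_reject = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            labels = sim.simulate_behavior(cfg, rng)
            _, speed = sim.simulate_trajectory(labels, cfg, rng)
            latent = sim.simulate_latent(speed, labels, cfg, seed=rng)
            raw, truth = sim.render_photometry(latent, cfg, rng)

            def detrend(y, t):
                p = np.polynomial.Polynomial.fit(t, y, deg=2)
                return y - p(t)

            y = detrend(raw.f405, raw.time_s)
            x = detrend(truth.true_dff_samples, raw.time_s)
            # thin to ~1 s spacing so the OLS independence assumption holds
            step = int(cfg.photometry_rate)
            res = stats.linregress(x[::step], y[::step])
            if res.pvalue < 0.01:
                n_reject += 1
        assert n_reject <= 2


class TestCohort:
    def test_same_seed_gives_byte_identical_manifests(self, tmp_path):
        cfg = sim.SynthConfig(session_duration=10.0)
        m1 = sim.simulate_cohort(cfg, 2, 1, seed=3, outdir=tmp_path / "a")
        m2 = sim.simulate_cohort(cfg, 2, 1, seed=3, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        for name in m1["photometry_path"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_manifest_row_count_is_total_sessions(self, tmp_path):
        cfg = sim.SynthConfig(session_duration=10.0)
        manifest = sim.simulate_cohort(
            cfg, 3, [2, 1, 3], seed=1, outdir=tmp_path / "c"
        )
        assert len(manifest) == 6

    def test_study_session_count_structure(self, tmp_path):
        """5 animals with 20/46/8/17/12 sessions give a 103-session
        cohort structure (manifest counting only; durations trivial)."""
        cfg = sim.SynthConfig(session_duration=2.0)
        counts = [20, 46, 8, 17, 12]
        manifest = sim.simulate_cohort(
            cfg, 5, counts, seed=2, outdir=tmp_path / "d"
        )
        assert len(manifest) == 103
        per_animal = manifest.groupby("animal_id").size()
        assert sorted(per_animal.tolist()) == sorted(counts)

    def test_aligned_cohort_deterministic(self, small_config):
        s1, _ = sim.simulate_aligned_cohort(small_config, 2, 2, seed=11)
        s2, _ = sim.simulate_aligned_cohort(small_config, 2, 2, seed=11)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.zdff, b.zdff)
            np.testing.assert_array_equal(a.speed, b.speed)
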