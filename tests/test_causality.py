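"""Multi-trial VAR fitting, order selection and Granger-causality
magnitudes, checked against null calibration, consistency Monte-Carlo and
brute-force regression oracles."""

import numpy as np
import pytest
from scipy import stats

from achdyn import causality as gc


class TestTruncate:
    def test_ten_minute_session_keeps_9000_frames(self):
        n = 10 * 60 * 30
        trial = gc.truncate_first_minutes(np.zeros(n) + 1, np.arange(n, dtype=float), 30.0)
        assert len(trial) == 9000

    def test_short_session_used_whole_with_warning(self):
        n = 4 * 60 * 30
        with pytest.warns(UserWarning, match="whole session"):
            trial = gc.truncate_first_minutes(np.ones(n), np.ones(n), 30.0)
        assert len(trial) == n

    def test_output_is_mean_removed(self):
        rng = np.random.default_rng(0)
        trial = gc.truncate_first_minutes(
            rng.standard_normal(9500) + 3, rng.standard_normal(9500) - 1, 30.0
        )
        np.testing.assert_allclose(trial.mean(axis=0), 0.0, atol=1e-12)


class TestVARFit:
    def test_null_coefficients_within_three_se(self):
        """White-noise trials: every coefficient within 3 SE of zero in at
        least 95% of 100 seeds."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trials = [rng.standard_normal((500, 2)) for _ in range(2)]
            fit = gc.fit_var_multitrial(trials, 1)
            if np.all(np.abs(fit.coef) < 3 * fit.se_coef):
                ok += 1
        assert ok >= 95

    def test_consistency_on_known_var1(self):
        A = np.array([[[0.5, 0.2], [0.0, 0.4]]])
        data = gc.simulate_var(A, 100_000, seed=7)
        fit = gc.fit_var_multitrial([data], 1)
        np.testing.assert_allclose(fit.coef[0], A[0], atol=0.02)

    def test_multitrial_equals_explicitly_stacked_regression(self):
        rng = np.random.default_rng(8)
        trials = [rng.standard_normal((80, 2)) for _ in range(3)]
        p = 2
        fit = gc.fit_var_multitrial(trials, p)
        # brute-force oracle: build the stacked design row by row
        rows, ys = [], []
        for tr in trials:
            for t in range(p, len(tr)):
                rows.append(np.concatenate([tr[t - k] for k in range(1, p + 1)]))
                ys.append(tr[t])
        B, *_ = np.linalg.lstsq(np.array(rows), np.array(ys), rcond=None)
        oracle = B.reshape(p, 2, 2).transpose(0, 2, 1)
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-10)

    def test_singular_design_rejected(self):
        x = np.zeros((100, 2))
        with pytest.raises(np.linalg.LinAlgError):
            gc.fit_var_multitrial([x], 1)


class TestOrderSelection:
    def test_pmax_one(self):
        rng = np.random.default_rng(1)
        assert gc.select_order([rng.standard_normal((200, 2))], 1) == 1

    def test_recovers_var3_order(self):
        """AIC picks the true order 3 in >= 16/20 seeds at n=1e4."""
        A = np.zeros((3, 2, 2))
        A[0] = [[0.4, 0.1], [0.1, 0.3]]
        A[2] = [[-0.3, 0.1], [0.2, -0.35]]
        hits = 0
        for seed in range(20):
            data = gc.simulate_var(A, 10_000, seed=100 + seed)
            if gc.select_order([data], 6) == 3:
                hits += 1
        assert hits >= 16

    def test_criterion_matches_independent_loglik_formula(self):
        rng = np.random.default_rng(2)
        trials = [rng.standard_normal((300, 2)) for _ in range(2)]
        p, p_max = 2, 4
        val = gc.information_criterion(trials, p, p_max, "aic")
        # independent enumeration on the common sample
        ys, xs = [], []
        for tr in trials:
            for t in range(p_max, len(tr)):
                xs.append(np.concatenate([tr[t - k] for k in range(1, p + 1)]))
                ys.append(tr[t])
        X, Y = np.array(xs), np.array(ys)
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ B
        sigma = R.T @ R / len(Y)
        expect = len(Y) * np.log(np.linalg.det(sigma)) + 2 * (4 * p)
        assert abs(val - expect) < 1e-9


class TestGCMagnitude:
    def test_null_bias_and_type_one_error(self):
        """Independent channels (n=9000, p=9): mean magnitude below the
        asymptotic bias bound 1.5*2p/n, and chi2 rejection rate at
        alpha=0.05 within [0.03, 0.07], over 400 replicates."""
        rng = np.random.default_rng(3)
        mags, rej = [], 0
        for _ in range(400):
            x = rng.standard_normal((9000, 2))
            res = gc.gc_pair([x], 9)
            mags.append(res.gc_speed_to_ach)
            rej += res.p_speed_to_ach < 0.05
        assert np.mean(mags) < 1.5 * 2 * 9 / 9000
        assert 0.03 <= rej / 400 <= 0.07

    def test_matches_bruteforce_long_run_oracle(self):
        """Estimated GC within 5% of a brute-force restricted-vs-full
        regression oracle on one n=1e6 series from a known VAR(1)."""
        A = np.array([[[0.5, 0.0], [0.3, 0.5]]])
        data = gc.simulate_var(A, 10**6, seed=11)
        est = gc.gc_magnitude([data], 1, "speed->ach")
        # oracle: independent lag-1 regressions via normal equations
        y = data[1:, 1]
        x_full = np.column_stack([data[:-1, 1], data[:-1, 0]])
        x_red = data[:-1, 1:2]

        def ssr(X, y):
            b = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ b
            return r @ r

        oracle = np.log(ssr(x_red, y) / ssr(x_full, y))
        assert abs(est - oracle) / oracle < 0.05

    def test_f_zero_gives_p_one(self):
        assert gc.gc_significance(0.0, 1000, 5) == pytest.approx(1.0)

    def test_chi2_quantile_definition(self):
        crit = stats.chi2.ppf(0.95, 9)
        assert gc.gc_significance(crit / 5000, 5000, 9) == pytest.approx(0.05, abs=1e-9)

    def test_agrees_with_f_test_variant_at_large_n(self):
        """The chi2 likelihood-ratio p-value agrees with an F-test variant
        within 10% relative for n_eff >= 5000 and moderate evidence."""
        A = np.array([[[0.5, 0.0], [0.022, 0.5]]])
        data = gc.simulate_var(A, 9000, seed=13)
        p_order = 1
        full = gc.fit_var_multitrial([data], p_order)
        mag = gc.gc_magnitude([data], p_order, "speed->ach")
        p_chi2 = gc.gc_significance(mag, full.n_eff, p_order)
        ssr_full = full.ssr[gc.ACH]
        ssr_red = ssr_full * np.exp(mag)
        n, k = full.n_eff, 2 * p_order
        fstat = ((ssr_red - ssr_full) / p_order) / (ssr_full / (n - k))
        p_f = stats.f.sf(fstat, p_order, n - k)
        assert 1e-6 < p_chi2 < 0.9  # moderate-evidence regime
        assert abs(p_chi2 - p_f) / p_f < 0.10

    def test_affine_invariance(self):
        rng = np.random.default_rng(14)
        data = rng.standard_normal((2000, 2))
        data = data - data.mean(axis=0)
        base = gc.gc_pair([data], 3)
        scaled = np.column_stack([5.0 * data[:, 0] - 2.0, 0.3 * data[:, 1] + 7.0])
        scaled = scaled - scaled.mean(axis=0)
        res = gc.gc_pair([scaled], 3)
        assert abs(res.gc_speed_to_ach - base.gc_speed_to_ach) < 1e-9
        assert abs(res.gc_ach_to_speed - base.gc_ach_to_speed) < 1e-9

    def test_magnitude_monotone_in_coupling(self):
        """Median GC decreases toward 0 as the coupling shrinks (3 levels
        x 20 seeds)."""
        medians = []
        for c in (0.3, 0.15, 0.05):
            mags = []
            for seed in range(20):
                A = np.array([[[0.5, 0.0], [c, 0.4]]])
                data = gc.simulate_var(A, 4000, seed=1000 + seed)
                mags.append(gc.gc_magnitude([data], 1, "speed->ach"))
            medians.append(np.median(mags))
        assert medians[0] > medians[1] > medians[2]

    def test_reduced_ssr_never_below_full(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            data = rng.standard_normal((800, 2))
            res = gc.gc_pair([data], 4)
            assert res.gc_speed_to_ach >= 0
            assert res.gc_ach_to_speed >= 0


class TestPerMouse:
    def _sessions(self, n_animals, n_sessions, n=4000, seed=0):
        from achdyn.tuning import AlignedSession

        rng = np.random.default_rng(seed)
        out = []
        for a in range(n_animals):
            for s in range(n_sessions):
                x = rng.standard_normal(n)
                z = np.roll(x, 3) * 0.5 + rng.standard_normal(n)
                out.append(
                    AlignedSession(
                        animal_id=f"m{a}",
                        session_id=f"m{a}_s{s}",
                        lighting="light" if s % 2 == 0 else "dark",
                        frame_time=np.arange(n) / 30.0,
                        zdff=z,
                        speed=np.exp(x),
                        logspeed=x,
                        community=np.zeros(n, dtype=int),
                    )
                )
        return out

    def test_single_session_equals_single_trial_gc(self):
        sess = self._sessions(1, 1)
        per_animal, per_session = gc.per_mouse_gc(sess, 30.0, p_max=5)
        trial = gc.truncate_first_minutes(
            sess[0].logspeed, sess[0].zdff, 30.0
        )
        p = int(per_animal["order"].iloc[0])
        direct = gc.gc_pair([trial], p)
        assert per_animal["gc_speed_to_ach"].iloc[0] == pytest.approx(
            direct.gc_speed_to_ach
        )
        row = per_session[per_session.direction == "speed_to_ach"]
        assert row["gc_nats"].iloc[0] == pytest.approx(direct.gc_speed_to_ach)

    def test_session_order_permutation_invariant(self):
        sess = self._sessions(2, 3, n=3000, seed=5)
        a1, _ = gc.per_mouse_gc(sess, 30.0, p_max=4)
        a2, _ = gc.per_mouse_gc(sess[::-1], 30.0, p_max=4)
        m1 = a1.set_index("animal_id")["gc_speed_to_ach"]
        m2 = a2.set_index("animal_id")["gc_speed_to_ach"]
        for k in m1.index:
            assert m1[k] == pytest.approx(m2[k], abs=1e-12)
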