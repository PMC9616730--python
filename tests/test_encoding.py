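"""Tests of the design-matrix builder and cross-validated ridge fits."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from twotask2p import (
    EventStreams,
    KernelWindows,
    RidgeEncodingCV,
    SimConfig,
    build_design_matrix,
    encoding_cross_task,
    fit_ridge_cv,
    generate_session,
    ridge_solve,
    variance_explained,
)


def _streams(stim=((), ()), choice=((), ()), reward=(), continuous=None):
    return EventStreams(
        stimulus_onsets=(np.asarray(stim[0], float), np.asarray(stim[1])),
        choice_times=(np.asarray(choice[0], float), np.asarray(choice[1])),
        reward_times=np.asarray(reward, float),
        continuous=continuous or {},
    )


class TestBuildDesignMatrix:
    def test_single_event_window_rounds_outward(self):
        """One stimulus at frame 10 with a (-50, 500) ms window at 10 Hz
        gives one indicator column per lag -1..5, each with its single
        nonzero entry at frames 9..15."""
        streams = _streams(stim=([1.0], ["R"]))
        dm = build_design_matrix(streams, KernelWindows(), 10.0, 30)
        stim_cols = [
            (i, c) for i, c in enumerate(dm.columns)
            if c["predictor"] == "stimulus"
        ]
        assert [c["lag_frames"] for _, c in stim_cols] == list(range(-1, 6))
        for i, c in stim_cols:
            col = dm.X[:, i]
            peak = np.argmax(col)
            assert peak == 10 + c["lag_frames"]
            # z-scored single indicator: one high value, T-1 equal low ones
            assert np.sum(col == col.max()) == 1

    def test_continuous_channel_has_five_lags(self, rng):
        streams = _streams(continuous={"wheel_cw": rng.normal(size=100)})
        dm = build_design_matrix(streams, KernelWindows(), 10.0, 100)
        lags = [c["lag_frames"] for c in dm.columns if c["kind"] == "continuous"]
        assert len(lags) == 5  # -500, -250, 0, +250, +500 ms
        assert lags[2] == 0 and lags[0] < 0 < lags[-1]

    def test_overlapping_event_windows_add(self):
        """Two same-type events with overlapping windows: the raw indicator
        columns sum, verified against a hand-looped oracle."""
        times = [1.0, 1.2]
        streams = _streams(stim=(times, ["R", "R"]))
        dm = build_design_matrix(streams, KernelWindows(), 10.0, 40)
        for i, c in enumerate(dm.columns):
            if c["predictor"] != "stimulus":
                continue
            raw = np.zeros(40)
            for t in times:
                f = int(round(t * 10.0)) + c["lag_frames"]
                if 0 <= f < 40:
                    raw[f] += 1.0
            expected = (raw - raw.mean()) / raw.std()
            np.testing.assert_allclose(dm.X[:, i], expected, atol=1e-12)

    def test_event_outside_span_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(
                _streams(stim=([99.0], ["L"])), KernelWindows(), 10.0, 50
            )

    def test_empty_streams_warn_intercept_only(self):
        with pytest.warns(UserWarning):
            dm = build_design_matrix(_streams(), KernelWindows(), 10.0, 20)
        assert dm.X.shape == (20, 1)

    def test_columns_are_z_scored_with_intercept(self, rng):
        streams = _streams(
            stim=([1.0, 3.0], ["L", "R"]),
            continuous={"v": rng.normal(size=80)},
        )
        dm = build_design_matrix(streams, KernelWindows(), 10.0, 80)
        np.testing.assert_allclose(dm.X[:, 0], 1.0)
        np.testing.assert_allclose(dm.X[:, 1:].mean(axis=0), 0.0, atol=1e-10)
        sds = dm.X[:, 1:].std(axis=0)
        assert np.all((np.isclose(sds, 1.0)) | (sds == 0.0))


class TestRidgeSolve:
    def test_lambda_zero_equals_ols_closed_form(self, rng):
        X = np.column_stack([np.ones(4), [0.0, 1, 2, 3]])
        y = np.array([1.0, 2.0, 2.5, 4.0])
        w = ridge_solve(X, y, 0.0)
        w_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(w, w_ols, rtol=1e-12)

    def test_large_lambda_limit(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50) + 5.0
        w = ridge_solve(X, y, 1e12)
        np.testing.assert_allclose(w[1:], 0.0, atol=1e-6)
        assert w[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_duplicated_column_weights_equal(self, rng):
        z = rng.normal(size=60)
        X = np.column_stack([np.ones(60), z, z])
        y = rng.normal(size=60)
        w = ridge_solve(X, y, 0.5)
        assert w[1] == pytest.approx(w[2], rel=1e-10)

    def test_stationarity_condition(self, rng):
        """grad of the penalized objective vanishes at the solution:
        || X'(y - Xw) - lam * w ||  small on penalized coordinates."""
        X = np.column_stack([np.ones(100), rng.normal(size=(100, 6))])
        y = rng.normal(size=100)
        for lam in (0.01, 0.1, 1.0):
            w = ridge_solve(X, y, lam)
            grad = X.T @ (y - X @ w)
            grad[1:] -= lam * w[1:]
            assert np.linalg.norm(grad) < 1e-6 * np.linalg.norm(X.T @ y)

    def test_matches_sklearn_when_all_penalized(self, rng):
        X = rng.normal(size=(80, 5))
        y = rng.normal(size=80)
        lam = 0.7
        w = ridge_solve(X, y, lam, penalized=np.ones(5, bool))
        sk = Ridge(alpha=lam, fit_intercept=False).fit(X, y)
        np.testing.assert_allclose(w, sk.coef_, rtol=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ridge_solve(np.array([[1.0], [np.inf]]), np.array([1.0, 2.0]), 0.1)


class TestVarianceExplained:
    def test_examples(self):
        y = np.array([0.0, 1, 2, 3])
        assert variance_explained(y, y) == pytest.approx(100.0)
        assert variance_explained(y, np.full(4, y.mean())) == pytest.approx(0.0)
        assert variance_explained(y, np.array([0.0, 1, 2, 2])) == pytest.approx(80.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(5), np.zeros(5))


class TestRidgeEncodingCV:
    def test_noiseless_recovery(self, rng):
        X = np.column_stack([np.ones(220), rng.normal(size=(220, 4))])
        w_true = np.array([1.0, 2.0, -1.0, 0.5, 0.0])
        y = X @ w_true
        est = RidgeEncodingCV().fit(X, y)
        assert est.cv_variance_explained_ > 95.0

    def test_null_has_nonpositive_ve_on_average(self, rng):
        ves = []
        for _ in range(50):
            X = np.column_stack([np.ones(120), rng.normal(size=(120, 4))])
            y = rng.normal(size=120)
            ves.append(RidgeEncodingCV().fit(X, y).cv_variance_explained_)
        assert np.mean(ves) <= 0.0

    def test_chosen_lambda_in_grid_and_folds_partition(self, rng):
        X = np.column_stack([np.ones(130), rng.normal(size=(130, 3))])
        y = X @ np.array([0.5, 1.0, 0.0, -1.0]) + rng.normal(size=130)
        est = RidgeEncodingCV().fit(X, y)
        assert est.lambda_ in est.lambda_grid
        folds = est.fold_assignment_
        assert len(folds) == 130
        assert set(folds) == set(range(1, 12))
        # contiguous blocks: fold index is non-decreasing
        assert np.all(np.diff(folds) >= 0)

    def test_too_few_folds_rejected(self, rng):
        X = np.ones((30, 1))
        with pytest.raises(ValueError):
            RidgeEncodingCV(n_folds=1).fit(X, np.ones(30))


class TestKernelRecovery:
    def test_event_kernel_weights_correlate_with_generating_kernel(self):
        """At high SNR, fitted stimulus-kernel weights recover the shape of
        the generating response kernel (median weight correlation > 0.9
        over 20 seeds)."""
        from twotask2p.simulate import Kernel

        # generating kernels whose support fits inside the fitting windows,
        # so the indicator model is well-specified
        kernels = {
            "stimulus": Kernel(1.0, 0.15, 0.08),
            "choice": Kernel(0.8, 0.1, 0.07),
            "reward": Kernel(1.2, 0.12, 0.07),
        }
        cors = []
        for seed in range(20):
            cfg = SimConfig(
                n_neurons=6, session_minutes=3.0,
                fractions=(0.0, 1.0, 0.0, 0.0),
                baseline_scale=0.0, noise_scale=0.01, gain_sigma=0.1,
                kernel_library=kernels,
            )
            s = generate_session(cfg, seed=seed, conditions=("SW",))
            ev = s.events["SW"]
            streams = EventStreams(
                stimulus_onsets=ev["stimulus"], choice_times=ev["choice"],
                reward_times=ev["reward"], continuous={},
            )
            T = s.traces["SW"].shape[1]
            dm = build_design_matrix(streams, KernelWindows(), 10.0, T)
            fit = fit_ridge_cv(dm, s.traces["SW"][0])
            idx, lags = zip(*[
                (i, c["lag_frames"]) for i, c in enumerate(dm.columns)
                if c["predictor"] == "stimulus" and c["lag_frames"] >= 0
            ])
            w = fit.weights[list(idx)]
            k_true = cfg.kernel_library["stimulus"].sample(10.0)
            k = np.array([k_true[l] if l < len(k_true) else 0.0 for l in lags])
            cors.append(np.corrcoef(w, k)[0, 1])
        assert np.median(cors) > 0.9


class TestEncodingCrossTask:
    def test_identical_ve_unit_rho(self, rng):
        ve = rng.normal(size=30)
        rho, p, m1, m2 = encoding_cross_task(ve, ve.copy())
        assert rho == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        ve = np.array([7.9, 8.0, 8.1, 50.0, 8.0, 1.0, 9.0, 8.2, 0.0, 12.0])
        _, _, m1, _ = encoding_cross_task(ve, ve)
        np.testing.assert_array_equal(
            m1, ve > 8.0
        )

    def test_exclusive_populations_give_negative_rho(self):
        """Task-exclusive populations: VE is high in the preferred task and
        near zero in the other, so VE anti-correlates across tasks."""
        rhos = []
        for seed in range(20):
            cfg = SimConfig(
                n_neurons=14, session_minutes=2.0,
                fractions=(0.5, 0.5, 0.0, 0.0),
                baseline_scale=0.0, noise_scale=0.05,
            )
            s = generate_session(cfg, seed=seed, conditions=("TM", "SW"))
            ves = {}
            for task in ("TM", "SW"):
                ev = s.events[task]
                streams = EventStreams(
                    stimulus_onsets=ev["stimulus"], choice_times=ev["choice"],
                    reward_times=ev["reward"], continuous={},
                )
                T = s.traces[task].shape[1]
                dm = build_design_matrix(streams, KernelWindows(), 10.0, T)
                ves[task] = np.array([
                    fit_ridge_cv(dm, s.traces[task][i]).cv_variance_explained
                    for i in range(cfg.n_neurons)
                ])
            rho, _, _, _ = encoding_cross_task(ves["TM"], ves["SW"])
            rhos.append(rho)
        assert np.median(rhos) < 0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            encoding_cross_task(np.zeros(5), np.zeros(6))
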