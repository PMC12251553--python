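"""Soft-sensor pipeline tests: feature assembly against closed-form
derivatives, training determinism and skill, online correction on a
regime-shift fixture, and the cascade identity diagnostic."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fermsense.model import Trajectory
from fermsense.preprocessing import NormalizationStats
from fermsense.soft_sensor import (
    FEATURE_NAMES,
    SoftSensorRegressor,
    StatsMismatchError,
    build_features,
    cascade_identity_check,
    evaluate,
)
from fermsense.synthetic import make_fixture


def constant_trajectory(n=20, h=0.5):
    t = h * np.arange(n)
    states = np.tile([10.0, 5.0, 1.0, 50.0, 1e-6, 60.0], (n, 1))
    feeds = np.tile([0.05, 0.01, 0.02, 0.01], (n, 1))
    env = np.tile([30.0, 250.0, 60.0], (n, 1))
    return Trajectory(t=t, states=states, feeds=feeds, env=env)


def quiet_fit(model, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(X, y)


class TestBuildFeatures:
    def test_constant_inputs_give_zero_derivative_features(self):
        ds = build_features(constant_trajectory())
        assert list(ds.X.columns) == list(FEATURE_NAMES)
        np.testing.assert_allclose(ds.X[["x4_dot", "x4_ddot", "x5_dot"]].to_numpy(), 0.0, atol=1e-9)
        assert ds.X["x4"].nunique() == 1

    def test_row_count_matches_sample_times(self, noisefree_campaign):
        batch, _ = noisefree_campaign
        assert batch.dataset.X.shape == (len(batch.dataset.t), 13)

    def test_derivative_features_match_closed_form(self):
        """Exponential DO relaxation sampled at 0.5 h: five-point features
        track the analytic first and second derivatives."""
        K, C_star, C0 = 0.4, 100.0, 20.0
        t = 0.5 * np.arange(41)
        x4 = C_star - (C_star - C0) * np.exp(-K * t)
        traj = constant_trajectory(n=41, h=0.5)
        traj.states[:, 3] = x4
        ds = build_features(traj)
        d1 = K * (C_star - C0) * np.exp(-K * t)
        d2 = -K * d1
        assert np.max(np.abs(ds.X["x4_dot"].to_numpy() - d1) / np.abs(d1)) < 1e-3
        # interior rows use the central stencil; the two one-sided boundary
        # rows are one order less accurate in the second derivative
        rel2 = np.abs(ds.X["x4_ddot"].to_numpy() - d2) / np.abs(d2)
        assert np.max(rel2[2:-2]) < 1e-3
        assert np.max(rel2) < 0.1

    def test_optional_x6_derivative_feature(self):
        ds = build_features(constant_trajectory(), include_x6_dot=True)
        assert "x6_dot" in ds.X.columns and ds.X.shape[1] == 14

    def test_off_grid_sample_times_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            build_features(constant_trajectory(), sample_times=np.array([0.0, 0.3, 0.6, 0.9, 1.2]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            build_features(constant_trajectory(), sample_times=np.array([0.0, 0.5, 1.0]))


class TestSoftSensorRegressor:
    def test_refit_with_same_seed_is_identical(self, noisefree_campaign):
        batch, _ = noisefree_campaign
        ds = batch.dataset
        a = quiet_fit(SoftSensorRegressor(max_epochs=60, random_state=5), ds.X, ds.y)
        b = quiet_fit(SoftSensorRegressor(max_epochs=60, random_state=5), ds.X, ds.y)
        for na, nb in zip(a.networks_, b.networks_):
            for Wa, Wb in zip(na.weights, nb.weights):
                np.testing.assert_array_equal(Wa, Wb)

    def test_noise_free_training_mse_is_small(self, trained_noisefree):
        """Each target's final training loss in normalized units < 1e-3."""
        for hist in trained_noisefree.loss_histories_:
            assert hist[-1] < 1e-3

    def test_monotone_skill_over_permuted_targets(self, noisefree_campaign):
        """Trained test MSE beats the shuffled-target control for every
        target and seed (no-skill null)."""
        batch, _ = noisefree_campaign
        ds = batch.dataset
        n = len(ds)
        test_mask = np.arange(n) % 3 == 2
        Xtr, ytr = ds.X[~test_mask], ds.y[~test_mask]
        Xte, yte = ds.X[test_mask], ds.y[test_mask]
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(len(ytr))
            real = quiet_fit(SoftSensorRegressor(max_epochs=800, random_state=seed), Xtr, ytr)
            null = quiet_fit(SoftSensorRegressor(max_epochs=800, random_state=seed), Xtr, ytr[perm])
            for j in range(3):
                mse_real = np.mean((real.y_stats_.apply(real.predict(Xte))[:, j]
                                    - real.y_stats_.apply(yte)[:, j]) ** 2)
                mse_null = np.mean((null.y_stats_.apply(null.predict(Xte))[:, j]
                                    - null.y_stats_.apply(yte)[:, j]) ** 2)
                assert mse_real < mse_null

    def test_permuted_control_matches_target_variance_scale(self, noisefree_campaign):
        """The no-skill control's test MSE is on the order of the target
        variance (normalized units)."""
        batch, _ = noisefree_campaign
        ds = batch.dataset
        test_mask = np.arange(len(ds)) % 3 == 2
        perm = np.random.default_rng(0).permutation(int((~test_mask).sum()))
        null = quiet_fit(SoftSensorRegressor(max_epochs=800, random_state=0),
                         ds.X[~test_mask], ds.y[~test_mask][perm])
        yn = null.y_stats_.apply(ds.y[test_mask])
        pn = null.y_stats_.apply(null.predict(ds.X[test_mask]))
        mse = np.mean((pn - yn) ** 2)
        var = np.mean(yn.var(axis=0))
        assert 0.3 * var < mse < 10 * var

    def test_constant_targets_are_predicted(self):
        traj = constant_trajectory(n=30)
        rng = np.random.default_rng(0)
        traj.states[:, 3] += rng.normal(0, 0.5, 30)  # some feature variation
        ds = build_features(traj, targets=np.tile([7.0, 3.0, 1.5], (30, 1)))
        with pytest.warns(UserWarning, match="degenerate"):
            model = SoftSensorRegressor(max_epochs=300, random_state=0).fit(ds.X, ds.y)
        pred = model.predict(ds.X)
        np.testing.assert_allclose(pred, np.tile([7.0, 3.0, 1.5], (30, 1)), atol=0.2)

    def test_normalized_prediction_round_trip(self, trained_noisefree, noisefree_campaign):
        """Denormalizing the normalized-space prediction equals predict()."""
        batch, _ = noisefree_campaign
        X = batch.dataset.X
        direct = trained_noisefree.predict(X)
        xn = trained_noisefree.x_stats_.apply(X.values)
        via_norm = trained_noisefree.y_stats_.invert(
            trained_noisefree.predict_normalized(xn, trained_noisefree.stats_fingerprint())
        )
        np.testing.assert_allclose(direct, via_norm, rtol=1e-12)

    def test_stats_fingerprint_mismatch_refused(self, trained_noisefree):
        with pytest.raises(StatsMismatchError):
            trained_noisefree.predict_normalized(np.zeros((1, 13)), "deadbeef00000000")

    def test_feature_count_contract(self, trained_noisefree, noisefree_campaign):
        """A 13-input model refuses the 12-feature ablation (x4_ddot removed)."""
        batch, _ = noisefree_campaign
        ablated = batch.dataset.X.drop(columns=["x4_ddot"])
        assert ablated.shape[1] == 12
        with pytest.raises(ValueError, match="13"):
            trained_noisefree.predict(ablated)

    def test_normalization_stats_come_from_train_rows_only(self, noisefree_campaign):
        batch, _ = noisefree_campaign
        ds = batch.dataset
        n_train = 40
        model = quiet_fit(SoftSensorRegressor(max_epochs=30, random_state=0),
                          ds.X.iloc[:n_train], ds.y[:n_train])
        expected = NormalizationStats.fit(ds.X.values[:n_train])
        np.testing.assert_array_equal(model.x_stats_.offset, expected.offset)
        np.testing.assert_array_equal(model.x_stats_.scale, expected.scale)
        full = NormalizationStats.fit(ds.X.values)
        assert not np.array_equal(model.x_stats_.offset, full.offset)


class TestOnlineCorrection:
    def test_zero_epochs_is_identity(self, noisefree_campaign):
        batch, _ = noisefree_campaign
        ds = batch.dataset
        model = quiet_fit(SoftSensorRegressor(max_epochs=50, random_state=1), ds.X[:40], ds.y[:40])
        before = [W.copy() for W in model.networks_[0].weights]
        model.online_correct(ds.X[40:45], ds.y[40:45], epochs=0)
        for Wb, Wa in zip(before, model.networks_[0].weights):
            np.testing.assert_array_equal(Wb, Wa)

    def test_empty_update_warns_and_is_noop(self, noisefree_campaign):
        batch, _ = noisefree_campaign
        ds = batch.dataset
        model = quiet_fit(SoftSensorRegressor(max_epochs=30, random_state=1), ds.X[:40], ds.y[:40])
        with pytest.warns(UserWarning, match="no new samples"):
            model.online_correct(ds.X.iloc[:0], ds.y[:0], epochs=10)

    def test_training_row_loss_does_not_increase(self, noisefree_campaign):
        """Feeding back a sample the model has already seen keeps the fit on
        the training pool from degrading."""
        batch, _ = noisefree_campaign
        ds = batch.dataset
        model = quiet_fit(SoftSensorRegressor(max_epochs=1500, random_state=1), ds.X[:40], ds.y[:40])

        def pool_mse(m):
            yn = m.y_stats_.apply(ds.y[:40])
            pn = m.y_stats_.apply(m.predict(ds.X[:40]))
            return float(np.mean((pn - yn) ** 2))

        before = pool_mse(model)
        model.online_correct(ds.X.iloc[[10]], ds.y[[10]], epochs=20)
        assert pool_mse(model) <= before * 1.05 + 1e-9

    def test_adaptation_after_regime_shift(self):
        """A mid-campaign kinetic step degrades the offline model; correcting
        on the first post-shift assays improves the rest of the new regime."""
        batch = make_fixture("regime-shift", seed=0)
        ds = batch.dataset
        n = len(ds)
        pre = slice(0, n // 2)                  # old regime
        adapt = slice(n // 2, n // 2 + 5)       # first labeled samples after the shift
        hold = slice(n // 2 + 5, n)             # evaluation window in the new regime
        model = quiet_fit(SoftSensorRegressor(max_epochs=2000, random_state=0), ds.X[pre], ds.y[pre])

        def hold_mse(m):
            yn = m.y_stats_.apply(ds.y[hold])
            pn = m.y_stats_.apply(m.predict(ds.X[hold]))
            return float(np.mean((pn - yn) ** 2))

        before = hold_mse(model)
        model.online_correct(ds.X[adapt], ds.y[adapt], epochs=300, window=20)
        after = hold_mse(model)
        assert after < before


class TestEvaluate:
    def test_constant_predictor_mse_equals_target_variance(self, trained_noisefree, noisefree_campaign):
        """Forcing every network to output the mean normalized target turns
        the normalized MSE into the population variance."""
        import copy

        batch, _ = noisefree_campaign
        ds = batch.dataset
        model = copy.deepcopy(trained_noisefree)
        yn = model.y_stats_.apply(ds.y)
        for j, net in enumerate(model.networks_):
            for W in net.weights:
                W[:] = 0.0
            for b in net.biases:
                b[:] = 0.0
            net.biases[-1][0] = yn[:, j].mean()
        report = evaluate(model, ds)
        # splits were tagged by a previous evaluate call or default 70/30
        for tag, mse in (("train", report.mse_train), ("test", report.mse_test)):
            mask = ds.split == tag
            for j, name in enumerate(("x1", "x2", "x3")):
                var = np.mean((yn[mask, j] - yn[:, j].mean()) ** 2)
                assert mse[name] == pytest.approx(var, rel=1e-9)

    def test_relative_error_floor_flags_near_zero_targets(self, trained_noisefree, noisefree_campaign):
        batch, _ = noisefree_campaign
        ds = batch.dataset
        y = ds.y.copy()
        y[5, 2] = 0.0  # an assay at exactly zero
        ds2 = type(ds)(t=ds.t, X=ds.X, y=y, split=ds.split)
        report = evaluate(trained_noisefree, ds2)
        assert bool(report.rel_error["excluded_x3"].iloc[5])
        assert np.isnan(report.rel_error["rel_x3"].iloc[5])
        assert np.isfinite(report.medians["x3"])

    def test_prediction_curve_is_on_the_display_grid(self, trained_noisefree, noisefree_campaign):
        batch, _ = noisefree_campaign
        report = evaluate(trained_noisefree, batch.dataset, interp_minutes=30.0)
        dt = np.diff(report.pred_curve["t_h"].to_numpy())
        np.testing.assert_allclose(dt, 0.5)


class TestCascade:
    def test_trained_model_approximates_identity(self, trained_noisefree, noisefree_campaign):
        batch, _ = noisefree_campaign
        med = cascade_identity_check(trained_noisefree, batch.traj, batch.dataset.t)
        for name, val in med.items():
            assert val < 0.05, f"{name}: median relative error {val:.3f}"

    def test_untrained_model_deviates_much_more(self, trained_noisefree, noisefree_campaign):
        batch, _ = noisefree_campaign
        ds = batch.dataset
        barely = quiet_fit(SoftSensorRegressor(max_epochs=1, random_state=0), ds.X, ds.y)
        med_trained = cascade_identity_check(trained_noisefree, batch.traj, ds.t)
        med_raw = cascade_identity_check(barely, batch.traj, ds.t)
        for name in med_trained:
            assert med_raw[name] > 5 * med_trained[name]

    def test_short_horizon_rejected(self, trained_noisefree, noisefree_campaign):
        batch, _ = noisefree_campaign
        with pytest.raises(ValueError, match="stencil"):
            cascade_identity_check(trained_noisefree, batch.traj, batch.dataset.t[:3])
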