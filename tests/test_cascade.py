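"""Dataset splitting, stage regressors, and the chained cascade."""

import numpy as np
import pandas as pd
import pytest

import fishweigh as fw
from fishweigh.cascade import (CascadeWeightEstimator, NINE_CASE_LABELS,
                               RegressorSpec, SplitSpec, fit_regressor,
                               grid_search, load_cascade, nine_case_reports,
                               predict_cascade, save_cascade, split_dataset)
from fishweigh.synthetic import CameraModel, GrowthModel, make_file_dataset


class TestSplitDataset:
    @pytest.mark.parametrize("n, outer, inner, expected", [
        (2777, 0.7, 0.8, (1555, 389, 833)),   # regression-table partition
        (4287, 0.7, 0.7, (2101, 900, 1286)),  # detection-image partition
    ])
    def test_published_partition_sizes(self, n, outer, inner, expected):
        tr, va, te = split_dataset(n, SplitSpec(outer, inner))
        assert (len(tr), len(va), len(te)) == expected

    def test_degenerate_all_train(self):
        with pytest.warns(UserWarning, match="empty partition"):
            tr, va, te = split_dataset(10, SplitSpec(1.0, 1.0))
        assert (len(tr), len(va), len(te)) == (10, 0, 0)

    def test_disjoint_exhaustive_deterministic(self):
        s = SplitSpec(0.7, 0.8, seed=3)
        tr, va, te = split_dataset(1000, s)
        tr2, va2, te2 = split_dataset(1000, s)
        everything = np.concatenate([tr, va, te])
        assert sorted(everything) == list(range(1000))
        assert np.array_equal(tr, tr2) and np.array_equal(va, va2)
        assert np.array_equal(te, te2)

    def test_different_seed_different_shuffle(self):
        tr1, _, _ = split_dataset(500, SplitSpec(seed=0))
        tr2, _, _ = split_dataset(500, SplitSpec(seed=1))
        assert not np.array_equal(tr1, tr2)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(outer_train_frac=0.0)


class TestFitRegressor:
    def test_lr_recovers_exact_line(self):
        x = np.arange(10, dtype=float)[:, None]
        y = 1.0 + 2.0 * x.ravel()
        model = fit_regressor(RegressorSpec("LR"), x, y)
        assert model.intercept_ == pytest.approx(1.0)
        assert model.coef_[0] == pytest.approx(2.0)

    def test_lr_constant_targets(self):
        x = np.arange(8, dtype=float)[:, None]
        model = fit_regressor(RegressorSpec("LR"), x, np.full(8, 5.0))
        assert model.coef_[0] == pytest.approx(0.0, abs=1e-12)
        assert model.intercept_ == pytest.approx(5.0)

    def test_lr_matches_pseudoinverse_oracle(self, rng):
        """Least squares agrees with the explicit pinv solution to 1e-8."""
        for _ in range(5):
            X = rng.normal(size=(60, 4))
            beta = rng.normal(size=5)
            y = beta[0] + X @ beta[1:] + rng.normal(scale=0.1, size=60)
            model = fit_regressor(RegressorSpec("LR"), X, y)
            design = np.hstack([np.ones((60, 1)), X])
            oracle = np.linalg.pinv(design) @ y
            assert model.intercept_ == pytest.approx(oracle[0], abs=1e-8)
            np.testing.assert_allclose(model.coef_, oracle[1:], atol=1e-8)

    def test_rank_deficient_lr_warns(self):
        X = np.ones((10, 2))
        X[:, 1] = 2.0  # constant duplicate column
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_regressor(RegressorSpec("LR"), X, np.arange(10.0))

    def test_svr_pipeline_standardises_features(self):
        model = fit_regressor(RegressorSpec("SVR"),
                              np.arange(20.0)[:, None], np.arange(20.0))
        assert model.named_steps["scale"].mean_ is not None
        assert model.named_steps["svr"].kernel == "rbf"

    def test_rfr_depth_limited_and_seeded(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 0] * 2
        a = fit_regressor(RegressorSpec("RFR"), X, y, seed=7)
        b = fit_regressor(RegressorSpec("RFR"), X, y, seed=7)
        assert all(t.get_depth() <= 2 for t in a.estimators_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_regressor(RegressorSpec("LR"), [[1.0]], [1.0])
        with pytest.raises(ValueError, match="missing"):
            fit_regressor(RegressorSpec("LR"), [[1.0], [np.nan]], [1.0, 2.0])
        with pytest.raises(ValueError, match="family"):
            RegressorSpec("MLP")


class TestGridSearch:
    def _data(self):
        x = np.linspace(0, 10, 40)[:, None]
        y = 3.0 + 0.5 * x.ravel()
        return (x[:30], y[:30]), (x[30:], y[30:])

    def test_single_point_grid(self):
        train, val = self._data()
        spec = grid_search("SVR", {"C": [10.0]}, train, val)
        assert spec == RegressorSpec("SVR", {"C": 10.0})

    def test_generating_model_selected(self):
        # data has a true nonzero intercept: the spec fitting it wins
        train, val = self._data()
        spec = grid_search("LR", {"fit_intercept": [False, True]}, train, val)
        assert spec.params == {"fit_intercept": True}

    def test_tie_keeps_first_combination(self):
        train, val = self._data()
        # duplicated value: identical MAE, first in iteration order wins
        spec = grid_search("LR", {"fit_intercept": [True, True]}, train, val)
        assert spec == RegressorSpec("LR", {"fit_intercept": True})

    def test_empty_grid_rejected(self):
        train, val = self._data()
        with pytest.raises(ValueError, match="empty"):
            grid_search("LR", {}, train, val)


class TestCascade:
    def test_default_family_assignment(self, trained_cascade):
        assert trained_cascade.depth_spec_.family == "SVR"
        assert trained_cascade.size_spec_.family == "LR"
        assert trained_cascade.weight_spec_.family == "LR"

    def test_missing_column_named_in_error(self, default_table):
        with pytest.raises(KeyError, match="depth_label_cm"):
            CascadeWeightEstimator().fit(
                default_table.drop(columns=["depth_label_cm"]))

    def test_noiseless_depth_r2(self):
        """With pixel noise and quantisation off, depth is learnable from
        (age, pixel dims) to high accuracy."""
        camera = CameraModel(marker_spacing_cm=None)
        table = make_file_dataset(800, camera=camera, seed=5,
                                  pixel_noise_sd=0.0)
        with pytest.warns(UserWarning):
            model = fw.train_cascade(table, seed=0)
        report = fw.evaluate_cascade(model, table)
        assert report["depth"].r2 >= 0.95

    def test_tiny_table_warns_but_trains(self):
        table = make_file_dataset(8, seed=1)
        with pytest.warns(UserWarning):
            model = fw.train_cascade(table, split=SplitSpec(1.0, 1.0), seed=0)
        assert np.isfinite(model.predict(table)).all()

    def test_residual_summaries_deterministic(self, default_table):
        with pytest.warns(UserWarning):
            a = fw.train_cascade(default_table, seed=0)
            b = fw.train_cascade(default_table, seed=0)
        assert a.residual_summaries_ == b.residual_summaries_
        assert set(a.residual_summaries_) == {"depth", "length_cm",
                                              "width_cm", "weight"}

    def test_predict_empty_stream(self, trained_cascade):
        out = predict_cascade([], trained_cascade)
        assert len(out) == 0
        assert list(out.columns) == ["depth_cm", "length_cm", "width_cm",
                                     "weight_g"]

    def test_identical_observations_identical_predictions(self, trained_cascade):
        obs = [(24, 600.0, 230.0), (24, 600.0, 230.0)]
        out = predict_cascade(obs, trained_cascade)
        assert out.iloc[0].equals(out.iloc[1])

    def test_stages_chain_forward(self, trained_cascade):
        """The weight stage must consume predicted depth and cm dims, not
        annotations: feeding the depth model's output through by hand
        reproduces predict_stages exactly."""
        A = np.array([[24.0, 700.0, 260.0], [22.0, 420.0, 160.0]])
        stages = trained_cascade.predict_stages(A)
        depth = trained_cascade.depth_model_.predict(A)
        np.testing.assert_allclose(stages["depth_cm"], depth)
        size_in = np.column_stack([A, depth])
        np.testing.assert_allclose(
            stages["length_cm"], trained_cascade.length_model_.predict(size_in))

    def test_noiseless_parameter_recovery_within_10pct(self, noiseless_setup,
                                                       noiseless_cascade):
        _, _, table = noiseless_setup
        test = table.iloc[noiseless_cascade.split_indices_[2]]
        pred = noiseless_cascade.predict(test)
        rel = np.abs(pred - test.weight_g.to_numpy()) / test.weight_g.to_numpy()
        assert rel.max() <= 0.10

    def test_larger_fish_never_predicted_lighter(self, trained_cascade):
        """Scaling a fish's pixel AND centimetre dimensions up at fixed age
        and depth never decreases the default LR weight stage's output."""
        base = np.array([24.0, 600.0, 228.0, 35.0, 24.0, 9.12])
        weights = []
        for scale in np.linspace(1.0, 1.4, 9):
            row = base.copy()
            row[[1, 2, 4, 5]] *= scale
            weights.append(trained_cascade.weight_model_.predict(row[None, :])[0])
        assert all(b >= a for a, b in zip(weights, weights[1:]))

    def test_untrained_predict_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            CascadeWeightEstimator().predict(np.zeros((1, 3)))

    def test_sklearn_params_round_trip(self):
        est = CascadeWeightEstimator(seed=5)
        params = est.get_params()
        assert params["seed"] == 5
        est.set_params(seed=9)
        assert est.seed == 9


class TestNineCases:
    def test_all_labels_reported(self, default_table):
        with pytest.warns(UserWarning):
            reports = nine_case_reports(default_table, seed=0)
        assert tuple(reports) == NINE_CASE_LABELS
        for report in reports.values():
            assert report.mae > 0 and np.isfinite(report.r2)


class TestPersistence:
    def test_round_trip_bit_exact(self, trained_cascade, tmp_path):
        path = tmp_path / "cascade.bin"
        save_cascade(trained_cascade, path)
        loaded = load_cascade(path)
        A = np.array([[24.0, 650.0, 250.0], [20.0, 380.0, 150.0]])
        np.testing.assert_array_equal(loaded.predict(A),
                                      trained_cascade.predict(A))
        assert loaded.residual_summaries_ == trained_cascade.residual_summaries_

    def test_version_checked(self, trained_cascade, tmp_path):
        import joblib
        path = tmp_path / "bad.bin"
        joblib.dump({"format_version": 99, "estimator": None}, path)
        with pytest.raises(ValueError, match="version"):
            load_cascade(path)
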