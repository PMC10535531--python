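"""Retrieval: transforms, training, prediction, evaluation protocol."""

import numpy as np
import pytest
from sklearn.model_selection import KFold, train_test_split

import cyanospec as cs
from cyanospec.metrics import r_squared
from cyanospec.retrieval import load_model, save_model

FAST = cs.TrainConfig(max_epochs=25, early_stop_patience=5)


class TestMakeFeatures:
    def test_car_target_untransformed(self, small_rrs_dataset, full_config):
        _, y, t = cs.make_features(small_rrs_dataset, "car", full_config)
        labels = np.array([r.labels.car for r in small_rrs_dataset.records])
        assert t.target_log is False
        assert np.array_equal(y, labels)

    def test_pigment_target_is_log10(self, small_rrs_dataset, full_config):
        _, y, t = cs.make_features(small_rrs_dataset, "chl_a", full_config)
        labels = np.array([r.labels.chl_a for r in small_rrs_dataset.records])
        assert t.target_log is True
        assert np.allclose(y, np.log10(labels))
        assert t.transform_target(np.array([100.0]))[0] == pytest.approx(2.0)

    def test_training_columns_standardized(self, small_rrs_dataset, full_config):
        n = len(small_rrs_dataset.records)
        train_idx = np.arange(0, n, 2)
        X, _, _ = cs.make_features(small_rrs_dataset, "chl_a", full_config,
                                   train_idx=train_idx)
        cols = X[train_idx]
        assert np.max(np.abs(cols.mean(axis=0))) <= 1e-9
        assert np.max(np.abs(cols.var(axis=0) - 1.0)) <= 1e-6

    def test_unknown_product_rejected(self, small_rrs_dataset, full_config):
        with pytest.raises(ValueError, match="product"):
            cs.make_features(small_rrs_dataset, "turbidity", full_config)

    def test_mixed_data_types_rejected(self, full_config):
        ds = cs.generate_dataset(3, seed=0)
        with pytest.raises(ValueError, match="data types"):
            cs.make_features(ds, "chl_a", full_config)


def _toy_linear(n=2000, n_features=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    return X, 3.0 * X[:, 0]


class TestTrainPredict:
    def test_architecture(self):
        X, y = _toy_linear(300)
        model = cs.train_model(X, y, FAST, seed=0)
        assert model.hidden_layer_sizes == (100,) * 5

    def test_seeded_determinism(self):
        X, y = _toy_linear(500)
        a = cs.train_model(X, y, FAST, seed=4)
        b = cs.train_model(X, y, FAST, seed=4)
        assert abs(a.net.best_validation_mae_ - b.net.best_validation_mae_) <= 1e-7

    def test_learns_noiseless_linear_map(self):
        X, y = _toy_linear(2000)
        model = cs.train_model(X[:1600], y[:1600], cs.TrainConfig(), seed=0)
        assert r_squared(y[1600:], model.predict(X[1600:])) >= 0.99

    def test_transform_inverse_round_trip(self):
        t = cs.TransformRecord(input_log=True, input_means=np.zeros(3),
                               input_scales=np.ones(3), target_log=True)
        y = np.array([0.5, 10.0, 4321.0])
        assert np.allclose(t.inverse_target(t.transform_target(y)), y,
                           rtol=1e-9)

    def test_pigment_predictions_positive(self, small_rrs_dataset, full_config):
        X, y, t = cs.make_features(small_rrs_dataset, "chl_a", full_config)
        model = cs.train_model(X, y, FAST, seed=1, transform=t, product="chl_a")
        assert np.all(cs.predict(model, X) > 0.0)

    def test_feature_count_mismatch_rejected(self):
        X, y = _toy_linear(300)
        model = cs.train_model(X, y, FAST, seed=0)
        with pytest.raises(ValueError, match="feature count"):
            cs.predict(model, np.zeros((5, 7)))

    def test_too_few_rows_rejected(self):
        X, y = _toy_linear(50)
        with pytest.raises(ValueError, match="100"):
            cs.train_model(X, y, FAST, seed=0)

    def test_nonfinite_features_rejected(self):
        X, y = _toy_linear(300)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cs.train_model(X, y, FAST, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_linear(300)
        model = cs.train_model(X, y, FAST, seed=0, product="car")
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert np.allclose(back.net.predict(X), model.net.predict(X))
        assert back.product == "car"


@pytest.fixture(scope="module")
def dataset(grid):
    import dataclasses
    gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
    return cs.generate_dataset(600, seed=9, config=gen, grid=grid)


class TestEvaluate:

    def test_holdout_protocol(self, dataset, full_config):
        res = cs.evaluate(dataset, "chl_a", full_config, FAST, seed=0,
                          run_cv=False)
        assert res.report.held_out_only
        assert res.report.n_test == 120  # 20% of 600
        # metrics computed on held-out rows only: test rows disjoint from train
        train_idx, test_idx = train_test_split(np.arange(600), test_size=0.2,
                                               random_state=0)
        assert set(res.test_idx) == set(test_idx)

    def test_cv_folds_partition_training_split(self, dataset, full_config):
        res = cs.evaluate(dataset, "chl_a", full_config, FAST, seed=0,
                          run_cv=True, cv_folds=5)
        assert set(res.report.cv_fold_means) == {"r2", "mape_percent", "rmsele"}
        # the folds partition the 80% training split (each record in exactly
        # one test fold), mirroring the evaluation protocol
        train_idx, _ = train_test_split(np.arange(600), test_size=0.2,
                                        random_state=0)
        seen = []
        for _, te in KFold(5, shuffle=True, random_state=0).split(train_idx):
            seen.extend(train_idx[te])
        assert sorted(seen) == sorted(train_idx)

    def test_too_small_dataset_rejected(self, grid, full_config):
        import dataclasses
        gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
        ds = cs.generate_dataset(100, seed=1, config=gen, grid=grid)
        with pytest.raises(ValueError, match="500"):
            cs.evaluate(ds, "chl_a", full_config, FAST)

    def test_feature_count_agnostic(self, dataset, grid):
        # identical pipeline for 3, 9 or 100 input channels
        for centers in (np.array([548.0, 626.0, 680.0]),
                        np.linspace(510.0, 770.0, 9)):
            bc = cs.srf_matrix(centers, 12.0, grid)
            res = cs.evaluate(dataset, "chl_a", bc, FAST, seed=0, run_cv=False)
            assert np.isfinite(res.report.r2)


class TestEmulatedRecovery:
    """Parameter recovery on the emulated study (shared session fixture)."""

    def test_chl_log_recovery(self, emulated_run):
        assert emulated_run["chl_a"]["reports"]["Full"].r2 >= 0.9

    def test_car_recovery(self, emulated_run):
        assert emulated_run["car"]["reports"]["Full"].r2 >= 0.7

    def test_config_ordering(self, emulated_run):
        for product in cs.PRODUCTS:
            rep = emulated_run[product]["reports"]
            assert rep["Full"].r2 >= rep["P1"].r2 - 0.05
            assert rep["P2"].r2 <= rep["P1"].r2
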