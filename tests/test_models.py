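"""Regressors, standardization hygiene, grid search, persistence."""

import numpy as np
import pandas as pd
import pytest

from gripsense.errors import UsageError
from gripsense.features import KEY_COLUMNS, TARGET_COLUMN
from gripsense.models import (
    ALGORITHMS,
    ModelConfig,
    default_config,
    fit,
    grid_search,
    load_model,
    predict,
    save_model,
)


def make_frame(X, y):
    X = np.asarray(X, float)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "participant_id", "P01")
    df.insert(1, "day", 1)
    df.insert(2, "set_index", 1)
    df[TARGET_COLUMN] = np.asarray(y, float)
    return df


@pytest.fixture(scope="module")
def regression_frame():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((60, 4))
    y = 30 + 3 * X[:, 0] - 2 * X[:, 1] + 0.1 * rng.standard_normal(60)
    return make_frame(X, y)


class TestConfiguredDefaults:
    def test_fixed_hyperparameter_defaults(self):
        rf = fit(default_config("random_forest"),
                 make_frame(np.random.default_rng(0).normal(size=(12, 3)),
                            np.arange(12) + 20.0))
        params = rf.pipeline.named_steps["regressor"].get_params()
        assert params["n_estimators"] == 200
        assert params["max_depth"] == 20
        assert params["max_features"] == "sqrt"
        assert params["random_state"] == 42

        svr = default_config("svr_rbf").effective_hyperparameters()
        assert svr["kernel"] == "rbf" and svr["C"] == 100.0 and \
            svr["gamma"] == "scale"
        gb = default_config("gradient_boosting").effective_hyperparameters()
        assert (gb["n_estimators"], gb["learning_rate"], gb["max_depth"]) == \
            (100, 0.1, 5)
        knn = default_config("knn").effective_hyperparameters()
        assert (knn["n_neighbors"], knn["weights"], knn["metric"]) == \
            (9, "distance", "manhattan")

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(UsageError):
            ModelConfig("deep_net")


class TestFitPredict:
    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_refit_reproducibility(self, alg, regression_frame):
        m1 = fit(default_config(alg), regression_frame)
        m2 = fit(default_config(alg), regression_frame)
        probe = regression_frame.iloc[:10]
        np.testing.assert_array_equal(predict(m1, probe), predict(m2, probe))

    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_constant_target_predicted(self, alg):
        rng = np.random.default_rng(3)
        df = make_frame(rng.standard_normal((20, 3)), np.full(20, 27.5))
        model = fit(default_config(alg), df)
        np.testing.assert_allclose(predict(model, df), 27.5, atol=1e-6)

    def test_standardizer_fits_training_columns(self, regression_frame):
        model = fit(default_config("svr_rbf"), regression_frame)
        scaler = model.pipeline.named_steps["scaler"]
        names = [f"f{i}" for i in range(4)]
        X = regression_frame[names].to_numpy(float)
        Xs = scaler.transform(X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_scaled_by_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        X[:, 2] = 5.0
        df = make_frame(X, 30 + X[:, 0])
        with pytest.warns(UserWarning, match="constant"):
            model = fit(default_config("knn"), df)
        scaler = model.pipeline.named_steps["scaler"]
        assert scaler.scale_[2] == pytest.approx(1.0)

    def test_schema_mismatch_refused(self, regression_frame):
        model = fit(default_config("knn"), regression_frame)
        other = regression_frame.rename(columns={"f0": "g0"})
        with pytest.raises(UsageError, match="schema"):
            predict(model, other)

    def test_no_leakage_from_held_out_targets(self, regression_frame):
        train = regression_frame.iloc[:40]
        test = regression_frame.iloc[40:].copy()
        model = fit(default_config("svr_rbf"), train)
        before = predict(model, test)
        test[TARGET_COLUMN] = 999.0  # corrupting held-out targets is invisible
        model2 = fit(default_config("svr_rbf"), train)
        after = predict(model2, test)
        np.testing.assert_array_equal(before, after)

    @pytest.mark.parametrize("alg", ["svr_rbf", "knn"])
    def test_affine_feature_rescaling_absorbed_by_scaler(self, alg,
                                                         regression_frame):
        model = fit(default_config(alg), regression_frame)
        probe = regression_frame.iloc[:15]
        base = predict(model, probe)
        scaled = regression_frame.copy()
        scaled["f1"] = scaled["f1"] * 37.0 - 4.0
        probe2 = scaled.iloc[:15]
        model2 = fit(default_config(alg), scaled)
        np.testing.assert_allclose(predict(model2, probe2), base, rtol=1e-9)


class TestKnnAgainstBruteForce:
    def test_distance_weighted_manhattan_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_train = int(rng.integers(10, 30))
            dim = int(rng.integers(2, 5))
            X = rng.uniform(-2, 2, size=(n_train, dim))
            y = rng.uniform(10, 50, size=n_train)
            q = rng.uniform(-2, 2, size=(5, dim))
            train = make_frame(X, y)
            model = fit(default_config("knn"), train)
            got = predict(model, make_frame(q, np.zeros(5)))
            scaler = model.pipeline.named_steps["scaler"]
            Xs = scaler.transform(X)
            qs = scaler.transform(q)
            for i in range(5):
                d = np.abs(Xs - qs[i]).sum(axis=1)
                order = np.argsort(d)[:9]
                wgt = 1.0 / d[order]
                expect = float(np.sum(wgt * y[order]) / np.sum(wgt))
                assert got[i] == pytest.approx(expect, abs=1e-9)


class TestGridSearch:
    def test_singleton_grid_returned(self, regression_frame):
        cfg = grid_search("knn", {"n_neighbors": [5]}, regression_frame, folds=3)
        assert cfg.hyperparameters == {"n_neighbors": 5}

    def test_selects_minimum_of_exhaustive_score_table(self, regression_frame):
        from itertools import product
        from sklearn.model_selection import KFold
        from gripsense.evaluation import metrics

        grid = {"n_neighbors": [3, 9, 25], "weights": ["distance"]}
        chosen = grid_search("knn", grid, regression_frame, folds=3)

        # independent exhaustive table with the same fold plan
        scores = {}
        kf = KFold(n_splits=3, shuffle=True, random_state=42)
        for k, w in product(grid["n_neighbors"], grid["weights"]):
            cfg = ModelConfig("knn", {"n_neighbors": k, "weights": w})
            mapes = []
            for tr, te in kf.split(np.arange(len(regression_frame))):
                m = fit(cfg, regression_frame.iloc[tr])
                pred = predict(m, regression_frame.iloc[te])
                mapes.append(metrics(
                    regression_frame.iloc[te][TARGET_COLUMN].to_numpy(),
                    pred)[1])
            scores[k] = np.mean(mapes)
        best_k = min(scores, key=lambda k: scores[k])
        assert chosen.hyperparameters["n_neighbors"] == best_k

    def test_deterministic_selection(self, regression_frame):
        grid = {"n_neighbors": [3, 9], "weights": ["distance", "uniform"]}
        a = grid_search("knn", grid, regression_frame, folds=3)
        b = grid_search("knn", grid, regression_frame, folds=3)
        assert a.hyperparameters == b.hyperparameters

    def test_empty_grid_rejected(self, regression_frame):
        with pytest.raises(UsageError):
            grid_search("knn", {}, regression_frame)


class TestPersistence:
    def test_save_load_round_trip(self, regression_frame, tmp_path):
        model = fit(default_config("gradient_boosting"), regression_frame)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        probe = regression_frame.iloc[:8]
        np.testing.assert_array_equal(predict(back, probe),
                                      predict(model, probe))
        assert back.schema_hash == model.schema_hash

    def test_version_mismatch_refused(self, regression_frame, tmp_path):
        import joblib
        model = fit(default_config("knn"), regression_frame)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        obj = joblib.load(path)
        obj["archive_version"] = 99
        joblib.dump(obj, path)
        with pytest.raises(UsageError, match="version"):
            load_model(path)
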