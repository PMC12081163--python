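import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

from mmdepth.depth import (
    DepthSweepDataset,
    MODEL_FEATURES,
    load_model,
    pcc,
    r2_score,
    rds,
    rmse,
    save_model,
    screen,
    train_model,
    uri,
)

DEPTHS = np.arange(2.0, 21.0, 2.0)


def _linear_dataset(noise=0.0, seed=0, n_per_depth=30, extra=None):
    rng = np.random.default_rng(seed)
    rows = []
    for d in DEPTHS:
        for _ in range(n_per_depth):
            rec = {"depth": d, "x": d / 20.0 + noise * rng.standard_normal()}
            if extra:
                rec.update({k: f(d, rng) for k, f in extra.items()})
            rows.append(rec)
    return DepthSweepDataset(pd.DataFrame(rows), depth_grid=DEPTHS)


class TestMetrics:
    def test_worked_residual_example(self):
        y, yhat = [1, 2, 3], [2, 2, 2]
        assert r2_score(y, yhat) == pytest.approx(0.0)
        assert rmse(y, yhat) == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_perfect_prediction(self):
        assert r2_score([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert rmse([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_against_sklearn_on_random_residuals(self, rng):
        for _ in range(10):
            y = rng.normal(10, 3, 50)
            yhat = y + rng.normal(0, 1, 50)
            assert r2_score(y, yhat) == pytest.approx(
                sklearn.metrics.r2_score(y, yhat), abs=1e-12
            )
            assert rmse(y, yhat) == pytest.approx(
                np.sqrt(sklearn.metrics.mean_squared_error(y, yhat)), abs=1e-12
            )


class TestPCC:
    def test_perfect_linear(self):
        assert pcc(DEPTHS / 20.0, DEPTHS) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pcc(-DEPTHS, DEPTHS) == pytest.approx(-1.0)

    def test_symmetric_parabola_uncorrelated(self):
        # (d - 11)^2 is symmetric about the grid mean: exactly zero PCC
        assert pcc((DEPTHS - 11.0) ** 2, DEPTHS) == pytest.approx(0.0, abs=1e-12)

    def test_uses_per_depth_means(self):
        vals = np.concatenate([DEPTHS + 5.0, DEPTHS - 5.0])
        deps = np.concatenate([DEPTHS, DEPTHS])
        assert pcc(vals, deps) == pytest.approx(1.0)

    def test_zero_variance_sentinel(self):
        assert np.isnan(pcc(np.ones_like(DEPTHS), DEPTHS))

    def test_too_few_depths(self):
        with pytest.raises(ValueError):
            pcc([1.0, 2.0], [2.0, 4.0])


class TestURI:
    def test_linear_response_crosses_at_18(self):
        res = uri(DEPTHS / 20.0, DEPTHS)
        assert res.width == pytest.approx(16.0)
        assert not res.flagged

    def test_step_response(self):
        v = np.array([0.0] + [1.0] * 9)
        res = uri(v, DEPTHS)
        assert res.width == pytest.approx(2.0)

    def test_constant_flagged_zero(self):
        res = uri(np.ones(10), DEPTHS)
        assert res.width == 0.0 and res.flagged

    def test_never_reached_returns_full_width_flagged(self):
        # range is set by an interior excursion never matched relative to d_first
        v = np.array([0.5, 1.0, 0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        res = uri(v, DEPTHS)
        assert res.width == pytest.approx(18.0) and res.flagged

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            uri([1.0, 2.0], [4.0, 2.0])


class TestRDS:
    def test_rank_scaling(self):
        stds = pd.DataFrame({"a": [0.0], "b": [0.5], "c": [1.0]})
        out = rds(stds)
        assert out["a"] == 1.0 and out["b"] == 0.5 and out["c"] == 0.0

    def test_ties_share_best_rank(self):
        stds = pd.DataFrame({"a": [0.3], "b": [0.3], "c": [0.3]})
        assert (rds(stds) == 1.0).all()

    def test_zero_variance_parameter_most_stable(self):
        stds = pd.DataFrame({"a": [0.0, 0.0], "b": [0.2, 0.3]})
        out = rds(stds)
        assert out["a"] == 1.0 and out["b"] == 0.0

    def test_single_parameter_rejected(self):
        with pytest.raises(ValueError):
            rds(pd.DataFrame({"a": [0.1]}))


class TestScreen:
    def test_identical_parameters_identical_rows(self):
        ds = _linear_dataset(extra={"y": lambda d, rng: d / 20.0})
        tbl = screen(ds, parameters=["x", "y"])
        assert np.allclose(tbl.stats.loc["x"].drop("URI_flagged").astype(float),
                           tbl.stats.loc["y"].drop("URI_flagged").astype(float))
        assert tbl.stats.loc["x", "PCC"] == pytest.approx(1.0)
        assert tbl.stats.loc["x", "URI"] == pytest.approx(16.0)

    def test_single_depth_rejected(self):
        df = pd.DataFrame({"depth": [2.0] * 5, "x": np.arange(5.0)})
        ds = DepthSweepDataset(df, depth_grid=[2.0])
        with pytest.raises(ValueError):
            screen(ds)

    def test_noisier_parameter_ranks_lower(self):
        ds = _linear_dataset(
            extra={
                "clean": lambda d, rng: d / 20.0,
                "noisy": lambda d, rng: d / 20.0 + 0.3 * rng.standard_normal(),
            }
        )
        tbl = screen(ds, parameters=["clean", "noisy"])
        assert tbl.stats.loc["clean", "RDS"] > tbl.stats.loc["noisy", "RDS"]


class TestTrainModel:
    def test_noiseless_linear_feature_near_interpolation(self):
        ds = _linear_dataset(noise=1e-4)
        m = train_model(ds, ["x"], algorithm="PR", seed=0)
        assert m.cv_r2 > 0.999
        assert m.cv_rmse < 0.05

    def test_determinism(self):
        ds = _linear_dataset(noise=0.02)
        m1 = train_model(ds, ["x"], algorithm="SVR", seed=3)
        m2 = train_model(ds, ["x"], algorithm="SVR", seed=3)
        assert m1.cv_rmse == m2.cv_rmse
        X = np.linspace(0, 1, 7)[:, None]
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_unknown_algorithm_and_empty_features(self):
        ds = _linear_dataset()
        with pytest.raises(ValueError):
            train_model(ds, ["x"], algorithm="GBM")
        with pytest.raises(ValueError):
            train_model(ds, [])
        with pytest.raises(ValueError):
            train_model(ds, "Mz")

    def test_flagged_records_guard(self):
        df = _linear_dataset().table
        df["flag"] = True
        df.loc[: len(df) // 2, "flag"] = False
        ds = DepthSweepDataset(df, depth_grid=DEPTHS)
        with pytest.raises(ValueError, match="80%"):
            train_model(ds, ["x"])

    def test_per_depth_mae_table(self):
        ds = _linear_dataset(noise=0.01)
        m = train_model(ds, ["x"], algorithm="KNN", seed=1)
        assert set(m.mae_by_depth.index) == set(DEPTHS)
        assert (m.mae_by_depth >= 0).all()

    def test_model_presets_exist(self):
        assert set(MODEL_FEATURES) == {"Mp", "MA", "MD", "MM"}


class TestPersistence:
    def test_pr_model_json_round_trip(self, tmp_path):
        ds = _linear_dataset(noise=0.01)
        m = train_model(ds, ["x"], algorithm="PR", seed=0)
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        X = np.linspace(0.0, 1.0, 9)[:, None]
        assert np.allclose(back.predict(X), m.predict(X), atol=1e-9)
        assert back.cv_rmse == pytest.approx(m.cv_rmse)

    def test_knn_model_sidecar_round_trip(self, tmp_path):
        ds = _linear_dataset(noise=0.01)
        m = train_model(ds, ["x"], algorithm="KNN", seed=0)
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        X = np.linspace(0.0, 1.0, 9)[:, None]
        assert np.allclose(back.predict(X), m.predict(X))


def test_dataset_requires_depths_on_grid():
    df = pd.DataFrame({"depth": [2.0, 3.0], "x": [0.1, 0.2]})
    with pytest.raises(ValueError):
        DepthSweepDataset(df, depth_grid=[2.0, 4.0])
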