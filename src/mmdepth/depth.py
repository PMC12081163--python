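"""Screening statistics, depth-regression models and 2-D depth mapping.

Candidate parameters are screened over a depth sweep with three
statistics: the Pearson correlation of the per-depth mean response with
depth (PCC), the unsaturated response interval (URI, the depth span over
which the response reaches 80% of its total change), and the rank of data
stability (RDS, a rank-scaled inverse of the accumulated per-depth
standard deviation).  Screened features feed shallow regression models
(support-vector regression, k-nearest neighbours, polynomial regression)
evaluated by five-fold cross-validation with

    R^2  = 1 - SS_res / SS_tot
    RMSE = sqrt( mean (y_i - yhat_i)^2 )

and per-depth mean absolute error.  A fitted model applied cell-wise to a
Mueller image yields a depth map with per-zone mean and MAE statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR

from .features import features_from_image

__all__ = [
    "DepthSweepDataset",
    "ScreeningTable",
    "DepthModel",
    "DepthMap",
    "MODEL_FEATURES",
    "r2_score",
    "rmse",
    "pcc",
    "uri",
    "rds",
    "screen",
    "train_model",
    "predict_depth_map",
]

#: feature groups of the named models: Mp uses DOP-sensitive PBPs, MA
#: anisotropy-sensitive PBPs, MD the composite DSPFPs, MM the raw m44
#: element alone.
MODEL_FEATURES = {
    "Mp": ["Delta", "V", "gpse_c"],
    "MA": ["Ddag", "RA", "t1"],
    "MD": ["Ct", "CtD", "RVD"],
    "MM": ["m44"],
}


@dataclass
class DepthSweepDataset:
    """Feature records labelled with the true layer depth (mm)."""

    table: pd.DataFrame
    depth_grid: np.ndarray
    repeats: int = 1

    def __post_init__(self) -> None:
        if "depth" not in self.table.columns:
            raise ValueError("dataset table must carry a 'depth' column (mm)")
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        on_grid = np.isin(self.table["depth"].to_numpy(), self.depth_grid)
        if not on_grid.all():
            raise ValueError("every record must have a depth label on the grid")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# statistics


def r2_score(y, yhat) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - ss_res / ss_tot)


def rmse(y, yhat) -> float:
    """Root mean squared error of the residuals."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pcc(values, depths) -> float:
    """Pearson correlation of the per-depth mean response with depth.

    The response is first collapsed to one mean per depth (raw-point
    correlation is available by passing already-collapsed series).
    Returns NaN when either collapsed series has zero variance.
    """
    df = pd.DataFrame({"v": np.asarray(values, dtype=float), "d": np.asarray(depths, dtype=float)})
    if df["d"].nunique() < 3:
        raise ValueError("PCC needs responses at >= 3 distinct depths")
    means = df.groupby("d")["v"].mean()
    d = means.index.to_numpy()
    v = means.to_numpy()
    if np.std(v) == 0 or np.std(d) == 0:
        return np.nan
    return float(np.corrcoef(v, d)[0, 1])


class URIResult(NamedTuple):
    width: float
    flagged: bool


def uri(mean_response, depth_grid) -> URIResult:
    """Unsaturated response interval of a per-depth mean response.

    The total range is max - min of the means; the URI is the width from
    the first depth to the first grid depth ``d*`` at which
    ``|mean(d*) - mean(d_first)| >= 0.8 * range``.  A constant response
    yields width 0 (flagged); if the threshold is never crossed the full
    width is returned, flagged.
    """
    v = np.asarray(mean_response, dtype=float)
    d = np.asarray(depth_grid, dtype=float)
    if len(v) != len(d) or len(d) < 2:
        raise ValueError("need >= 2 depths with matching mean responses")
    if np.any(np.diff(d) <= 0):
        raise ValueError("depth grid must be sorted ascending")
    total = v.max() - v.min()
    if total == 0:
        return URIResult(0.0, True)
    change = np.abs(v - v[0])
    crossed = np.nonzero(change >= 0.8 * total)[0]
    if len(crossed) == 0:
        return URIResult(float(d[-1] - d[0]), True)
    return URIResult(float(d[crossed[0]] - d[0]), False)


def rds(per_depth_std: pd.DataFrame) -> pd.Series:
    """Rank of data stability from per-depth standard deviations.

    ``per_depth_std`` holds one column per parameter (already on a shared
    normalized scale) and one row per depth.  Standard deviations are
    accumulated over depths, parameters ranked ascending by the total,
    and the rank rescaled so the most stable parameter scores 1 and the
    least stable 0.  Tied totals share the best rank.
    """
    if per_depth_std.shape[1] < 2:
        raise ValueError("RDS needs >= 2 parameters to rank")
    totals = per_depth_std.sum(axis=0)
    ranks = totals.rank(method="min", ascending=True)
    n = len(totals)
    return 1.0 - (ranks - 1.0) / (n - 1.0)


def _minmax_to_pm1(x: pd.Series) -> pd.Series:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return x * 0.0
    return 2.0 * (x - lo) / (hi - lo) - 1.0


@dataclass
class ScreeningTable:
    """Per-parameter screening statistics plus normalized mean responses."""

    stats: pd.DataFrame          # index: parameter; columns: PCC, URI, URI_flagged, RDS
    responses: pd.DataFrame      # index: depth; columns: parameter (normalized means)


def screen(dataset: DepthSweepDataset, parameters: Sequence[str] | None = None) -> ScreeningTable:
    """Compute PCC, URI and RDS for every parameter over the depth sweep.

    Parameter values are min-max normalized to [-1, 1] (per parameter,
    over all records) before the per-depth means and standard deviations
    are accumulated, so that URI and RDS are comparable across parameters.
    """
    if len(dataset.depth_grid) < 3:
        raise ValueError("screening needs a sweep spanning >= 3 depths")
    tbl = dataset.table
    if parameters is None:
        parameters = [
            c for c in tbl.columns
            if c not in ("depth", "row", "col", "repeat", "flag")
            and np.issubdtype(tbl[c].dtype, np.number)
        ]
    depths = np.sort(dataset.depth_grid)
    norm = pd.DataFrame({p: _minmax_to_pm1(tbl[p]) for p in parameters})
    norm["depth"] = tbl["depth"].to_numpy()
    by_depth = norm.groupby("depth")
    means = by_depth.mean().loc[depths, parameters]
    stds = by_depth.std(ddof=0).loc[depths, parameters]
    rds_scores = rds(stds)
    rows = {}
    for p in parameters:
        u = uri(means[p].to_numpy(), depths)
        rows[p] = {
            "PCC": pcc(tbl[p], tbl["depth"]),
            "URI": u.width,
            "URI_flagged": u.flagged,
            "RDS": rds_scores[p],
        }
    stats = pd.DataFrame.from_dict(rows, orient="index")
    return ScreeningTable(stats=stats, responses=means)


# ---------------------------------------------------------------------------
# regression models


def _make_estimator(algorithm: str, pr_degree: int, knn_k: int):
    if algorithm == "SVR":
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    if algorithm == "KNN":
        return Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsRegressor(n_neighbors=knn_k))]
        )
    if algorithm == "PR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=pr_degree, include_bias=False)),
                ("lin", LinearRegression()),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; use 'SVR', 'KNN' or 'PR'")


@dataclass
class DepthModel:
    """A fitted depth-regression model with its cross-validation summary."""

    features: list[str]
    algorithm: str
    estimator: Pipeline
    cv_r2: float
    cv_rmse: float
    mae_by_depth: pd.Series
    seed: int | None = None
    folds: int = 5

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.features].to_numpy()
        return self.estimator.predict(np.asarray(X, dtype=float))

    def summary(self) -> dict:
        return {
            "features": self.features,
            "algorithm": self.algorithm,
            "cv_r2": self.cv_r2,
            "cv_rmse": self.cv_rmse,
            "mae_by_depth": {float(k): float(v) for k, v in self.mae_by_depth.items()},
            "seed": self.seed,
            "folds": self.folds,
        }


def train_model(
    dataset: DepthSweepDataset,
    features: Sequence[str] | str,
    algorithm: str = "SVR",
    seed: int | None = 0,
    folds: int = 5,
    pr_degree: int = 3,
    knn_k: int = 5,
    drop_flagged: bool = True,
) -> DepthModel:
    """Train and cross-validate a depth-regression model.

    ``features`` may be a list of column names or one of the named model
    presets (``Mp``, ``MA``, ``MD``, ``MM``).  The dataset is shuffled
    once (seeded) and split into ``folds`` cross-validation folds;
    feature standardization is fitted inside each training fold only.
    R^2, RMSE and the per-depth MAE table are computed from the pooled
    out-of-fold predictions, then the model is refitted on all records.
    """
    if isinstance(features, str):
        if features not in MODEL_FEATURES:
            raise ValueError(
                f"unknown model preset {features!r}; presets: {sorted(MODEL_FEATURES)}"
            )
        features = MODEL_FEATURES[features]
    features = list(features)
    if not features:
        raise ValueError("empty feature list")
    tbl = dataset.table
    missing = [f for f in features if f not in tbl.columns]
    if missing:
        raise ValueError(f"features not present in dataset: {missing}")
    if drop_flagged and "flag" in tbl.columns:
        ok = ~tbl["flag"].astype(bool)
        if ok.mean() < 0.8:
            raise ValueError(
                f"only {ok.mean():.0%} of records are unflagged; need >= 80%"
            )
        tbl = tbl[ok]
    X = tbl[features].to_numpy(dtype=float)
    y = tbl["depth"].to_numpy(dtype=float)

    est = _make_estimator(algorithm, pr_degree, knn_k)
    yhat = np.empty_like(y)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in cv.split(X):
        fold_est = clone(est)
        fold_est.fit(X[train_idx], y[train_idx])
        yhat[test_idx] = fold_est.predict(X[test_idx])
    mae = (
        pd.DataFrame({"depth": y, "abs_err": np.abs(y - yhat)})
        .groupby("depth")["abs_err"]
        .mean()
    )
    model_r2 = r2_score(y, yhat)
    model_rmse = rmse(y, yhat)
    est.fit(X, y)
    return DepthModel(
        features=features,
        algorithm=algorithm,
        estimator=est,
        cv_r2=model_r2,
        cv_rmse=model_rmse,
        mae_by_depth=mae,
        seed=seed,
        folds=folds,
    )


# ---------------------------------------------------------------------------
# depth maps


@dataclass
class DepthMap:
    """Per-cell retrieved depth (mm) with optional zone statistics."""

    depth: np.ndarray                      # (rows, cols), NaN where masked
    zone_labels: np.ndarray | None = None  # (rows, cols) int, 0 = no zone
    zone_stats: pd.DataFrame | None = None  # per-zone mean, MAE, truth


def predict_depth_map(
    model: DepthModel,
    img,
    grid: tuple[int, int] = (20, 20),
    zone_labels: np.ndarray | None = None,
    zone_truth: dict[int, float] | None = None,
    n_states: int = 2048,
) -> DepthMap:
    """Apply a fitted model cell-wise to a Mueller image.

    Cells with flagged (degenerate) features are masked rather than
    predicted.  If ``zone_labels`` (per cell, 0 = outside any zone) and
    ``zone_truth`` (zone -> true depth, mm) are given, per-zone mean
    retrieved depth and MAE against the truth are tabulated over
    unflagged cells.
    """
    feats = features_from_image(img, grid=grid, n_states=n_states)
    rows, cols = grid
    depth = np.full((rows, cols), np.nan)
    ok = ~feats["flag"].astype(bool).to_numpy()
    if ok.any():
        pred = model.predict(feats.loc[ok])
        depth[feats.loc[ok, "row"].to_numpy(), feats.loc[ok, "col"].to_numpy()] = pred
    stats = None
    if zone_labels is not None:
        zone_labels = np.asarray(zone_labels)
        if zone_labels.shape != (rows, cols):
            raise ValueError("zone_labels must match the cell grid shape")
        recs = []
        for z in np.unique(zone_labels):
            if z == 0:
                continue
            vals = depth[(zone_labels == z) & ~np.isnan(depth)]
            rec = {"zone": int(z), "n_cells": int(vals.size), "mean_depth": float(np.mean(vals)) if vals.size else np.nan}
            if zone_truth is not None and z in zone_truth:
                rec["true_depth"] = float(zone_truth[z])
                rec["mae"] = float(np.mean(np.abs(vals - zone_truth[z]))) if vals.size else np.nan
            recs.append(rec)
        stats = pd.DataFrame.from_records(recs).set_index("zone") if recs else None
    return DepthMap(depth=depth, zone_labels=zone_labels, zone_stats=stats)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: DepthModel, path) -> None:
    """Persist a model: JSON config + coefficients where the algorithm is
    parametric (PR), or a pickle sidecar for non-parametric fits."""
    cfg = model.summary()
    if model.algorithm == "PR":
        lin = model.estimator.named_steps["lin"]
        scale = model.estimator.named_steps["scale"]
        cfg["coefficients"] = {
            "coef": lin.coef_.tolist(),
            "intercept": float(lin.intercept_),
            "scale_mean": scale.mean_.tolist(),
            "scale_std": scale.scale_.tolist(),
            "degree": int(model.estimator.named_steps["poly"].degree),
        }
    else:
        import pickle

        sidecar = str(path) + ".pkl"
        with open(sidecar, "wb") as fh:
            pickle.dump(model.estimator, fh)
        cfg["estimator_sidecar"] = sidecar
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)


def load_model(path) -> DepthModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        cfg = json.load(fh)
    if "estimator_sidecar" in cfg:
        import pickle

        with open(cfg["estimator_sidecar"], "rb") as fh:
            est = pickle.load(fh)
    else:
        co = cfg["coefficients"]
        est = _make_estimator("PR", pr_degree=co["degree"], knn_k=5)
        poly = est.named_steps["poly"]
        poly.fit(np.zeros((1, len(cfg["features"]))))
        scale = est.named_steps["scale"]
        scale.mean_ = np.asarray(co["scale_mean"])
        scale.scale_ = np.asarray(co["scale_std"])
        scale.var_ = scale.scale_**2
        scale.n_features_in_ = len(cfg["features"])
        lin = est.named_steps["lin"]
        lin.coef_ = np.asarray(co["coef"])
        lin.intercept_ = co["intercept"]
    mae = pd.Series(
        {float(k): v for k, v in cfg["mae_by_depth"].items()}, name="abs_err"
    )
    return DepthModel(
        features=list(cfg["features"]),
        algorithm=cfg["algorithm"],
        estimator=est,
        cv_r2=cfg["cv_r2"],
        cv_rmse=cfg["cv_rmse"],
        mae_by_depth=mae,
        seed=cfg.get("seed"),
        folds=cfg.get("folds", 5),
    )
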