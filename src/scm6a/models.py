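"""The five-family regression zoo mapping features to per-site m6A levels.

:class:`Scm6ARegressor` is an sklearn-style estimator.  In ``per_site`` mode
it fits one regressor per m6A site on the trans feature matrix (observations
x regulators) with the site's level vector as target; in ``global`` mode a
single regressor is fit on stacked (site, observation) rows whose features
are the trans vector concatenated with the site's cis features.  Candidate
hyperparameters are selected by exhaustive grid search with k-fold
cross-validated mean R², ties broken by grid order; all stochastic stages
(splits, folds, forests) are seeded.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR, LinearSVR

from .config import TrainConfig

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "make_estimator",
    "split_train_test",
    "grid_search",
    "Scm6ARegressor",
    "save_models",
    "load_models",
]

FORMAT_VERSION = "scm6a-model-1"

FAMILIES = ("rf", "knn", "svr_poly", "lr", "linear_svr")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    "knn": {"n_neighbors": [3, 5, 10]},
    "svr_poly": {"degree": [2, 3], "C": [0.1, 1.0, 10.0]},
    "linear_svr": {"C": [0.1, 1.0, 10.0]},
    "lr": {},
}


def make_estimator(family: str, params: dict | None = None, seed: int = 0):
    """Instantiate one of the five regressor families with given params."""
    params = dict(params or {})
    if family == "rf":
        params.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "knn":
        return KNeighborsRegressor(**params)
    if family == "svr_poly":
        return SVR(kernel="poly", **params)
    if family == "lr":
        return LinearRegression(**params)
    if family == "linear_svr":
        params.setdefault("max_iter", 10000)
        params.setdefault("dual", True)
        return LinearSVR(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")


def split_train_test(ids, cfg: TrainConfig | None = None,
                     train_fraction: float | None = None,
                     seed: int | None = None):
    """Random disjoint, exhaustive train/test partition of observation ids.

    The training set holds round(train_fraction * n) observations (70/30 by
    default); reproducible under the seed.
    """
    cfg = cfg or TrainConfig()
    frac = train_fraction if train_fraction is not None else cfg.train_fraction
    seed = seed if seed is not None else cfg.seed
    ids = list(ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 observations to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def grid_search(family: str, grid: dict[str, list] | None, X, y,
                cv_folds: int = 5, seed: int = 0):
    """Exhaustive k-fold CV over a hyperparameter grid.

    Returns ``(best_params, table)``; the table has one row per (candidate,
    fold) with the fold R².  The best candidate maximizes mean fold R²; ties
    go to the earlier candidate in grid order.
    """
    grid = DEFAULT_GRIDS[family] if grid is None else grid
    candidates = list(ParameterGrid(grid)) if grid else [{}]
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    records = []
    means = []
    for ci, params in enumerate(candidates):
        scores = []
        for fi, (tr, te) in enumerate(folds):
            est = make_estimator(family, params, seed=seed)
            est.fit(X[tr], y[tr])
            s = float(est.score(X[te], y[te]))
            scores.append(s)
            records.append({"candidate": ci, "params": json.dumps(params),
                            "fold": fi, "r2": s})
        means.append(np.mean(scores))
    means = np.asarray(means)
    if not np.isfinite(means).any():
        raise ValueError("no grid candidate produced a finite CV score")
    best = int(np.nanargmax(np.where(np.isfinite(means), means, -np.inf)))
    return candidates[best], pd.DataFrame.from_records(records)


def _transform_target(y: np.ndarray, how: str) -> np.ndarray:
    return np.log2(1.0 + y) if how == "log2" else y


def _inverse_target(v: np.ndarray, how: str) -> np.ndarray:
    return np.exp2(v) - 1.0 if how == "log2" else v


class Scm6ARegressor(BaseEstimator, RegressorMixin):
    """Per-site (or pooled) regression from feature matrices to m6A levels.

    Parameters
    ----------
    family:
        One of ``rf``, ``knn``, ``svr_poly``, ``lr``, ``linear_svr``.
    mode:
        ``per_site`` fits one regressor per m6A site on the trans features;
        ``global`` fits a single regressor over stacked (site, observation)
        rows of trans features concatenated with per-site cis features.
    param_grid:
        Hyperparameter grid searched by CV.  ``None`` uses the family's
        default grid; an empty dict skips the search and uses the family's
        default parameters.
    cv_folds, target_transform, seed:
        CV fold count for the search, target scale (``identity`` or
        ``log2`` as log2(1+y)), and the seed threaded into every stochastic
        stage.

    Fitted attributes: ``models_`` (site id -> fitted sklearn regressor, or
    the single key ``__global__``), ``best_params_``, ``sites_``,
    ``skipped_sites_``, ``feature_names_in_``, ``cv_tables_``.
    """

    def __init__(self, family: str = "rf", mode: str = "per_site",
                 param_grid: dict | None = None, cv_folds: int = 5,
                 target_transform: str = "identity", seed: int = 0):
        self.family = family
        self.mode = mode
        self.param_grid = param_grid
        self.cv_folds = cv_folds
        self.target_transform = target_transform
        self.seed = seed

    # -- helpers ----------------------------------------------------------
    def _check_inputs(self, X: pd.DataFrame, Y: pd.DataFrame):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.mode not in ("per_site", "global"):
            raise ValueError("mode must be 'per_site' or 'global'")
        if not set(Y.columns) <= set(X.index):
            missing = sorted(set(Y.columns) - set(X.index))[:5]
            raise ValueError(f"targets reference unknown observations {missing}")
        return X.loc[list(Y.columns)]

    def _search(self, X, y):
        if self.param_grid is not None and not self.param_grid:
            return {}, None
        params, table = grid_search(self.family, self.param_grid, X, y,
                                    cv_folds=self.cv_folds, seed=self.seed)
        return params, table

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, Y: pd.DataFrame,
            cis: pd.DataFrame | None = None):
        """Fit on observations x features ``X`` and sites x observations ``Y``."""
        X = self._check_inputs(X, Y)
        self.feature_names_in_ = list(X.columns)
        self.cis_feature_names_ = list(cis.columns) if cis is not None else None
        self.models_ = {}
        self.best_params_ = {}
        self.cv_tables_ = {}
        self.skipped_sites_ = []
        xv = X.to_numpy(float)

        if self.mode == "global":
            if cis is None:
                raise ValueError("global mode requires per-site cis features")
            sites = [s for s in Y.index if s in cis.index]
            if not sites:
                raise ValueError("no site has both targets and cis features")
            blocks, targets = [], []
            for s in sites:
                y = Y.loc[s].to_numpy(float)
                ok = np.isfinite(y)
                if not ok.any():
                    self.skipped_sites_.append(s)
                    continue
                cvec = np.broadcast_to(cis.loc[s].to_numpy(float),
                                       (ok.sum(), cis.shape[1]))
                blocks.append(np.hstack([xv[ok], cvec]))
                targets.append(y[ok])
            Xg = np.vstack(blocks)
            yg = _transform_target(np.concatenate(targets),
                                   self.target_transform)
            params, table = self._search(Xg, yg)
            est = make_estimator(self.family, params, seed=self.seed)
            est.fit(Xg, yg)
            self.models_["__global__"] = est
            self.best_params_["__global__"] = params
            if table is not None:
                self.cv_tables_["__global__"] = table
            self.sites_ = [s for s in sites if s not in self.skipped_sites_]
            return self

        self.sites_ = []
        for s in Y.index:
            y = Y.loc[s].to_numpy(float)
            ok = np.isfinite(y)
            if not ok.any():
                self.skipped_sites_.append(s)
                continue
            if ok.sum() < self.cv_folds:
                raise ValueError(
                    f"site {s} has {ok.sum()} training observations, fewer "
                    f"than cv_folds={self.cv_folds}")
            yt = _transform_target(y[ok], self.target_transform)
            if np.ptp(yt) == 0:
                # constant target: degenerate site, fit reduces to the constant
                warnings.warn(f"site {s} has constant target; model degenerates "
                              "to a constant predictor", stacklevel=2)
            params, table = self._search(xv[ok], yt)
            est = make_estimator(self.family, params, seed=self.seed)
            est.fit(xv[ok], yt)
            self.models_[s] = est
            self.best_params_[s] = params
            if table is not None:
                self.cv_tables_[s] = table
            self.sites_.append(s)
        if not self.sites_:
            raise ValueError("every site was skipped (all-missing targets)")
        return self

    def _align_features(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(
                f"feature matrix lacks {len(missing)} manifest columns, "
                f"e.g. {missing[:5]}")
        extra = [c for c in X.columns if c not in self.feature_names_in_]
        if extra:
            warnings.warn(f"ignoring {len(extra)} feature columns outside the "
                          "training manifest", stacklevel=2)
        return X[self.feature_names_in_].to_numpy(float)

    def predict(self, X: pd.DataFrame,
                cis: pd.DataFrame | None = None) -> pd.DataFrame:
        """Predict a sites x observations m6A matrix on the original scale."""
        xv = self._align_features(X)
        if self.mode == "global":
            if cis is None:
                raise ValueError("global mode requires per-site cis features")
            est = self.models_["__global__"]
            rows = []
            for s in self.sites_:
                cvec = np.broadcast_to(cis.loc[s].to_numpy(float),
                                       (xv.shape[0], cis.shape[1]))
                rows.append(est.predict(np.hstack([xv, cvec])))
            pred = np.vstack(rows)
        else:
            pred = np.vstack([self.models_[s].predict(xv)
                              for s in self.sites_])
        pred = _inverse_target(pred, self.target_transform)
        return pd.DataFrame(pred, index=self.sites_, columns=list(X.index))

    def score(self, X: pd.DataFrame, Y: pd.DataFrame) -> float:
        """Median per-site test R² (robust summary across sites)."""
        from .evaluate import r_squared

        pred = self.predict(X)
        vals = []
        for s in self.sites_:
            y = Y.loc[s, pred.columns].to_numpy(float)
            ok = np.isfinite(y)
            vals.append(r_squared(y[ok], pred.loc[s].to_numpy()[ok]))
        return float(np.median(vals))


def _manifest_hash(features: list[str]) -> str:
    return hashlib.sha256("\n".join(features).encode()).hexdigest()


def save_models(model: Scm6ARegressor, path: str | Path) -> None:
    """Persist a fitted model set: JSON manifest + joblib regressor bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "family": model.family,
        "mode": model.mode,
        "target_transform": model.target_transform,
        "seed": model.seed,
        "sites": model.sites_,
        "skipped_sites": model.skipped_sites_,
        "best_params": model.best_params_,
        "feature_names": model.feature_names_in_,
        "cis_feature_names": model.cis_feature_names_,
        "feature_hash": _manifest_hash(model.feature_names_in_),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    joblib.dump(model.models_, path / "models.joblib")


def load_models(path: str | Path) -> Scm6ARegressor:
    """Load a model bundle written by :func:`save_models`."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no model manifest at {mpath}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"model format {manifest.get('format_version')!r} does not match "
            f"{FORMAT_VERSION!r}")
    if _manifest_hash(manifest["feature_names"]) != manifest["feature_hash"]:
        raise ValueError("feature manifest hash mismatch; bundle corrupted")
    model = Scm6ARegressor(
        family=manifest["family"], mode=manifest["mode"],
        target_transform=manifest["target_transform"], seed=manifest["seed"])
    model.models_ = joblib.load(path / "models.joblib")
    model.best_params_ = manifest["best_params"]
    model.sites_ = manifest["sites"]
    model.skipped_sites_ = manifest["skipped_sites"]
    model.feature_names_in_ = manifest["feature_names"]
    model.cis_feature_names_ = manifest["cis_feature_names"]
    model.cv_tables_ = {}
    return model
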