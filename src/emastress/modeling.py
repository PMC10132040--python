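"""Nomothetic and idiographic stress-recognition models.

Two training regimes over the same feature matrix:

* **Nomothetic** — one model per data split, trained across persons and
  evaluated on held-out persons: persons are partitioned into k groups
  (default 5, person-counts differing by at most one) and each fold's
  models never see any observation of its test persons, including during
  feature scaling.
* **Idiographic** — one model per person, trained on the person's first 80%
  of observations (time order) and evaluated on the final 20%; persons with
  fewer than 6 observations are excluded.

Model families are LASSO regression, RBF-kernel support vector regression
and random forest regression, each tuned by inner 5-fold search over a
small standard grid (randomized search with 10 draws for idiographic
random forests, which are the expensive case). The naive baseline predicts
a person's average stress: the person's mean over all their observations in
the nomothetic regime, and over their training rows only in the idiographic
regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold, RandomizedSearchCV
from sklearn.svm import SVR

from .features import FEATURE_COLUMNS, ScalerRecord, minmax_fit_apply

MODEL_KINDS = ("lasso", "svr", "rf")
BASELINE = "baseline"

#: Default hyperparameter grids: small, standard, desk-scale.
DEFAULT_GRIDS: dict[str, dict] = {
    "lasso": {"alpha": list(np.logspace(-4, 1, 7))},
    "svr": {
        "C": [0.1, 1.0, 10.0],
        "epsilon": [0.01, 0.1, 0.5],
        "gamma": ["scale", 0.01, 0.1],
    },
    "rf": {
        "n_estimators": [100, 300],
        "max_depth": [None, 5, 10],
        "min_samples_leaf": [1, 5, 10],
    },
}

#: Randomized-search draws for idiographic random forests.
RF_RANDOM_SEARCH_ITER = 10

IDIOGRAPHIC_MIN_OBS = 6  # inclusion floor: persons with fewer obs are excluded


# ------------------------------------------------------------------ splits --


def group_user_folds(person_ids, k: int = 5, seed: int = 0) -> pd.Series:
    """Partition persons into k folds with person-counts differing by <=1.

    Returns a Series mapping person -> fold index; all observations of a
    person share a fold, so no person ever crosses a fold's train/test line.
    """
    persons = pd.unique(pd.Series(person_ids))
    if k > len(persons):
        raise ValueError(f"k={k} exceeds the number of persons ({len(persons)})")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(persons)
    folds = np.concatenate([np.full(len(part), i) for i, part in enumerate(np.array_split(shuffled, k))])
    return pd.Series(folds, index=shuffled, name="fold").sort_index()


def person_time_split(
    obs: pd.DataFrame, train_frac: float = 0.8, min_obs: int = IDIOGRAPHIC_MIN_OBS
):
    """First-80/final-20 time split of one person's observations.

    Returns (train_index, test_index) positions into the time-sorted frame,
    or ``None`` when the person has fewer than ``min_obs`` observations
    (the idiographic inclusion floor).
    """
    n = len(obs)
    if n < min_obs:
        return None
    order = np.argsort(obs["prompt_time"].to_numpy(), kind="stable")
    n_train = int(np.floor(train_frac * n))
    return order[:n_train], order[n_train:]


# ------------------------------------------------------------------ models --


def _make_estimator(model_kind: str, seed: int):
    if model_kind == "lasso":
        return Lasso(max_iter=50_000)
    if model_kind == "svr":
        return SVR(kernel="rbf")
    if model_kind == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    raise ValueError(f"unknown model kind: {model_kind!r}")


@dataclass
class FittedModelRecord:
    """A trained regressor plus everything needed to reuse it faithfully:
    its training-set scaler, chosen hyperparameters, and scope (the fold or
    person it belongs to)."""

    model_kind: str
    mode: str  # "nomothetic" | "idiographic"
    scope: object  # fold id or person id
    estimator: object  # fitted sklearn regressor, or None for the baseline
    scaler: ScalerRecord | None
    best_params: dict
    search_type: str  # "grid" | "randomized" | "none"
    seed: int
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    baseline_value: float | None = None  # constant prediction, baseline only

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predict for raw (unscaled) feature rows; applies the record's own
        scaler so test rows are always transformed with training bounds."""
        if self.model_kind == BASELINE:
            return np.full(len(rows), float(self.baseline_value))
        missing = set(self.feature_names) - set(rows.columns)
        if missing:
            raise ValueError(f"feature-set mismatch; missing: {sorted(missing)}")
        x = self.scaler.transform(rows[self.feature_names])
        return np.asarray(self.estimator.predict(x.to_numpy()), dtype=float)

    def metadata(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "mode": self.mode,
            "scope": str(self.scope),
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
            "search_type": self.search_type,
            "seed": self.seed,
        }


def tune_and_fit(
    model_kind: str,
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    *,
    grid: dict | None = None,
    inner_folds: int = 5,
    search: str = "grid",
    seed: int = 0,
    n_iter: int = RF_RANDOM_SEARCH_ITER,
):
    """Select hyperparameters by inner k-fold search and refit on all rows.

    ``x_train`` must already be scaled with a scaler fitted on these same
    rows. Inner folds shrink to the number of training rows when the set is
    tiny. The selection score is the estimator's default (coefficient of
    determination). Returns (fitted estimator, best_params).
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[model_kind]
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    n = len(x_train)
    n_splits = max(2, min(inner_folds, n))
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    est = _make_estimator(model_kind, seed)
    n_points = int(np.prod([len(v) for v in grid.values()]))
    if search == "randomized" and n_points > n_iter:
        searcher = RandomizedSearchCV(
            est, grid, n_iter=n_iter, cv=cv, random_state=seed, refit=True, n_jobs=1
        )
    else:
        searcher = GridSearchCV(est, grid, cv=cv, refit=True, n_jobs=1)
    searcher.fit(x_train.to_numpy(), np.asarray(y_train, dtype=float))
    return searcher.best_estimator_, dict(searcher.best_params_)


# ---------------------------------------------------------------- baseline --


def baseline_value(mode: str, y_all: np.ndarray, train_mask: np.ndarray | None = None) -> float:
    """The naive constant prediction for one person: their average stress.

    Nomothetic: the mean over all of the person's observations (identically
    0 under full-series within-person centering). Idiographic: the mean over
    the person's training rows only, to prevent train-to-test leakage.
    """
    y_all = np.asarray(y_all, dtype=float)
    if mode == "nomothetic":
        return float(np.mean(y_all))
    if mode == "idiographic":
        if train_mask is None:
            raise ValueError("idiographic baseline needs the person's train rows")
        return float(np.mean(y_all[np.asarray(train_mask, dtype=bool)]))
    raise ValueError(f"unknown mode: {mode!r}")


# ----------------------------------------------------------------- drivers --


@dataclass
class FitResult:
    """All fitted records of one regime plus tidy out-of-sample predictions
    (columns person_id, prompt_time, mode, model, prediction, observed)."""

    records: list[FittedModelRecord]
    predictions: pd.DataFrame
    excluded_persons: list = field(default_factory=list)


def fit_nomothetic(
    matrix: pd.DataFrame,
    model_kinds=MODEL_KINDS,
    *,
    k: int = 5,
    seed: int = 0,
    grids: dict | None = None,
    inner_folds: int = 5,
) -> FitResult:
    """Grouped k-fold training across persons.

    For each fold: scale on the training persons' rows, tune and fit each
    model kind by inner grid search, predict all observations of the held-out
    persons. The per-person baseline (mean centered stress over all of the
    person's observations) is emitted alongside.
    """
    folds = group_user_folds(matrix["person_id"], k=k, seed=seed)
    fold_of_row = matrix["person_id"].map(folds).to_numpy()
    records, pred_rows = [], []

    for fold in range(k):
        test_mask = fold_of_row == fold
        train, test = matrix[~test_mask], matrix[test_mask]
        [x_train, x_test], scaler = minmax_fit_apply(
            train, test, columns=list(FEATURE_COLUMNS)
        )
        y_train = train["stress_centered"].to_numpy()
        for kind in model_kinds:
            grid = (grids or {}).get(kind) or DEFAULT_GRIDS[kind]
            est, best = tune_and_fit(
                kind, x_train, y_train, grid=grid, inner_folds=inner_folds, seed=seed
            )
            rec = FittedModelRecord(
                model_kind=kind,
                mode="nomothetic",
                scope=fold,
                estimator=est,
                scaler=scaler,
                best_params=best,
                search_type="grid",
                seed=seed,
            )
            records.append(rec)
            pred_rows.append(_tidy(test, "nomothetic", kind, rec.predict(test)))

        # Nomothetic baseline: person's mean centered stress over ALL their
        # observations (a person's rows all live in one fold, so the fold's
        # test rows are that person's full series).
        base = test.groupby("person_id")["stress_centered"].transform("mean")
        pred_rows.append(_tidy(test, "nomothetic", BASELINE, base.to_numpy()))

    return FitResult(records=records, predictions=pd.concat(pred_rows, ignore_index=True))


def fit_idiographic(
    matrix: pd.DataFrame,
    model_kinds=MODEL_KINDS,
    *,
    seed: int = 0,
    grids: dict | None = None,
    train_frac: float = 0.8,
    min_obs: int = IDIOGRAPHIC_MIN_OBS,
    inner_folds: int = 5,
    rf_n_iter: int = RF_RANDOM_SEARCH_ITER,
) -> FitResult:
    """Per-person models on first-80/final-20 time splits.

    Random forests are tuned by randomized search (10 draws); LASSO and SVR
    by full grid search. Persons under the inclusion floor are excluded and
    reported.
    """
    records, pred_rows, excluded = [], [], []
    for pid, obs in matrix.groupby("person_id", sort=True):
        obs = obs.reset_index(drop=True)
        split = person_time_split(obs, train_frac=train_frac, min_obs=min_obs)
        if split is None:
            excluded.append(pid)
            continue
        tr_idx, te_idx = split
        train, test = obs.iloc[tr_idx], obs.iloc[te_idx]
        [x_train, x_test], scaler = minmax_fit_apply(
            train, test, columns=list(FEATURE_COLUMNS)
        )
        y_train = train["stress_centered"].to_numpy()
        for kind in model_kinds:
            grid = (grids or {}).get(kind) or DEFAULT_GRIDS[kind]
            search = "randomized" if kind == "rf" else "grid"
            est, best = tune_and_fit(
                kind,
                x_train,
                y_train,
                grid=grid,
                inner_folds=inner_folds,
                search=search,
                seed=seed,
                n_iter=rf_n_iter,
            )
            rec = FittedModelRecord(
                model_kind=kind,
                mode="idiographic",
                scope=pid,
                estimator=est,
                scaler=scaler,
                best_params=best,
                search_type=search,
                seed=seed,
            )
            records.append(rec)
            pred_rows.append(_tidy(test, "idiographic", kind, rec.predict(test)))

        bval = baseline_value(
            "idiographic",
            obs["stress_centered"].to_numpy(),
            train_mask=np.isin(np.arange(len(obs)), tr_idx),
        )
        records.append(
            FittedModelRecord(
                model_kind=BASELINE,
                mode="idiographic",
                scope=pid,
                estimator=None,
                scaler=None,
                best_params={},
                search_type="none",
                seed=seed,
                baseline_value=bval,
            )
        )
        pred_rows.append(_tidy(test, "idiographic", BASELINE, np.full(len(test), bval)))

    preds = (
        pd.concat(pred_rows, ignore_index=True)
        if pred_rows
        else pd.DataFrame(columns=["person_id", "prompt_time", "mode", "model", "prediction", "observed"])
    )
    return FitResult(records=records, predictions=preds, excluded_persons=excluded)


def _tidy(rows: pd.DataFrame, mode: str, model: str, pred: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": rows["person_id"].to_numpy(),
            "prompt_time": rows["prompt_time"].to_numpy(),
            "mode": mode,
            "model": model,
            "prediction": np.asarray(pred, dtype=float),
            "observed": rows["stress_centered"].to_numpy(),
        }
    )
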