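"""Random-forest models of residency drivers.

The central object is :class:`ResidencyDriverForest`, a scikit-learn-style
regressor wrapping a bagged regression forest. It reports out-of-bag (OOB)
R²/MSE from the bagging mechanism, evaluates permutation variable importance
on a held-out validation block, attaches Altmann-style target-permutation
p-values, and computes partial-dependence curves.

Fix-level rows are strongly autocorrelated: fixes in the same grid cell and
hour share the target exactly and differ only marginally in covariates. A
random row split therefore leaks information between training and evaluation.
The estimator's default validation split holds out *whole hours*, which is
the blocked evaluation movement-data analyses call for; OOB metrics keep the
classical per-row bootstrap so they remain comparable with standard forest
reports (and inherit the optimism that autocorrelation brings — see the
methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .covariates import PREDICTORS

#: predictors treated as unordered categoricals (grid for PDPs = levels)
CATEGORICAL_PREDICTORS = ("A",)


class ResidencyDriverForest(RegressorMixin, BaseEstimator):
    """Regression forest for the livestock residency index.

    Parameters
    ----------
    n_trees : int, default 500
        Trees in the forest (must be >= 100 so OOB estimates stabilise).
    mtry : int, default 4
        Predictors tried per split; the regression-forest convention p/3
        rounded down for the 12-predictor table.
    min_samples_leaf : int, default 5
        Leaf size; 5 is the classical regression-forest default.
    val_fraction : float, default 0.33
        Share of the data (hours or rows) held out per validation block.
    block_by_hour : bool, default True
        Hold out whole hours for validation (recommended for fix-level rows);
        falls back to a random row split when no hour labels are available.
    importance_folds : int, default 3
        Hour-grouped folds for the importance score: one forest per fold
        complement, permutation importance on the held-out fold, averaged.
        Averaging over folds keeps a single unrepresentative block (say, the
        only rainy hours) from dominating the ranking.
    n_repeats : int, default 2
        Permutation repeats per predictor per fold for the importance score.
    seed : int or None
        Seed for the forest, the split and the permutations.

    Attributes (after :meth:`fit`)
    ------------------------------
    forest_ : fitted ``RandomForestRegressor`` (on the first fold's calibration
        block; used for prediction and partial dependence)
    oob_r2_, oob_mse_ : out-of-bag performance of that forest (per-row bagging)
    val_r2_, val_mse_ : pooled out-of-fold performance (with hour labels this
        is generalisation to unseen hours, immune to within-hour duplication)
    n_calibration_, n_validation_ : row counts of the first fold's blocks
    importances_ : Series of fold-averaged permutation importances
        (held-out MSE increase)
    feature_names_in_ : predictor names
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int = 4,
        min_samples_leaf: int = 5,
        val_fraction: float = 0.33,
        block_by_hour: bool = True,
        importance_folds: int = 3,
        n_repeats: int = 2,
        seed: int | None = None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.val_fraction = val_fraction
        self.block_by_hour = block_by_hour
        self.importance_folds = importance_folds
        self.n_repeats = n_repeats
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _validate(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        if Xv.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(Xv)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return Xv, names
        yv = np.asarray(y, dtype=float)
        if len(yv) != len(Xv):
            raise ValueError("X and y length mismatch")
        if np.var(yv) == 0:
            raise ValueError("constant target: R² is undefined")
        return Xv, names, yv

    def _split(self, n: int, hours, rng: np.random.Generator):
        """Calibration/validation indices; whole hours held out when possible."""
        if self.block_by_hour and hours is not None:
            hours = np.asarray(hours)
            uniq = np.unique(hours)
            n_val = max(1, int(round(len(uniq) * self.val_fraction)))
            if len(uniq) - n_val < 1:
                raise ValueError("too few hours to hold any out for validation")
            val_hours = rng.choice(uniq, size=n_val, replace=False)
            val = np.isin(hours, val_hours)
        else:
            val = np.zeros(n, dtype=bool)
            val[rng.choice(n, size=max(1, int(round(n * self.val_fraction))), replace=False)] = True
        return ~val, val

    def _folds(self, n: int, hours, rng: np.random.Generator) -> list[np.ndarray]:
        """Validation masks of ``importance_folds`` disjoint blocks (whole hours
        per block when labels are available)."""
        k = max(2, int(self.importance_folds))
        if self.block_by_hour and hours is not None:
            hours = np.asarray(hours)
            uniq = rng.permutation(np.unique(hours))
            if len(uniq) < k:
                raise ValueError(f"need at least {k} distinct hours for {k}-fold importance")
            return [np.isin(hours, grp) for grp in np.array_split(uniq, k)]
        idx = rng.permutation(n)
        return [np.isin(np.arange(n), grp) for grp in np.array_split(idx, k)]

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, hours: Sequence | None = None):
        """Fit on the calibration block and score importance on the held-out block.

        ``hours`` are per-row hour labels for the blocked split; if ``X`` is a
        DataFrame containing an ``hour_index`` column that column is used (and
        never enters the predictor set).
        """
        if self.n_trees < 100:
            raise ValueError("n_trees must be at least 100")
        if isinstance(X, pd.DataFrame) and hours is None and "hour_index" in X.columns:
            hours = X["hour_index"].to_numpy()
        if isinstance(X, pd.DataFrame):
            X = X[[c for c in X.columns if c not in ("hour_index", "timestamp", "lri")]]
        Xv, names, yv = self._validate(X, y)
        rng = np.random.default_rng(self.seed)

        folds = self._folds(len(Xv), hours, rng)
        oof = np.full(len(yv), np.nan)
        fold_imps = []
        for k, val in enumerate(folds):
            cal = ~val
            if np.var(yv[cal]) == 0:
                raise ValueError("constant target in calibration block")
            forest = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=min(self.mtry, Xv.shape[1]),
                min_samples_leaf=self.min_samples_leaf,
                oob_score=(k == 0),
                n_jobs=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xv[cal], yv[cal])
            if k == 0:
                self.forest_ = forest
                oob_pred = forest.oob_prediction_
                self.oob_mse_ = float(np.mean((oob_pred - yv[cal]) ** 2))
                self.oob_r2_ = float(1.0 - self.oob_mse_ / np.var(yv[cal]))
                self.n_calibration_ = int(cal.sum())
                self.n_validation_ = int(val.sum())
                self._val_mask = val
            oof[val] = forest.predict(Xv[val])
            fold_imps.append(
                permutation_importance_mse(forest, Xv[val], yv[val], rng, self.n_repeats)
            )

        # pooled out-of-fold metrics: generalisation to unseen hours, immune to
        # the near-duplicate leakage that inflates per-row OOB on burst fixes
        self.val_mse_ = float(np.mean((oof - yv) ** 2))
        self.val_r2_ = float(1.0 - self.val_mse_ / np.var(yv))

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xv.shape[1]
        self.importances_ = pd.Series(
            np.mean(fold_imps, axis=0), index=names, name="importance"
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)]
        return self.forest_.predict(np.asarray(X, dtype=float))

    # -- importance significance ------------------------------------------
    def importance_pvalues(
        self,
        X,
        y,
        hours: Sequence | None = None,
        n_perm: int = 100,
        n_trees_null: int = 25,
        max_rows: int | None = 2000,
        n_obs_splits: int = 5,
    ) -> pd.DataFrame:
        """Target-permutation p-values for every predictor's importance.

        The target is permuted ``n_perm`` times; each time a forest of
        ``n_trees_null`` trees is refit and the validation permutation
        importance recomputed, yielding a null draw per predictor. The
        observed importance is computed under the identical reduced
        configuration — averaged over ``n_obs_splits`` calibration/validation
        splits so a single unlucky held-out block cannot dominate it — and

            p = (1 + #{null >= observed}) / (1 + n_perm).

        Null draws use one split each, so the null distribution also carries
        the split variability; relative to the averaged observed statistic
        that makes the test mildly conservative.

        ``max_rows`` subsamples rows (whole hours when available) before the
        procedure to keep the refits affordable; the full-size fit in
        :meth:`fit` is unaffected. Requires ``n_perm >= 20`` (p-value
        resolution below that is useless at the 0.01 level; 100+ is needed to
        resolve p <= 0.01 at all).
        """
        if n_perm < 20:
            raise ValueError("n_perm must be at least 20 for usable p-values")
        if isinstance(X, pd.DataFrame) and hours is None and "hour_index" in X.columns:
            hours = X["hour_index"].to_numpy()
        if isinstance(X, pd.DataFrame):
            X = X[[c for c in X.columns if c not in ("hour_index", "timestamp", "lri")]]
        Xv, names, yv = self._validate(X, y)
        rng = np.random.default_rng(None if self.seed is None else self.seed + 1)

        if max_rows is not None and len(Xv) > max_rows:
            sub = rng.choice(len(Xv), size=max_rows, replace=False)
            sub.sort()
            Xv, yv = Xv[sub], yv[sub]
            hours = None if hours is None else np.asarray(hours)[sub]

        def importance_of(target: np.ndarray) -> np.ndarray:
            cal, val = self._split(len(Xv), hours, rng)
            forest = RandomForestRegressor(
                n_estimators=n_trees_null,
                max_features=min(self.mtry, Xv.shape[1]),
                min_samples_leaf=self.min_samples_leaf,
                n_jobs=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xv[cal], target[cal])
            return permutation_importance_mse(forest, Xv[val], target[val], rng, n_repeats=1)

        observed = np.mean([importance_of(yv) for _ in range(n_obs_splits)], axis=0)
        null = np.empty((n_perm, Xv.shape[1]))
        for b in range(n_perm):
            null[b] = importance_of(rng.permutation(yv))
        p = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n_perm)
        return pd.DataFrame(
            {"importance_reduced": observed, "p_value": p}, index=pd.Index(names, name="predictor")
        )

    # -- partial dependence ------------------------------------------------
    def partial_dependence(self, X, predictor: str, n_grid: int = 50) -> pd.DataFrame:
        check_is_fitted(self, "forest_")
        return partial_dependence(self, X, predictor, n_grid=n_grid)


def permutation_importance_mse(
    model, X: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_repeats: int = 3
) -> np.ndarray:
    """Permutation importance as the increase in MSE on (X, y).

    For each column, its values are shuffled ``n_repeats`` times and the mean
    rise of the prediction MSE above the baseline is returned. Positive values
    mean the model relied on the column.
    """
    base = np.mean((model.predict(X) - y) ** 2)
    out = np.empty(X.shape[1])
    Xp = X.copy()
    for j in range(X.shape[1]):
        scores = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(X))
            Xp[:, j] = X[perm, j]
            scores.append(np.mean((model.predict(Xp) - y) ** 2))
        Xp[:, j] = X[:, j]
        out[j] = np.mean(scores) - base
    return out


def importance_significance(
    est: "ResidencyDriverForest", rows: pd.DataFrame, n_perm: int = 100, **kwargs
) -> pd.DataFrame:
    """Target-permutation p-values for a fitted model and its assembled table.

    Functional wrapper over :meth:`ResidencyDriverForest.importance_pvalues`
    for tables carrying the standard predictor columns plus ``lri``.
    """
    X = rows[PREDICTORS + (["hour_index"] if "hour_index" in rows.columns else [])]
    return est.importance_pvalues(X, rows["lri"].to_numpy(), n_perm=n_perm, **kwargs)


def rank_importance(importances: pd.Series, p_values: pd.Series | None = None, alpha: float = 0.01) -> pd.DataFrame:
    """Rank predictors by importance: 1 = largest; ties break by name order.

    When p-values are supplied a ``significant`` star column is attached at
    ``p < alpha``.
    """
    df = importances.rename("importance").rename_axis("predictor").reset_index()
    df = df.sort_values(["importance", "predictor"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    if p_values is not None:
        df["p_value"] = df["predictor"].map(p_values)
        df["significant"] = df["p_value"] < alpha
    return df.reset_index(drop=True)


def partial_dependence(model, X, predictor: str, n_grid: int = 50) -> pd.DataFrame:
    """Partial-dependence curve: mean prediction with ``predictor`` set to each
    grid value over all rows of ``X`` (the set-and-average definition).

    The grid is ``n_grid`` evenly spaced values over the predictor's observed
    range; for the categorical animal code the observed levels are the grid.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X[names].to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xv.shape[1])]
    if predictor not in names:
        raise ValueError(f"{predictor!r} not among predictors {names}")
    j = names.index(predictor)
    col = Xv[:, j]
    if predictor in CATEGORICAL_PREDICTORS:
        grid = np.unique(col)
    else:
        lo, hi = col.min(), col.max()
        grid = np.linspace(lo, hi, n_grid) if hi > lo else np.array([lo])

    base_model = getattr(model, "forest_", model)
    Xw = Xv.copy()
    means = np.empty(len(grid))
    for i, g in enumerate(grid):
        Xw[:, j] = g
        means[i] = base_model.predict(Xw).mean()
    return pd.DataFrame({predictor: grid, "mean_prediction": means})


def subset_grazing_hours(
    rows: pd.DataFrame, grazing_intervals: Sequence[tuple] | None, mode: str = "GH"
) -> pd.DataFrame:
    """Restrict the model table to times when grazing was observed.

    ``grazing_intervals`` are half-open ``[start, end)`` timestamp pairs. In
    AH (all-hours) mode the table passes through unchanged.
    """
    if mode == "AH":
        return rows
    if mode != "GH":
        raise ValueError("mode must be 'AH' or 'GH'")
    if not grazing_intervals:
        raise ValueError("GH mode requires at least one grazing interval")
    ts = pd.to_datetime(rows["timestamp"], utc=True)
    keep = np.zeros(len(rows), dtype=bool)
    for start, end in grazing_intervals:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        keep |= ((ts >= start) & (ts < end)).to_numpy()
    return rows[keep].reset_index(drop=True)


@dataclass
class FitResult:
    """Per-model outputs in the shape the study report tabulates."""

    trial: str
    treatment: str
    hours_mode: str
    oob_r2: float
    oob_mse: float
    val_r2: float
    val_mse: float
    n_calibration: int
    n_validation: int
    importance: pd.DataFrame  # predictor, importance, rank (+ p_value, significant)
    seed: int | None


def fit_rf(
    rows: pd.DataFrame,
    trial: str = "T1",
    treatment: str = "IP",
    hours_mode: str = "AH",
    n_trees: int = 500,
    mtry: int = 4,
    seed: int | None = 0,
    with_pvalues: bool = False,
    n_perm: int = 100,
    **pv_kwargs,
) -> tuple[ResidencyDriverForest, FitResult]:
    """Fit one residency model on an assembled table (columns PREDICTORS + lri).

    Thin functional wrapper over :class:`ResidencyDriverForest` that returns
    the fitted estimator plus a :class:`FitResult` row for study tables.
    """
    if len(rows) < 500:
        raise ValueError("need at least 500 rows for a stable forest fit")
    missing = [c for c in PREDICTORS if c not in rows.columns]
    if missing:
        raise ValueError(f"model table missing predictors: {missing}")
    X = rows[PREDICTORS]
    y = rows["lri"].to_numpy()
    hours = rows["hour_index"].to_numpy() if "hour_index" in rows.columns else None

    est = ResidencyDriverForest(n_trees=n_trees, mtry=mtry, seed=seed).fit(X, y, hours=hours)
    pvals = None
    if with_pvalues:
        pv = est.importance_pvalues(X, y, hours=hours, n_perm=n_perm, **pv_kwargs)
        pvals = pv["p_value"]
    ranking = rank_importance(est.importances_, pvals)
    result = FitResult(
        trial=trial,
        treatment=treatment,
        hours_mode=hours_mode,
        oob_r2=est.oob_r2_,
        oob_mse=est.oob_mse_,
        val_r2=est.val_r2_,
        val_mse=est.val_mse_,
        n_calibration=est.n_calibration_,
        n_validation=est.n_validation_,
        importance=ranking,
        seed=seed,
    )
    return est, result


def run_study(
    tables: dict[tuple[str, str], tuple[pd.DataFrame, Sequence[tuple] | None]],
    out_dir: str | Path | None = None,
    n_trees: int = 500,
    mtry: int = 4,
    seed: int = 0,
    with_pvalues: bool = False,
    n_perm: int = 100,
    pdp_predictors: Sequence[str] = (),
) -> dict:
    """Fit the full model family: each (trial, treatment) in AH and GH mode.

    ``tables`` maps ``(trial, treatment)`` to ``(model_table,
    grazing_intervals)``. Four trials x two treatments x {AH, GH} gives the
    sixteen-model family; cells whose table is too small or whose GH subset is
    empty are skipped with a warning. Returns a bundle with the performance
    table (one row per model), the ranking table (12 predictors x models) and
    optional PDP curves; writes CSVs when ``out_dir`` is given.
    """
    results: list[FitResult] = []
    pdps: dict[str, pd.DataFrame] = {}
    model_seed = seed
    for (trial, treatment), (rows, grazing) in sorted(tables.items()):
        for mode in ("AH", "GH"):
            model_seed += 1
            try:
                subset = subset_grazing_hours(rows, grazing, mode=mode)
                est, res = fit_rf(
                    subset,
                    trial=trial,
                    treatment=treatment,
                    hours_mode=mode,
                    n_trees=n_trees,
                    mtry=mtry,
                    seed=model_seed,
                    with_pvalues=with_pvalues,
                    n_perm=n_perm,
                )
            except ValueError as err:
                warnings.warn(f"skipping {trial}/{treatment}/{mode}: {err}", stacklevel=2)
                continue
            results.append(res)
            for pred in pdp_predictors:
                curve = est.partial_dependence(subset[PREDICTORS], pred)
                pdps[f"{trial}_{treatment}_{mode}_{pred}"] = curve

    performance = pd.DataFrame(
        {
            "model": [f"{r.trial}_{r.treatment}_{r.hours_mode}" for r in results],
            "oob_r2": [r.oob_r2 for r in results],
            "oob_mse": [r.oob_mse for r in results],
            "val_r2": [r.val_r2 for r in results],
            "val_mse": [r.val_mse for r in results],
            "n_calibration": [r.n_calibration for r in results],
            "n_validation": [r.n_validation for r in results],
        }
    )
    ranking = {}
    for r in results:
        col = r.importance.set_index("predictor")["rank"].astype(str)
        if "significant" in r.importance.columns:
            stars = r.importance.set_index("predictor")["significant"].map({True: "*", False: ""})
            col = col + stars
        ranking[f"{r.trial}_{r.treatment}_{r.hours_mode}"] = col
    ranking = pd.DataFrame(ranking)

    bundle = {"performance": performance, "ranking": ranking, "results": results, "pdps": pdps,
              "seed": seed}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        performance.to_csv(out_dir / "model_performance.csv", index=False)
        ranking.to_csv(out_dir / "importance_ranking.csv")
        for name, curve in pdps.items():
            curve.to_csv(out_dir / f"pdp_{name}.csv", index=False)
    return bundle
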