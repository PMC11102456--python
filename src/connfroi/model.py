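"""Ridge models predicting contrast maps from connectivity features, with
nested leave-one-subject-out (LOSO) cross-validation for the penalty.

Training rows are the stacked search-space vertices of the training
subjects. Features are standardized by training mean/SD (zero-SD columns
dropped), the intercept is the training target mean and is unpenalized.
The penalty grid is 100 logarithmically spaced values spanning 1e-5 to
1e2; the inner LOSO loop picks the value minimizing held-out mean squared
error (ties go to the smaller penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LambdaGrid",
    "RidgeModel",
    "CVReport",
    "lambda_grid",
    "ridge_fit",
    "select_lambda_inner",
    "loso_predict",
    "fit_final_model",
]

_ZERO_SD_TOL = 1e-12


@dataclass(frozen=True)
class LambdaGrid:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least 2 values")
        if np.any(np.diff(v) <= 0):
            raise ValueError("grid must be strictly increasing")
        ratios = v[1:] / v[:-1]
        if np.max(np.abs(ratios - ratios[0])) > 1e-9 * ratios[0]:
            raise ValueError("grid must be logarithmically spaced")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def lambda_grid(n: int = 100, lo: float = 1e-5, hi: float = 1e2) -> LambdaGrid:
    """Logarithmically spaced penalty grid (default 100 points, 1e-5..1e2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    return LambdaGrid(values=np.logspace(np.log10(lo), np.log10(hi), n))


@dataclass
class RidgeModel:
    """Fitted ridge model with its training standardization statistics."""

    weights: np.ndarray            # on standardized features, kept columns only
    intercept: float
    lam: float
    mean: np.ndarray               # training column means (kept columns)
    sd: np.ndarray                 # training column SDs (kept columns)
    columns: tuple[str, ...]       # kept column names
    dropped_columns: tuple[str, ...] = ()
    froi_id: str = ""
    training_subjects: tuple[str, ...] = ()

    def predict(self, X: np.ndarray, columns: tuple[str, ...] | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if columns is not None and tuple(columns) != self.columns:
            lookup = {c: i for i, c in enumerate(columns)}
            try:
                X = X[:, [lookup[c] for c in self.columns]]
            except KeyError as exc:
                raise ValueError(f"prediction input missing column {exc}") from exc
        elif X.shape[1] != len(self.columns):
            raise ValueError("feature count mismatch; pass column names to map")
        return self.intercept + ((X - self.mean) / self.sd) @ self.weights

    @property
    def raw_weights(self) -> np.ndarray:
        """Weights expressed on the unstandardized feature scale."""
        return self.weights / self.sd


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > _ZERO_SD_TOL
    return mean, sd, keep


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    columns: tuple[str, ...] | None = None,
    standardize: bool = True,
    fit_intercept: bool = True,
    froi_id: str = "",
    training_subjects: tuple[str, ...] = (),
) -> RidgeModel:
    """Solve ``(X'X + lam I) w = X'y`` on (optionally standardized) features.

    Zero-SD columns are dropped from the fit and recorded on the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValueError("X rows must match y with at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.isfinite(lam)):
        raise ValueError("non-finite inputs")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if columns is None:
        columns = tuple(f"f{i}" for i in range(X.shape[1]))

    if standardize:
        mean, sd, keep = _standardize_stats(X)
        dropped = tuple(c for c, k in zip(columns, keep) if not k)
        kept_cols = tuple(c for c, k in zip(columns, keep) if k)
        Xs = (X[:, keep] - mean[keep]) / sd[keep]
        mean, sd = mean[keep], sd[keep]
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
        dropped, kept_cols, Xs = (), tuple(columns), X

    intercept = float(y.mean()) if fit_intercept else 0.0
    yc = y - intercept
    G = Xs.T @ Xs + lam * np.eye(Xs.shape[1])
    w = np.linalg.solve(G, Xs.T @ yc)
    return RidgeModel(
        weights=w,
        intercept=intercept,
        lam=float(lam),
        mean=mean,
        sd=sd,
        columns=kept_cols,
        dropped_columns=dropped,
        froi_id=froi_id,
        training_subjects=tuple(training_subjects),
    )


class _SubjectStats:
    """Per-subject raw cross-products enabling fast fold-wise ridge."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] == 0:
            raise ValueError("subject with empty or mismatched search-space data")
        self.n = self.X.shape[0]
        self.colsum = self.X.sum(axis=0)
        self.gram = self.X.T @ self.X
        self.xy = self.X.T @ self.y
        self.ysum = float(self.y.sum())
        self.yss = float(self.y @ self.y)


def _fold_solver(stats: list[_SubjectStats], lams: np.ndarray):
    """Closure evaluating ridge weights for a training subset over all lams.

    Returns (predict_fn, mean, sd, keep): ``predict_fn(Xv)`` yields an
    (n_val, n_lams) prediction matrix.
    """
    n = sum(s.n for s in stats)
    colsum = sum(s.colsum for s in stats)
    gram = sum(s.gram for s in stats)
    xy = sum(s.xy for s in stats)
    ysum = sum(s.ysum for s in stats)

    mu = colsum / n
    var = np.clip(np.diag(gram) / n - mu**2, 0.0, None)
    sd = np.sqrt(var)
    keep = sd > _ZERO_SD_TOL
    ybar = ysum / n

    Gc = gram - n * np.outer(mu, mu)
    Gs = Gc[np.ix_(keep, keep)] / np.outer(sd[keep], sd[keep])
    rhs = (xy - mu * ysum)[keep] / sd[keep]

    evals, Q = np.linalg.eigh(Gs)
    evals = np.clip(evals, 0.0, None)
    qr = Q.T @ rhs
    # (kept, n_lams) weight matrix for all penalties at once
    W = Q @ (qr[:, None] / (evals[:, None] + lams[None, :]))

    def predict(Xv: np.ndarray) -> np.ndarray:
        Xs = (Xv[:, keep] - mu[keep]) / sd[keep]
        return ybar + Xs @ W

    return predict, mu, sd, keep


def select_lambda_inner(
    data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    grid: LambdaGrid,
    *,
    inner_mse: str = "fold_mean",
) -> tuple[float, pd.DataFrame]:
    """Inner LOSO selection of the penalty.

    Each training subject is left out once; for every grid value the model
    is fit on the remaining subjects' stacked vertices and scored by MSE on
    the left-out subject. ``inner_mse='fold_mean'`` averages fold MSEs
    before the argmin; ``'pooled'`` pools squared errors over all held-out
    vertices. Ties select the smaller penalty.
    """
    ids = sorted(data)
    if len(ids) < 2:
        raise ValueError("inner cross-validation needs at least 2 subjects")
    if inner_mse not in ("fold_mean", "pooled"):
        raise ValueError("inner_mse must be 'fold_mean' or 'pooled'")
    lams = np.asarray(grid.values)
    stats = {sid: _SubjectStats(*data[sid]) for sid in ids}

    rows = []
    sq_err = np.zeros(len(lams))
    n_val_total = 0
    for sid in ids:
        predict, *_ = _fold_solver([stats[s] for s in ids if s != sid], lams)
        Xv, yv = stats[sid].X, stats[sid].y
        err2 = (yv[:, None] - predict(Xv)) ** 2
        sq_err += err2.sum(axis=0)
        n_val_total += len(yv)
        rows.append(err2.mean(axis=0))

    table = pd.DataFrame(rows, index=pd.Index(ids, name="left_out"), columns=lams)
    if inner_mse == "fold_mean":
        mean_mse = table.to_numpy().mean(axis=0)
    else:
        mean_mse = sq_err / n_val_total
    best = int(np.argmin(mean_mse))  # first minimum = smallest lam on ties
    return float(lams[best]), table


@dataclass
class CVReport:
    """Outer LOSO results for one region."""

    froi_id: str
    folds: pd.DataFrame                      # subject, lam columns
    predictions: dict[str, np.ndarray]       # left-out subject -> predicted map
    inner_mse: dict[str, pd.DataFrame] = field(default_factory=dict)
    models: dict[str, RidgeModel] = field(default_factory=dict)


def loso_predict(
    data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    grid: LambdaGrid,
    *,
    columns: tuple[str, ...] | None = None,
    froi_id: str = "",
    inner_mse: str = "fold_mean",
    keep_models: bool = False,
) -> CVReport:
    """Nested LOSO: per outer fold, pick the penalty by inner LOSO over the
    training subjects, fit on their stacked vertices and predict the
    left-out subject's map."""
    ids = sorted(data)
    if len(ids) < 3:
        raise ValueError("nested LOSO needs at least 3 subjects")
    for sid in ids:
        if len(data[sid][1]) == 0:
            raise ValueError(f"subject {sid} has empty search-space data")

    fold_rows = []
    predictions: dict[str, np.ndarray] = {}
    inner_tables: dict[str, pd.DataFrame] = {}
    models: dict[str, RidgeModel] = {}
    for sid in ids:
        train = {s: data[s] for s in ids if s != sid}
        lam, table = select_lambda_inner(train, grid, inner_mse=inner_mse)
        X = np.vstack([train[s][0] for s in sorted(train)])
        y = np.concatenate([train[s][1] for s in sorted(train)])
        model = ridge_fit(
            X, y, lam, columns=columns, froi_id=froi_id,
            training_subjects=tuple(sorted(train)),
        )
        predictions[sid] = model.predict(data[sid][0], columns=columns)
        fold_rows.append({"subject": sid, "lam": lam})
        inner_tables[sid] = table
        if keep_models:
            models[sid] = model
    return CVReport(
        froi_id=froi_id,
        folds=pd.DataFrame(fold_rows),
        predictions=predictions,
        inner_mse=inner_tables,
        models=models,
    )


def fit_final_model(
    data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    grid: LambdaGrid,
    *,
    columns: tuple[str, ...] | None = None,
    froi_id: str = "",
    inner_mse: str = "fold_mean",
) -> RidgeModel:
    """All-subject model: penalty chosen by LOSO over the full set, then
    fit on everyone's stacked vertices."""
    ids = sorted(data)
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects")
    lam, _ = select_lambda_inner(data, grid, inner_mse=inner_mse)
    X = np.vstack([data[s][0] for s in ids])
    y = np.concatenate([data[s][1] for s in ids])
    return ridge_fit(X, y, lam, columns=columns, froi_id=froi_id, training_subjects=tuple(ids))
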