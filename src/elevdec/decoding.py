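"""LASSO decoding of a continuous emotion score from band-power features.

The decoder fits

    w = argmin ||y - Xw - b||^2 + lambda * ||w||_1

mapping per-second group-level EEG features X to the per-second emotion
score y, and evaluates it by repeated k-fold cross-validation (5 folds,
100 repetitions by default).  Within every training portion, features are
z-scored with training statistics and lambda is chosen on a 50-point
logarithmic grid from lambda_max down to 1e-3*lambda_max by inner 5-fold
cross-validated NMSE, ties broken toward the larger (sparser) lambda.
Reported per-fold metrics are the test-fold Pearson r and the NMSE
(test MSE divided by the population variance of the test targets, so a
constant mean prediction scores exactly 1).

Univariate feature-score Pearson correlation maps with Bonferroni-corrected
significance are also provided for topography-style summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "LassoModel",
    "CVConfig",
    "DecodingResult",
    "lambda_max",
    "make_lambda_grid",
    "fit_lasso",
    "nmse",
    "select_lambda",
    "cross_validated_decode",
    "correlation_map",
]


class DecodingError(ValueError):
    """Invalid decoding inputs (misaligned, degenerate or non-finite)."""


@dataclass(frozen=True)
class LassoModel:
    """Fitted coefficients, bias and penalty of one LASSO solution."""

    coef: np.ndarray
    intercept: float
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of features with nonzero coefficients."""
        return self.coef != 0


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold cross-validation settings."""

    n_folds: int = 5
    n_repeats: int = 100
    inner_folds: int = 5
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.inner_folds < 2:
            raise DecodingError("n_folds and inner_folds must be >= 2")
        if self.n_repeats < 1 or self.n_lambdas < 1:
            raise DecodingError("n_repeats and n_lambdas must be >= 1")
        if not 0 < self.lambda_min_ratio <= 1:
            raise DecodingError("lambda_min_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class DecodingResult:
    """Per-fold metrics, aggregates and the final all-data model.

    ``fold_metrics`` has one row per (repeat, fold) with the selected
    lambda, test Pearson r (NaN when the prediction or target is constant),
    test NMSE and the nonzero-coefficient count.  Aggregates are computed
    over all defined fold-level values and over per-repeat means.
    """

    fold_metrics: pd.DataFrame
    final_model: LassoModel
    feature_labels: tuple[str, ...]

    def summary(self) -> dict[str, float]:
        fm = self.fold_metrics
        r = fm["r"].to_numpy(dtype=float)
        valid = np.isfinite(r)
        repeat_means = fm[np.isfinite(fm["r"])].groupby("repeat")["r"].mean()
        return {
            "r_mean": float(np.mean(r[valid])) if valid.any() else float("nan"),
            "r_sd": float(np.std(r[valid], ddof=1)) if valid.sum() > 1 else float("nan"),
            "r_mean_over_repeats": float(repeat_means.mean()) if len(repeat_means) else float("nan"),
            "r_sd_over_repeats": float(repeat_means.std(ddof=1)) if len(repeat_means) > 1 else float("nan"),
            "nmse_mean": float(fm["nmse"].mean()),
            "nmse_sd": float(fm["nmse"].std(ddof=1)),
            "n_folds_total": int(len(fm)),
            "n_r_missing": int((~valid).sum()),
        }

    def coefficient_table(self) -> pd.DataFrame:
        """Final-model coefficients per feature (original feature units)."""
        return pd.DataFrame(
            {"feature": list(self.feature_labels),
             "coefficient": self.final_model.coef,
             "selected": self.final_model.support}
        )


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DecodingError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] == 0:
        raise DecodingError("X has zero rows")
    if X.shape[0] != len(y):
        raise DecodingError(f"X has {X.shape[0]} rows but y has {len(y)}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DecodingError("non-finite values in X or y")
    return X, y


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the solution is entirely zero.

    For the objective ||y - Xw - b||^2 + lam*||w||_1 this is
    2 * max_j |X_c[:, j]^T (y - mean(y))| with column-centered X.
    """
    X, y = _check_xy(X, y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(2.0 * np.max(np.abs(Xc.T @ yc)))


def make_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 50, min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(X, y)
    if lmax == 0:
        raise DecodingError("lambda_max is 0: y is constant or X is uncorrelated")
    return np.logspace(np.log10(lmax), np.log10(lmax * min_ratio), n_lambdas)


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> LassoModel:
    """Minimize ||y - Xw - b||^2 + lam*||w||_1 at a fixed penalty.

    ``lam = 0`` reduces to ordinary least squares.  X is used as given;
    standardize beforehand if the penalty should act uniformly across
    features (the cross-validation driver does this with training-fold
    statistics).
    """
    X, y = _check_xy(X, y)
    if lam < 0:
        raise DecodingError(f"lambda must be >= 0, got {lam}")
    n = X.shape[0]
    if lam == 0:
        A = np.column_stack([X, np.ones(n)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return LassoModel(coef=beta[:-1], intercept=float(beta[-1]), lam=0.0)
    # sklearn minimizes 1/(2n)*||r||^2 + alpha*||w||_1  =>  alpha = lam/(2n)
    est = Lasso(alpha=lam / (2 * n), fit_intercept=True,
                max_iter=100_000, tol=1e-10)
    est.fit(X, y)
    return LassoModel(coef=est.coef_.copy(), intercept=float(est.intercept_),
                      lam=float(lam))


def nmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Normalized MSE: mean squared error over the variance of ``y_true``.

    Population variance, so predicting ``mean(y_true)`` scores exactly 1
    and a perfect prediction scores 0.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise DecodingError("y_true and y_pred differ in length")
    var = y_true.var()
    if var == 0:
        raise DecodingError("zero variance in y_true: NMSE undefined")
    return float(np.mean((y_true - y_pred) ** 2) / var)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _path_coefs(Xs: np.ndarray, yc: np.ndarray, grid: np.ndarray,
                tol: float = 1e-4) -> np.ndarray:
    """Coefficients (n_features, n_lambdas) along a descending grid.

    Expects standardized X and centered y (no intercept in the path).
    """
    n = Xs.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(Xs, yc, alphas=grid / (2 * n),
                                 precompute=True, tol=tol)
    return coefs


def select_lambda(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: Sequence[float],
    inner_folds: int = 5,
    rng_seed: int = 0,
) -> float:
    """Pick the grid penalty minimizing inner-cross-validated NMSE.

    The grid must be descending; ties break toward the larger (sparser)
    penalty.  Standardization inside each inner fold uses that fold's
    training statistics only.
    """
    X_train, y_train = _check_xy(X_train, y_train)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DecodingError("empty lambda grid")
    if grid.size == 1:
        return float(grid[0])
    if y_train.var() == 0:
        raise DecodingError("degenerate training target (zero variance)")
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=rng_seed)
    total = np.zeros(grid.size)
    n_used = 0
    for tri, tei in kf.split(X_train):
        ytr, yte = y_train[tri], y_train[tei]
        if yte.var() == 0:
            continue
        mu, sd = _standardize_fit(X_train[tri])
        Xs = (X_train[tri] - mu) / sd
        coefs = _path_coefs(Xs, ytr - ytr.mean(), grid)
        preds = ((X_train[tei] - mu) / sd) @ coefs + ytr.mean()
        mses = np.mean((yte[:, None] - preds) ** 2, axis=0)
        total += mses / yte.var()
        n_used += 1
    if n_used == 0:
        raise DecodingError("all inner folds had constant targets")
    return float(grid[np.argmin(total)])  # first minimum = largest lambda


def _safe_pearson(a: np.ndarray, b: np.ndarray, rel_tol: float = 0.0,
                  scale: float = 1.0) -> float:
    """Pearson r, NaN when either input is (numerically) constant.

    ``rel_tol * scale`` guards against predictions whose variance is pure
    solver round-off (coefficients that should be exactly zero).
    """
    if a.std() <= rel_tol * scale or b.std() <= rel_tol * scale:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cross_validated_decode(
    X: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig = CVConfig(),
    feature_labels: Sequence[str] | None = None,
) -> DecodingResult:
    """Repeated k-fold cross-validated LASSO decoding.

    For each repeat a fresh random fold partition is drawn; within each
    fold, lambda selection, feature standardization and fitting use the
    training portion only.  Folds whose test target or prediction is
    constant get r = NaN and are excluded from r aggregation (NMSE is
    still defined unless the target is constant, in which case the fold
    is skipped with a warning).  A fixed ``cfg.rng_seed`` makes the whole
    procedure deterministic.
    """
    X, y = _check_xy(X, y)
    if feature_labels is None:
        feature_labels = tuple(f"f{i}" for i in range(X.shape[1]))
    else:
        feature_labels = tuple(feature_labels)
        if len(feature_labels) != X.shape[1]:
            raise DecodingError("feature_labels length mismatch")
    # deterministic per-repeat / per-fold seeds below 2**31
    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(
        2 * cfg.n_repeats + 1) % (2**31)
    rows = []
    for rep in range(cfg.n_repeats):
        kf = KFold(n_splits=cfg.n_folds, shuffle=True,
                   random_state=int(seeds[2 * rep]))
        for fold, (tri, tei) in enumerate(kf.split(X)):
            Xtr, ytr = X[tri], y[tri]
            Xte, yte = X[tei], y[tei]
            if yte.var() == 0 or ytr.var() == 0:
                warnings.warn(
                    f"repeat {rep} fold {fold}: constant target, fold skipped",
                    stacklevel=2,
                )
                continue
            mu, sd = _standardize_fit(Xtr)
            Xs = (Xtr - mu) / sd
            yc = ytr - ytr.mean()
            lmax = 2.0 * np.max(np.abs(Xs.T @ yc))
            grid = np.logspace(np.log10(lmax),
                               np.log10(lmax * cfg.lambda_min_ratio),
                               cfg.n_lambdas)
            lam = select_lambda(Xtr, ytr, grid, cfg.inner_folds,
                                rng_seed=int(seeds[2 * rep + 1]))
            coef = _path_coefs(Xs, yc, np.array([lam]), tol=1e-6)[:, 0]
            pred = ((Xte - mu) / sd) @ coef + ytr.mean()
            rows.append({
                "repeat": rep,
                "fold": fold,
                "lambda": lam,
                "r": _safe_pearson(yte, pred, rel_tol=1e-10, scale=ytr.std()),
                "nmse": nmse(yte, pred),
                "n_nonzero": int(np.count_nonzero(coef)),
            })
    fold_metrics = pd.DataFrame(
        rows, columns=["repeat", "fold", "lambda", "r", "nmse", "n_nonzero"]
    )
    # final model on all data, lambda selected by inner CV on all data
    grid = make_lambda_grid(X, y, cfg.n_lambdas, cfg.lambda_min_ratio)
    lam = select_lambda(X, y, grid, cfg.inner_folds, rng_seed=int(seeds[-1]))
    mu, sd = _standardize_fit(X)
    coef_std = _path_coefs((X - mu) / sd, y - y.mean(),
                           np.array([lam]), tol=1e-6)[:, 0]
    coef = coef_std / sd  # back to original feature units
    intercept = float(y.mean() - mu @ coef)
    final = LassoModel(coef=coef, intercept=intercept, lam=float(lam))
    return DecodingResult(fold_metrics=fold_metrics, final_model=final,
                          feature_labels=feature_labels)


def correlation_map(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    feature_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Univariate Pearson r and p per feature, Bonferroni-flagged.

    Significance requires p < alpha / n_features.  Constant feature
    columns get r = NaN and are never significant.
    """
    X, y = _check_xy(X, y)
    n, m = X.shape
    if n < 3:
        raise DecodingError("need at least 3 samples for correlation")
    if y.std() == 0:
        raise DecodingError("constant target: correlations undefined")
    if feature_labels is None:
        feature_labels = [f"f{i}" for i in range(m)]
    elif len(feature_labels) != m:
        raise DecodingError("feature_labels length mismatch")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xnorm = np.sqrt((Xc ** 2).sum(axis=0))
    ynorm = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (xnorm * ynorm)
    r = np.where(xnorm == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    # two-sided p from the t distribution with n-2 dof
    p = 2 * special.stdtr(n - 2, -np.abs(t))
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    threshold = alpha / m
    significant = np.where(np.isnan(p), False, p < threshold)
    return pd.DataFrame({
        "feature": list(feature_labels),
        "r": r,
        "p": p,
        "significant": significant.astype(bool),
    })
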