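"""Gaussian-kernel partial least squares (KPLS) regression.

Predicts the pre-to-post-treatment change in the Vineland Adaptive Behavior
Composite from pre-to-post changes in a subset of FOCM/TS measurements.  The
predictors are mapped through a Gaussian kernel, K[i,j] =
exp(-||x_i - x_j||^2 / (2 w^2)), and PLS proceeds in the dual: each latent
score direction t maximizes covariance between the centered kernel and the
(deflated) response, the kernel and response are deflated by the extracted
score, and the dual regression coefficients are recovered from the collected
score/residual-response pairs.  A linear kernel (K = X X') is kept solely as
a test oracle: with a full set of components it reproduces ordinary least
squares on full-rank data.

Predictors are z-scored and the response centered with parameters estimated
on training samples only; leave-one-out cross-validation refits both inside
every fold.  The kernel width defaults to the median pairwise Euclidean
distance among the normalized training vectors — scale-adaptive and
deterministic — and the number of latent components defaults to an inner
leave-one-out sweep on the first training fold, then held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance

#: Largest component count the automatic inner sweep will consider.
MAX_AUTO_COMPONENTS = 10
#: Score-norm tolerance below which the component extraction stops (rank exhausted).
RANK_TOL = 1e-12


def gaussian_kernel_matrix(A: np.ndarray, B: np.ndarray, width: float) -> np.ndarray:
    """K[i,j] = exp(-||a_i - b_j||^2 / (2 width^2)); symmetric PSD when A is B."""
    if width <= 0:
        raise ValueError("kernel width must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimensionality mismatch between A and B")
    sq = scipy.spatial.distance.cdist(A, B, "sqeuclidean")
    return np.exp(-sq / (2.0 * width * width))


def linear_kernel_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """K = A B' — test-oracle kernel equivalent to linear PLS."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return A @ B.T


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median Euclidean distance over all sample pairs; 1.0 for degenerate sets."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(X) < 2:
        return 1.0
    d = scipy.spatial.distance.pdist(X, "euclidean")
    med = float(np.median(d))
    return med if med > 0 else 1.0


def _center_train_kernel(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    col = K.mean(axis=0, keepdims=True)
    row = K.mean(axis=1, keepdims=True)
    return K - col - row + K.mean()

def _center_test_kernel(Kt: np.ndarray, K_train: np.ndarray) -> np.ndarray:
    M = Kt - K_train.mean(axis=0, keepdims=True)
    return M - M.mean(axis=1, keepdims=True)


@dataclass
class KplsModel:
    """Fitted dual-form KPLS model over a predictor subset."""

    subset: tuple[str, ...] | None
    kernel: str
    width: float
    n_components: int
    X_train: np.ndarray       # normalized training predictors
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    dual_coefs: np.ndarray    # length-n dual regression vector
    scores: np.ndarray        # T, n x p latent scores (truncation support)
    residual_responses: np.ndarray  # U, n x p deflated responses
    K_train: np.ndarray       # uncentered training kernel (for test centering)
    fitted: np.ndarray

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "gaussian":
            return gaussian_kernel_matrix(A, B, self.width)
        return linear_kernel_matrix(A, B)

    def predict(self, X_new: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Predict responses for raw (unnormalized) predictor vectors."""
        if isinstance(X_new, pd.DataFrame):
            X_new = X_new[list(self.subset)].to_numpy(dtype=float)
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"expected {self.X_train.shape[1]} predictors, got {X_new.shape[1]}"
            )
        Z = (X_new - self.x_mean) / self.x_std
        Kt = self._kernel(Z, self.X_train)
        Ktc = _center_test_kernel(Kt, self.K_train)
        return Ktc @ self.dual_coefs + self.y_mean


def _extract_components(Kc: np.ndarray, yc: np.ndarray, n_components: int,
                        warn_truncation: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Iterate score extraction with kernel/response deflation.

    Returns (T, U): latent scores and the deflated responses they were
    extracted from.  Stops early (with a warning) when the response residual
    is exhausted — requesting more components than the data's rank supports.
    """
    n = Kc.shape[0]
    Kd = Kc.copy()
    yr = yc.astype(float).copy()
    T, U = [], []
    for _ in range(n_components):
        t = Kd @ yr
        nt = np.linalg.norm(t)
        if nt < RANK_TOL * max(1.0, np.linalg.norm(yr)) or nt == 0.0:
            if warn_truncation:
                warnings.warn(
                    f"component extraction stopped at {len(T)} of {n_components}: "
                    "residual rank exhausted", stacklevel=2)
            break
        t = t / nt
        T.append(t)
        U.append(yr.copy())
        # deflate both kernel and response by the extracted score
        Kt_ = Kd - np.outer(t, t @ Kd)
        Kd = Kt_ - np.outer(Kt_ @ t, t)
        yr = yr - t * (t @ yr)
    if not T:
        return np.zeros((n, 0)), np.zeros((n, 0))
    return np.column_stack(T), np.column_stack(U)


def _dual_coefficients(Kc: np.ndarray, yc: np.ndarray, T: np.ndarray,
                       U: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """d = U (T' Kc U)^-1 T' yc, optionally truncated to fewer components."""
    if n_components is not None:
        T = T[:, :n_components]
        U = U[:, :n_components]
    if T.shape[1] == 0:
        return np.zeros(len(yc))
    A = T.T @ Kc @ U
    b = T.T @ yc
    return U @ scipy.linalg.solve(A, b)


def fit_kpls(X: np.ndarray | pd.DataFrame, y: np.ndarray,
             subset: list[str] | None = None,
             n_components: int = 2,
             width: float | str = "median",
             kernel: str = "gaussian") -> KplsModel:
    """Fit dual-form KPLS on raw predictors and responses.

    Predictors are z-scored (sample sd) and the response centered internally;
    the parameters are stored on the model and reused at prediction time.
    `width="median"` uses the median pairwise distance of the normalized
    training vectors.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(subset) if subset is not None else list(X.columns)
        X = X[cols].to_numpy(dtype=float)
        subset = cols
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(X)
    if len(y) != n:
        raise ValueError("X and y must have equal length")
    if n_components > n - 1:
        warnings.warn(f"components truncated from {n_components} to {n - 1}", stacklevel=2)
        n_components = n - 1
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    x_std[x_std == 0] = 1.0
    Z = (X - x_mean) / x_std
    y_mean = float(y.mean())
    yc = y - y_mean

    if width == "median":
        width_val = median_pairwise_distance(Z)
    else:
        width_val = float(width)
    if kernel == "gaussian":
        K = gaussian_kernel_matrix(Z, Z, width_val)
    elif kernel == "linear":
        K = linear_kernel_matrix(Z, Z)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    Kc = _center_train_kernel(K)
    T, U = _extract_components(Kc, yc, n_components, warn_truncation=(yc.std() > 0))
    dual = _dual_coefficients(Kc, yc, T, U)
    fitted = Kc @ dual + y_mean
    return KplsModel(
        subset=tuple(subset) if subset is not None else None,
        kernel=kernel, width=width_val, n_components=T.shape[1],
        X_train=Z, x_mean=x_mean, x_std=x_std, y_mean=y_mean,
        dual_coefs=dual, scores=T, residual_responses=U,
        K_train=K, fitted=fitted,
    )


def _loo_predictions_nested(X: np.ndarray, y: np.ndarray, max_components: int,
                            width: float | str, kernel: str) -> np.ndarray:
    """LOO predictions for every truncation 1..max_components at once.

    One fit per fold at the maximum component count yields nested predictions
    for all smaller counts, since truncating the score/response factor pairs
    reproduces the smaller model exactly.
    Returns an (n, max_components) array.
    """
    n = len(X)
    preds = np.full((n, max_components), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_kpls(X[mask], y[mask], n_components=max_components,
                             width=width, kernel=kernel)
        Z_i = (X[i:i + 1] - model.x_mean) / model.x_std
        Kt = model._kernel(Z_i, model.X_train)
        Ktc = _center_test_kernel(Kt, model.K_train)
        Kc = _center_train_kernel(model.K_train)
        yc = y[mask] - model.y_mean
        for c in range(1, max_components + 1):
            d = _dual_coefficients(Kc, yc, model.scores, model.residual_responses,
                                   n_components=min(c, model.scores.shape[1]))
            preds[i, c - 1] = float((Ktc @ d)[0]) + model.y_mean
    return preds


def choose_components(X: np.ndarray, y: np.ndarray,
                      width: float | str = "median",
                      kernel: str = "gaussian",
                      max_components: int | None = None) -> int:
    """Select the component count minimizing inner-LOO squared error."""
    n = len(X)
    if max_components is None:
        max_components = min(MAX_AUTO_COMPONENTS, n - 2)
    max_components = max(1, max_components)
    preds = _loo_predictions_nested(np.asarray(X, float), np.asarray(y, float),
                                    max_components, width, kernel)
    press = ((preds - np.asarray(y, float)[:, None]) ** 2).sum(axis=0)
    return int(np.argmin(press)) + 1


def loo_r2(X: np.ndarray | pd.DataFrame, y: np.ndarray,
           subset: list[str] | None = None,
           n_components: int | str = "auto",
           width: float | str = "median",
           kernel: str = "gaussian",
           return_predictions: bool = False):
    """Leave-one-out cross-validated R^2.

    Each sample is predicted by a model fit (normalization, width, and dual
    coefficients all re-estimated) on the remaining n-1 samples;
    R^2 = 1 - sum (y - yhat_loo)^2 / sum (y - ybar)^2 and may be negative.
    `n_components="auto"` runs the inner selection sweep on the first
    training fold (all samples but the first) and holds the result fixed.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(subset) if subset is not None else list(X.columns)
        X = X[cols].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out R^2 needs at least 3 samples")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")

    if n_components == "auto":
        n_components = choose_components(X[1:], y[1:], width=width, kernel=kernel)
    n_components = int(n_components)

    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_kpls(X[mask], y[mask], n_components=n_components,
                             width=width, kernel=kernel)
        preds[i] = float(model.predict(X[i:i + 1])[0])
    r2 = 1.0 - float(((y - preds) ** 2).sum()) / ss_tot
    if return_predictions:
        return r2, preds
    return r2


def fitted_r2(model: KplsModel, y: np.ndarray) -> float:
    """R^2 of the stored training fit."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float(((y - model.fitted) ** 2).sum()) / ss_tot
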