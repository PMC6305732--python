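"""Two-class Fisher discriminant analysis for ASD/TD separation.

The discriminant direction w maximizes the Rayleigh quotient
J(w) = (w' S_B w) / (w' S_W w) of between- to within-class scatter.  With two
classes S_B has rank one, so the leading eigenvector of S_W^-1 S_B is, up to
scale, S_W^-1 (mean_ASD - mean_TD); the solver works on the equivalent
symmetric generalized eigenproblem for numerical stability.

Scatter matrices carry class-size prefactors: S_B weights each class's mean
deviation by its sample count, and S_W likewise multiplies each class's
summed outer-product scatter by the class size.  The prefactors rescale the
matrices without changing the two-class discriminant direction.

Orientation convention: the ASD cohort sits on the positive score axis
(mean score of ASD training samples exceeds the TD mean), which keeps the
downstream null-hypothesis threshold and Type II error definitions
unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .preprocessing import NormalizationParams, PanelError

#: Ridge scale for near-singular within-class scatter: eps = RIDGE * tr(S_W)/m.
RIDGE = 1e-8


class DegenerateFitError(ValueError):
    """Raised when the two cohorts cannot be separated (e.g. identical means)."""


def split_cohorts(table: pd.DataFrame, subset: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Return (X_ASD, X_TD) matrices over the named measure subset."""
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise PanelError(f"unknown measures: {missing}")
    X_asd = table.loc[table["cohort"] == "ASD", subset].to_numpy(dtype=float)
    X_td = table.loc[table["cohort"] == "TD", subset].to_numpy(dtype=float)
    if len(X_asd) == 0 or len(X_td) == 0:
        raise ValueError("both cohorts must be non-empty")
    return X_asd, X_td


def scatter_matrices(X_asd: np.ndarray, X_td: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-class scatter with class-size prefactors.

    S_B = n_ASD (m_ASD - m)'(m_ASD - m) + n_TD (m_TD - m)'(m_TD - m)
    S_W = n_ASD sum_i (x_i - m_ASD)'(x_i - m_ASD)  over ASD rows
        + n_TD  sum_i (x_i - m_TD)'(x_i - m_TD)    over TD rows
    """
    X_asd = np.atleast_2d(np.asarray(X_asd, dtype=float))
    X_td = np.atleast_2d(np.asarray(X_td, dtype=float))
    n_asd, n_td = len(X_asd), len(X_td)
    if n_asd == 0 or n_td == 0:
        raise ValueError("both cohorts must be non-empty")
    m_asd = X_asd.mean(axis=0)
    m_td = X_td.mean(axis=0)
    m_all = (n_asd * m_asd + n_td * m_td) / (n_asd + n_td)
    d_asd = (m_asd - m_all)[:, None]
    d_td = (m_td - m_all)[:, None]
    s_b = n_asd * (d_asd @ d_asd.T) + n_td * (d_td @ d_td.T)
    c_asd = X_asd - m_asd
    c_td = X_td - m_td
    s_w = n_asd * (c_asd.T @ c_asd) + n_td * (c_td.T @ c_td)
    return s_b, s_w


@dataclass
class FdaModel:
    """Fitted Fisher discriminant: direction, normalization, training scores."""

    subset: tuple[str, ...]
    w: np.ndarray
    norm: NormalizationParams
    t_asd: np.ndarray
    t_td: np.ndarray
    j_value: float

    def score(self, X: np.ndarray) -> np.ndarray:
        """Project normalized measurement vectors onto w: t = x . w."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != len(self.w):
            raise ValueError(
                f"expected vectors of length {len(self.w)}, got {X.shape[-1]}"
            )
        return X @ self.w

    def score_panels(self, table: pd.DataFrame) -> np.ndarray:
        """Normalize raw panels with the frozen training params, then score."""
        cols = list(self.subset)
        X = table[cols].to_numpy(dtype=float)
        idx = [self.norm.measures.index(c) for c in cols]
        Z = (X - self.norm.mean[idx]) / self.norm.std[idx]
        return self.score(Z)

    def to_json(self) -> str:
        return json.dumps({
            "subset": list(self.subset),
            "w": self.w.tolist(),
            "norm": self.norm.to_dict(),
            "t_asd": self.t_asd.tolist(),
            "t_td": self.t_td.tolist(),
            "j_value": self.j_value,
            "orientation": "ASD-positive",
        })

    @classmethod
    def from_json(cls, s: str) -> "FdaModel":
        d = json.loads(s)
        return cls(
            subset=tuple(d["subset"]),
            w=np.asarray(d["w"]),
            norm=NormalizationParams.from_dict(d["norm"]),
            t_asd=np.asarray(d["t_asd"]),
            t_td=np.asarray(d["t_td"]),
            j_value=float(d["j_value"]),
        )


def fit_direction(X_asd: np.ndarray, X_td: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector of S_W^-1 S_B, unit-norm, ASD-positive.

    Solves the symmetric generalized problem S_B v = λ S_W v after adding a
    relative ridge to S_W. Returns (w, J(w)).
    """
    s_b, s_w = scatter_matrices(X_asd, X_td)
    m = s_w.shape[0]
    eps = RIDGE * np.trace(s_w) / m
    if not np.isfinite(eps) or eps <= 0:
        eps = RIDGE
    s_w_reg = s_w + eps * np.eye(m)
    try:
        vals, vecs = scipy.linalg.eigh(s_b, s_w_reg)
    except scipy.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise DegenerateFitError(f"within-class scatter not invertible: {e}") from None
    w = vecs[:, -1]
    w = w / np.linalg.norm(w)
    num = float(w @ s_b @ w)
    den = float(w @ s_w_reg @ w)
    j = num / den if den > 0 else 0.0
    if j <= 0 or not np.isfinite(j):
        raise DegenerateFitError("identical class means: no discriminant direction")
    mean_diff = X_asd.mean(axis=0) - X_td.mean(axis=0)
    if float(mean_diff @ w) < 0:
        w = -w
    return w, j


def fit_fda(table: pd.DataFrame, subset: list[str], norm: NormalizationParams) -> FdaModel:
    """Fit FDA on a normalized cohort table restricted to a measure subset.

    `table` must already be normalized with `norm` (the frozen training
    parameters are stored on the model so trial data can be scored later).
    """
    subset = list(subset)
    if len(subset) < 1:
        raise ValueError("subset must contain at least one measure")
    X_asd, X_td = split_cohorts(table, subset)
    w, j = fit_direction(X_asd, X_td)
    return FdaModel(
        subset=tuple(subset),
        w=w,
        norm=norm,
        t_asd=X_asd @ w,
        t_td=X_td @ w,
        j_value=j,
    )


def c_statistic(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based AUC: fraction of (pos, neg) pairs with pos > neg, ties 1/2.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg; 0.5 is
    random guessing, 1.0 perfect separation.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    # midranks over the pooled sample give the tie-1/2 convention directly
    pooled = np.concatenate([pos, neg])
    ranks = scipy.stats.rankdata(pooled)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray, positive: str = "ASD") -> dict:
    """TPR/TNR/PPV/NPV and raw counts; undefined rates reported as None.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    p = predicted == positive
    t = truth == positive
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))

    def rate(num, den):
        return num / den if den > 0 else None

    return {
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
        "TPR": rate(tp, tp + fn),
        "TNR": rate(tn, tn + fp),
        "PPV": rate(tp, tp + fp),
        "NPV": rate(tn, tn + fn),
    }
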