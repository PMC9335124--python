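"""Filter feature selection and MinMax scaling.

Five filter scores against binary labels, all "higher is better":

* ``pearson`` — absolute Pearson correlation between feature and label.
* ``fscore`` — the Fisher-style F-score
  ((x+ - x)^2 + (x- - x)^2) / (s2+ + s2-) with per-class unbiased
  variance terms.
* ``chi2`` — Pearson chi-square of the (binned feature x class)
  contingency table.
* ``ig`` — information gain H(Y) - H(Y | X_binned).
* ``mi`` — plug-in mutual information I(X_binned; Y); numerically this
  coincides with ``ig`` under the same binning, both are provided for
  interface completeness.

Continuous descriptor values are discretized by equal-width binning (B=5
by default) for the contingency-based scores.  Constant features score 0
under every method.  Selection keeps the top-n scores (ties broken by
ascending feature index); selected features are then MinMax-scaled to
[0, 1], with application-time clamping for out-of-range values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted, check_X_y

FS_METHODS = ("pearson", "chi2", "ig", "fscore", "mi")


def _bin_feature(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)


def _contingency(xb: np.ndarray, y: np.ndarray, bins: int) -> np.ndarray:
    table = np.zeros((bins, 2))
    for b, c in zip(xb, y):
        table[b, c] += 1
    return table[table.sum(axis=1) > 0]  # drop empty bins


def _chi2_stat(table: np.ndarray) -> float:
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float((((table - expected) ** 2)[mask] / expected[mask]).sum())


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum())


def score_features(X, y, method: str = "pearson", bins: int = 5) -> np.ndarray:
    """Score each feature column against binary labels; higher is better."""
    X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y).astype(int))
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(int)
    n, d = X.shape
    scores = np.zeros(d)
    const = X.std(axis=0) == 0

    if method == "pearson":
        xc = X - X.mean(axis=0)
        yc = y01 - y01.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.abs(xc.T @ yc) / denom
        scores[denom == 0] = 0.0
    elif method == "fscore":
        pos, neg = X[y01 == 1], X[y01 == 0]
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError("fscore needs >= 2 samples per class")
        num = (pos.mean(axis=0) - X.mean(axis=0)) ** 2 + (neg.mean(axis=0) - X.mean(axis=0)) ** 2
        den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = num / den
        scores[den == 0] = 0.0
    elif method in ("chi2", "ig", "mi"):
        for j in range(d):
            if const[j]:
                continue
            table = _contingency(_bin_feature(X[:, j], bins), y01, bins)
            if method == "chi2":
                scores[j] = _chi2_stat(table)
            elif method == "ig":
                py = table.sum(axis=0) / n
                h_y = _entropy(py)
                px = table.sum(axis=1) / n
                h_y_given_x = sum(
                    px[i] * _entropy(table[i] / table[i].sum()) for i in range(table.shape[0])
                )
                scores[j] = h_y - h_y_given_x
            else:
                scores[j] = _mutual_information(table)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {FS_METHODS}")

    scores[const] = 0.0
    return np.where(np.isfinite(scores), scores, 0.0)


def select_top(scores: np.ndarray, n: int = 160) -> np.ndarray:
    """Indices of the n highest scores, ties broken by ascending index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if n >= scores.size:
        return np.arange(scores.size)
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:n])


def minmax_fit(X) -> MinMaxScaler:
    """Fit a [0, 1] MinMax scaler with application-time clamping; constant
    features map to 0."""
    return MinMaxScaler(clip=True).fit(np.asarray(X, dtype=float))


def minmax_apply(scaler: MinMaxScaler, X) -> np.ndarray:
    return scaler.transform(np.asarray(X, dtype=float))


class FilterSelector(BaseEstimator, TransformerMixin):
    """Filter feature selection + MinMax scaling as one sklearn transformer.

    fit(X, y) scores features by ``method``, keeps the top ``n_features``
    (``scores_``, ``selected_idx_``), and fits a MinMax scaler on the
    selected columns; transform selects and scales, clamping to [0, 1].
    """

    def __init__(self, method: str = "pearson", n_features: int = 160, bins: int = 5):
        self.method = method
        self.n_features = n_features
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.scores_ = score_features(X, y, method=self.method, bins=self.bins)
        self.selected_idx_ = select_top(self.scores_, self.n_features)
        self.scaler_ = minmax_fit(X[:, self.selected_idx_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, selector was fitted with {self.n_features_in_}"
            )
        return minmax_apply(self.scaler_, X[:, self.selected_idx_])
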