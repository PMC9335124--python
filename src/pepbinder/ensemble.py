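"""Ensemble RBF-SVM binder classifier with averaging voting.

One submodel is trained per balanced sub-dataset: filter feature selection
(160 features by default) -> MinMax scaling -> RBF-kernel SVM with
grid-searched (c, gamma) and Platt-scaled probabilities.  The ensemble
averages the submodel probabilities; a peptide is called a binder when the
mean probability is at least the threshold ``tp`` (0.5 by default; 0.55 is
the recommended operating point trading a little sensitivity for much
better rejection of non-binders).
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from pepbinder.datasets import SubDataset, build_sub_datasets
from pepbinder.descriptors import encode_many, feature_names
from pepbinder.feature_selection import FilterSelector
from pepbinder.io import Peptide
from pepbinder.metrics import auprc, auroc, confusion, mean_report, scalar_metrics

FORMAT_VERSION = "pepbinder-ensemble-1"

# canonical LIBSVM coarse grid
DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-15, 4, 2))


@dataclass(frozen=True)
class Prediction:
    seq: str
    prob: float
    votes: int
    label: str  # "binder" | "non-binder"
    error: str | None = None


def grid_search_rbf(
    X,
    y,
    folds: int = 5,
    c_grid: tuple = DEFAULT_C_GRID,
    gamma_grid: tuple = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (c, gamma) search maximizing mean stratified-CV accuracy.

    The fold assignment is seeded and shared across the grid; ties are
    broken toward smaller c, then smaller gamma (grid traversal order).
    """
    X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for tr, _ in splits:
        if np.unique(y[tr]).size < 2:
            raise ValueError("degenerate fold with a single class; check stratification")
    best = (-np.inf, None, None)
    for c in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for tr, va in splits:
                clf = SVC(C=c, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                accs.append((clf.predict(X[va]) == y[va]).mean())
            acc = float(np.mean(accs))
            if acc > best[0]:  # strict: first (smallest c, gamma) wins ties
                best = (acc, c, gamma)
    return best[1], best[2]


def _fit_platt_svc(X, y, c: float, gamma: float, folds: int = 5) -> CalibratedClassifierCV:
    """RBF SVC with Platt-scaled probabilities: a sigmoid is fitted to
    cross-validated decision values, then the SVC is refitted on all data
    (the LIBSVM probability-output procedure)."""
    clf = CalibratedClassifierCV(
        SVC(C=c, gamma=gamma, kernel="rbf"),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=folds),
        ensemble=False,
    )
    return clf.fit(X, y)


class SubmodelClassifier(BaseEstimator, ClassifierMixin):
    """One RBF-SVM submodel: select features -> scale -> grid-search -> fit.

    Operates on the full descriptor matrix (519 columns at defaults).
    Fitted attributes: ``selector_`` (scores, selected indices, MinMax
    parameters), ``c_``, ``gamma_``, ``svm_`` (Platt-calibrated), and
    ``cv_metrics_`` — fold-averaged Sn/Sp/Pr/F1/Acc/MCC/AUROC/AUPRC at the
    chosen hyperparameters.  With ``legacy_selection``/``legacy_scaling``
    the per-fold metrics reuse the whole-dataset feature selection/scaler
    (the leakage-prone variant some AutoML pipelines use); the default
    re-runs both inside each fold.
    """

    def __init__(
        self,
        fs_method: str = "pearson",
        n_features: int = 160,
        bins: int = 5,
        folds: int = 5,
        c_grid: tuple = DEFAULT_C_GRID,
        gamma_grid: tuple = DEFAULT_GAMMA_GRID,
        random_state: int = 0,
        legacy_selection: bool = False,
        legacy_scaling: bool = False,
    ):
        self.fs_method = fs_method
        self.n_features = n_features
        self.bins = bins
        self.folds = folds
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.random_state = random_state
        self.legacy_selection = legacy_selection
        self.legacy_scaling = legacy_scaling

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y).astype(int))
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("SubmodelClassifier is a binary classifier")
        self.selector_ = FilterSelector(self.fs_method, self.n_features, self.bins).fit(X, y)
        Xs = self.selector_.transform(X)
        self.c_, self.gamma_ = grid_search_rbf(
            Xs, y, self.folds, self.c_grid, self.gamma_grid, self.random_state
        )
        self.cv_metrics_ = self._cross_validate(X, y)
        self.svm_ = _fit_platt_svc(Xs, y, self.c_, self.gamma_, self.folds)
        return self

    def _cross_validate(self, X, y) -> dict[str, float]:
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.random_state)
        reports = []
        for tr, va in skf.split(X, y):
            if self.legacy_selection:
                sel = self.selector_
            else:
                sel = FilterSelector(self.fs_method, self.n_features, self.bins).fit(X[tr], y[tr])
                if self.legacy_scaling:
                    # scaler fitted on the whole sub-dataset (leaky legacy variant)
                    from pepbinder.feature_selection import minmax_fit

                    sel.scaler_ = minmax_fit(X[:, sel.selected_idx_])
            clf = SVC(C=self.c_, gamma=self.gamma_, kernel="rbf").fit(
                sel.transform(X[tr]), y[tr]
            )
            Xva = sel.transform(X[va])
            # label metrics from decision-sign predictions, rank metrics from
            # decision values (the SVM toolchain convention; Platt scaling is
            # a monotone map used only for ensemble probability averaging)
            rep = scalar_metrics(confusion(y[va], clf.predict(Xva)))
            scores = clf.decision_function(Xva)
            if list(clf.classes_) == [1, 0]:  # decision sign follows classes_
                scores = -scores
            rep["AUROC"] = auroc(scores, y[va])
            rep["AUPRC"] = auprc(scores, y[va])
            reports.append(rep)
        return mean_report(reports)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        prob = self.svm_.predict_proba(self.selector_.transform(np.asarray(X, dtype=float)))
        # reorder to self.classes_
        cols = [list(self.svm_.classes_).index(c) for c in self.classes_]
        return prob[:, cols]

    def predict(self, X) -> np.ndarray:
        prob = self.predict_proba(X)[:, 1]
        return np.where(prob >= 0.5, self.classes_[1], self.classes_[0])

    @property
    def selected_features(self) -> np.ndarray:
        check_is_fitted(self, "selector_")
        return self.selector_.selected_idx_


class EnsembleBinderClassifier(BaseEstimator, ClassifierMixin):
    """Averaging-voting ensemble of RBF-SVM submodels.

    fit(X, y) partitions the negatives into ``n_submodels`` disjoint
    groups of |positives| (seeded), pairs each with all positives, and
    trains one :class:`SubmodelClassifier` per pairing.  predict_proba
    returns the arithmetic mean of the submodel probabilities; predict
    labels a row positive when the mean is >= ``tp``.
    """

    def __init__(
        self,
        n_submodels: int = 10,
        tp: float = 0.5,
        fs_method: str = "pearson",
        n_features: int = 160,
        bins: int = 5,
        folds: int = 5,
        c_grid: tuple = DEFAULT_C_GRID,
        gamma_grid: tuple = DEFAULT_GAMMA_GRID,
        random_state: int = 1,
    ):
        self.n_submodels = n_submodels
        self.tp = tp
        self.fs_method = fs_method
        self.n_features = n_features
        self.bins = bins
        self.folds = folds
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.random_state = random_state

    def _submodel_template(self) -> SubmodelClassifier:
        return SubmodelClassifier(
            fs_method=self.fs_method,
            n_features=self.n_features,
            bins=self.bins,
            folds=self.folds,
            c_grid=self.c_grid,
            gamma_grid=self.gamma_grid,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        if not 0 <= self.tp <= 1:
            raise ValueError("tp must be in [0, 1]")
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y).astype(int))
        self.classes_ = np.unique(y)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        n_pos = pos_idx.size
        need = self.n_submodels * n_pos
        if neg_idx.size < need:
            raise ValueError(
                f"need {need} negatives for {self.n_submodels} balanced sub-datasets, got {neg_idx.size}"
            )
        rng = np.random.default_rng(self.random_state)
        chosen = rng.choice(neg_idx, size=need, replace=False)
        self.submodels_ = []
        for k in range(self.n_submodels):
            neg_k = chosen[k * n_pos : (k + 1) * n_pos]
            idx = np.concatenate([pos_idx, neg_k])
            sub = self._submodel_template()
            sub.fit(X[idx], y[idx])
            self.submodels_.append(sub)
        return self

    def fit_sub_datasets(self, Xy_pairs: list[tuple[np.ndarray, np.ndarray]]):
        """Fit from explicit (X, y) sub-dataset pairs (one submodel each)."""
        if not Xy_pairs:
            raise ValueError("need at least one sub-dataset")
        self.classes_ = np.array([0, 1])
        self.submodels_ = []
        for Xk, yk in Xy_pairs:
            sub = self._submodel_template()
            sub.fit(np.asarray(Xk, dtype=float), np.asarray(yk).astype(int))
            self.submodels_.append(sub)
        return self

    def submodel_probs(self, X) -> np.ndarray:
        """(n_samples, n_submodels) positive-class probabilities."""
        check_is_fitted(self, "submodels_")
        return np.column_stack([s.predict_proba(X)[:, 1] for s in self.submodels_])

    def predict_proba(self, X) -> np.ndarray:
        p = self.submodel_probs(X).mean(axis=1)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        prob = self.predict_proba(X)[:, 1]
        return np.where(prob >= self.tp, 1, 0)

    def cv_report(self) -> list[dict[str, float]]:
        check_is_fitted(self, "submodels_")
        return [s.cv_metrics_ for s in self.submodels_]


def _sub_to_Xy(sub: SubDataset) -> tuple[np.ndarray, np.ndarray]:
    X = encode_many([p.seq for p in sub.positives] + [n.seq for n in sub.negatives])
    y = np.r_[np.ones(len(sub.positives), int), np.zeros(len(sub.negatives), int)]
    return X, y


def train_submodel(
    sub: SubDataset,
    fs_method: str = "pearson",
    n_features: int = 160,
    folds: int = 5,
    seed: int = 0,
    **kw,
) -> SubmodelClassifier:
    """Encode a balanced sub-dataset and fit one submodel."""
    X, y = _sub_to_Xy(sub)
    return SubmodelClassifier(
        fs_method=fs_method, n_features=n_features, folds=folds, random_state=seed, **kw
    ).fit(X, y)


def train_ensemble(
    subs: list[SubDataset],
    tp: float = 0.5,
    fs_method: str = "pearson",
    n_features: int = 160,
    folds: int = 5,
    seed: int = 0,
    **kw,
) -> EnsembleBinderClassifier:
    """Fit the averaging-voting ensemble from explicit balanced sub-datasets."""
    if not subs:
        raise ValueError("need at least one sub-dataset")
    ens = EnsembleBinderClassifier(
        n_submodels=len(subs), tp=tp, fs_method=fs_method,
        n_features=n_features, folds=folds, random_state=seed, **kw,
    )
    return ens.fit_sub_datasets([_sub_to_Xy(s) for s in subs])


def train_ensemble_from_peptides(
    positives: list[Peptide],
    negatives: list[Peptide],
    n_submodels: int = 10,
    tp: float = 0.5,
    seed: int = 1,
    **kw,
) -> EnsembleBinderClassifier:
    subs = build_sub_datasets(positives, negatives, n_pairs=n_submodels, seed=seed)
    return train_ensemble(subs, tp=tp, seed=seed, **kw)


def predict_peptides(
    ens: EnsembleBinderClassifier, peptides: list, tp: float | None = None
) -> list[Prediction]:
    """Predict a peptide list; unencodable records get per-record errors."""
    tp = ens.tp if tp is None else tp
    if not 0 <= tp <= 1:
        raise ValueError("tp must be in [0, 1]")
    out: list[Prediction | None] = [None] * len(peptides)
    rows, ok_pos, ok_seqs = [], [], []
    for i, p in enumerate(peptides):
        seq = p.seq if isinstance(p, Peptide) else str(p)
        try:
            rows.append(encode_many([seq])[0])
        except ValueError as exc:
            out[i] = Prediction(seq=seq, prob=float("nan"), votes=0, label="error", error=str(exc))
            continue
        ok_pos.append(i)
        ok_seqs.append(seq)
    if ok_pos:
        probs = ens.submodel_probs(np.vstack(rows))
        mean = probs.mean(axis=1)
        votes = (probs >= tp).sum(axis=1)
        for i, seq, m, v in zip(ok_pos, ok_seqs, mean, votes):
            out[i] = Prediction(
                seq=seq,
                prob=float(m),
                votes=int(v),
                label="binder" if m >= tp else "non-binder",
            )
    return out  # type: ignore[return-value]


def save_ensemble(ens: EnsembleBinderClassifier, path) -> None:
    """Persist the ensemble (submodels, feature names, seeds) as one archive."""
    check_is_fitted(ens, "submodels_")
    joblib.dump(
        {
            "format_version": FORMAT_VERSION,
            "ensemble": ens,
            "feature_names": feature_names(),
            "random_state": ens.random_state,
        },
        path,
    )


def load_ensemble(path) -> EnsembleBinderClassifier:
    bundle = joblib.load(path)
    version = bundle.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"model archive version {version!r} != expected {FORMAT_VERSION!r}")
    return bundle["ensemble"]
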