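"""Classification benchmark: feature selection, imbalance-aware SVM tuning,
balanced accuracy, stratified repeated cross-validation and external
train -> test validation.

Every stage that learns from data — z-scaling, aggregator fitting, pathway
ranking, hyperparameter tuning — runs on training samples only; held-out
samples are transformed with the training-derived state.  Class imbalance
is countered three ways: class weights proportional to inverse class
proportion, the average classification error (mean of false positive and
false negative rates) as the tuning objective, and balanced accuracy (mean
of true positive and true negative rates) as the reported metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from pathagg.aggregate import fit_aggregator
from pathagg.data_io import (
    CASE,
    CONTROL,
    DataError,
    ExpressionDataset,
    GeneSetCollection,
    PathwayExpression,
    intersect_genes,
)
from pathagg.preprocess import two_sample_t

#: SVM cost grid, 2^-4 .. 2^6 (11 values); gamma grid = costs / n_features.
COST_GRID = 2.0 ** np.arange(-4, 7)


@dataclass
class TunedClassifier:
    C: float
    gamma: float
    class_weight: dict[str, float]
    model: SVC
    inner_ace: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


@dataclass
class AccuracyCurve:
    """Balanced accuracy per feature-set size k for one (method, dataset)."""

    method: str
    dataset: str
    mode: str  # "internal" or "external"
    ba: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "mode": self.mode,
                "dataset": self.dataset,
                "k": list(self.ba),
                "balanced_accuracy": list(self.ba.values()),
            }
        )


def select_features(pe: PathwayExpression, labels: pd.Series, k: int) -> list[str]:
    """Top-k pathways by t-test p-value on pathway-level expression.

    Ties broken by |t| descending, then pathway id ascending.
    """
    if not 1 <= k <= len(pe.pathway_ids):
        raise DataError(f"k={k} outside 1..{len(pe.pathway_ids)}")
    st = two_sample_t(pe.values, labels)
    order = sorted(pe.pathway_ids, key=lambda pw: (st.p.loc[pw], -abs(st.t.loc[pw]), pw))
    return order[:k]


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(balanced accuracy, average classification error); BA + ACE = 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == CASE
    neg = y_true == CONTROL
    if not pos.any() or not neg.any():
        raise DataError("both classes must be present in y_true")
    tpr = float((y_pred[pos] == CASE).mean())
    tnr = float((y_pred[neg] == CONTROL).mean())
    ba = (tpr + tnr) / 2.0
    return ba, 1.0 - ba


def _class_weights(y: np.ndarray) -> dict[str, float]:
    """Weights proportional to inverse class proportion, mean-1 normalized."""
    n = y.size
    w = {c: n / (2.0 * (y == c).sum()) for c in (CONTROL, CASE)}
    norm = (w[CONTROL] + w[CASE]) / 2.0
    return {c: v / norm for c, v in w.items()}


def tune_train(X: np.ndarray, y: np.ndarray, seed: int) -> TunedClassifier:
    """Grid-search an RBF SVM by inner stratified 5-fold CV on the ACE.

    The grid is the 11 cost values crossed with the same values divided by
    the number of features (121 pairs); ties on mean ACE prefer the smaller
    C, then the smaller gamma.  The winning pair is refit on all samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    k = X.shape[1]
    if k < 1:
        raise DataError("at least one feature required")
    counts = [(y == c).sum() for c in (CONTROL, CASE)]
    if min(counts) < 5:
        raise DataError("inner 5-fold tuning needs >= 5 samples per class; provide more data")
    weights = _class_weights(y)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (ace, C, gamma)
    for C in COST_GRID:
        for gamma in COST_GRID / k:
            aces = []
            for tr, te in folds:
                clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=weights)
                clf.fit(X[tr], y[tr])
                _, ace = classification_metrics(y[te], clf.predict(X[te]))
                aces.append(ace)
            mean_ace = float(np.mean(aces))
            if best is None or mean_ace < best[0] - 1e-12:
                best = (mean_ace, C, gamma)
    assert best is not None
    ace, C, gamma = best
    final = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=weights)
    final.fit(X, y)
    return TunedClassifier(C=C, gamma=gamma, class_weight=weights, model=final, inner_ace=ace)


def _features_matrix(pe: PathwayExpression, pathways: list[str]) -> np.ndarray:
    """samples x k design matrix from a pathway activity matrix."""
    return pe.values.loc[pathways].to_numpy().T


def _ba_over_k(
    pe_train: PathwayExpression,
    pe_test: PathwayExpression,
    y_train: pd.Series,
    y_test: pd.Series,
    k_max: int,
    seed: int,
) -> dict[int, float]:
    out: dict[int, float] = {}
    k_top = min(k_max, len(pe_train.pathway_ids))
    for k in range(1, k_top + 1):
        feats = select_features(pe_train, y_train, k)
        clf = tune_train(_features_matrix(pe_train, feats), y_train.to_numpy(), seed=seed)
        ba, _ = classification_metrics(
            y_test.to_numpy(), clf.predict(_features_matrix(pe_test, feats))
        )
        out[k] = ba
    return out


def internal_cv(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    method: str,
    seed: int,
    k_max: int = 10,
    reps: int = 2,
    min_class_size: int = 10,
) -> AccuracyCurve:
    """Stratified 5-fold CV repeated ``reps`` times with per-fold refitting.

    Within every fold, scaling, aggregation, feature selection and tuning
    are all redone on the training portion alone.
    """
    n1, n2 = ds.class_counts()
    if min(n1, n2) < min_class_size:
        raise DataError(f"each class needs >= {min_class_size} samples (got {n1}, {n2})")
    y_all = ds.labels.to_numpy()
    samples = np.asarray(ds.sample_ids)
    per_fold: list[dict[int, float]] = []
    fold_idx = 0
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=(seed + 7919 * rep) % (2**31))
        for tr, te in skf.split(samples, y_all):
            train = ds.subset_samples(samples[tr])
            test = ds.subset_samples(samples[te])
            agg = fit_aggregator(train, sets, method)
            pe_tr = agg.transform(train)
            pe_te = agg.transform(test)
            per_fold.append(
                _ba_over_k(pe_tr, pe_te, train.labels, test.labels, k_max, seed=(seed ^ fold_idx))
            )
            fold_idx += 1
    ks = sorted(per_fold[0])
    curve = AccuracyCurve(method=method, dataset=ds.name, mode="internal")
    for k in ks:
        curve.ba[k] = float(np.mean([f[k] for f in per_fold]))
    return curve


def external_validate(
    train: ExpressionDataset,
    test: ExpressionDataset,
    sets: GeneSetCollection,
    method: str,
    seed: int,
    k_max: int = 10,
) -> AccuracyCurve:
    """Train every stage on one dataset, evaluate balanced accuracy on the
    other, per feature-set size k."""
    train, test = intersect_genes(train, test)
    agg = fit_aggregator(train, sets, method)
    pe_tr = agg.transform(train)
    pe_te = agg.transform(test)
    curve = AccuracyCurve(method=method, dataset=f"{train.name}->{test.name}", mode="external")
    curve.ba = _ba_over_k(pe_tr, pe_te, train.labels, test.labels, k_max, seed=seed)
    return curve
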