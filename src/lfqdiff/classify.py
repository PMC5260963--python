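"""RFE-SVM protein ranking with leave-one-out error curves.

A linear support-vector machine is trained on all surviving proteins and the
features with the smallest absolute weights are eliminated so that the
survivor count shrinks by a fixed factor (default 1.414, i.e. roughly halving
every two rounds) until one protein remains; the elimination order defines a
ranking.  Generalisation error per panel size is estimated by leave-one-out
cross-validation over patients, re-running the ranking inside every fold so
the held-out patient never influences feature selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "RfeParams",
    "FeatureRanking",
    "ErrorCurve",
    "survivor_schedule",
    "svm_rfe_rank",
    "loo_error_curve",
    "minimal_feature_set",
    "RfeSvmModel",
    "RfeSvmResults",
]


@dataclass
class RfeParams:
    """RFE-SVM tuning constants.

    rank_cost
        SVM cost C used when ranking features (default 100).
    cv_cost
        SVM cost C used inside cross-validation folds (default 10).
    reduction_factor
        Per-round elimination divisor (default 1.414); survivor counts follow
        n -> max(1, round(n / factor)) with round-half-away-from-zero, one
        feature at a time once the step would be smaller than 1.
    """

    rank_cost: float = 100.0
    cv_cost: float = 10.0
    reduction_factor: float = 1.414
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reduction_factor <= 1:
            raise ValueError("reduction_factor must be > 1")
        if self.rank_cost <= 0 or self.cv_cost <= 0:
            raise ValueError("SVM costs must be positive")


@dataclass
class FeatureRanking:
    """Proteins ordered best-to-worst by classification contribution.

    ``rounds`` maps each protein to the elimination round in which it was
    removed (1 = first round); survivors of the final round carry the
    highest round number, so rounds are non-increasing down the ranking.
    """

    order: list[str]
    rounds: dict[str, int]

    def top(self, k: int) -> list[str]:
        return self.order[:k]


@dataclass
class ErrorCurve:
    """LOO misclassification rate per evaluated panel size (sizes ascending)."""

    sizes: list[int]
    errors: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "error": self.errors})


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def survivor_schedule(n_features: int, reduction_factor: float = 1.414) -> list[int]:
    """Descending feature-count schedule n, round(n/f), ... down to 1."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    sched = [n_features]
    n = n_features
    while n > 1:
        nxt = _round_half_away(n / reduction_factor)
        nxt = min(nxt, n - 1)  # guarantee progress (step >= 1)
        n = max(1, nxt)
        sched.append(n)
    return sched


def _zscore_train(train: np.ndarray, *others: np.ndarray):
    """Standardise columns by training-set statistics (leakage-free)."""
    mu = train.mean(axis=0, keepdims=True)
    sd = train.std(axis=0, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return tuple((x - mu) / sd for x in (train, *others))


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, cost: float) -> SVC:
    clf = SVC(kernel="linear", C=cost, tol=1e-4, shrinking=True)
    clf.fit(X, y)
    return clf


def svm_rfe_rank(
    X: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    params: RfeParams | None = None,
) -> FeatureRanking:
    """Rank features by recursive elimination of low-|weight| SVM features.

    ``X`` is patients x features (complete, patient-level); features are
    z-scored over the supplied patients before fitting.  Ties in |weight|
    break by feature id; eliminated features are appended to the tail of the
    ranking in elimination order.
    """
    if params is None:
        params = RfeParams()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 patients")
    n_features = X.shape[1]
    if len(feature_ids) != n_features:
        raise ValueError("feature_ids length does not match X")

    (Xz,) = _zscore_train(np.asarray(X, dtype=float))
    surviving = list(range(n_features))
    tail: list[int] = []  # worst at the end
    rounds: dict[str, int] = {}
    schedule = survivor_schedule(n_features, params.reduction_factor)
    round_no = 0
    for target in schedule[1:]:
        round_no += 1
        clf = _fit_linear_svm(Xz[:, surviving], labels, params.rank_cost)
        w = np.abs(clf.coef_.ravel())
        # eliminate the (len - target) smallest-|w| features, ties by id
        keyed = sorted(
            range(len(surviving)), key=lambda i: (w[i], feature_ids[surviving[i]])
        )
        n_drop = len(surviving) - target
        drop_local = keyed[:n_drop]
        # within a round, weaker features go further down the ranking
        dropped = [surviving[i] for i in sorted(drop_local, key=lambda i: (-w[i], feature_ids[surviving[i]]))]
        for f in dropped:
            rounds[feature_ids[f]] = round_no
        tail = dropped + tail  # later-round (stronger) drops rank above earlier ones
        keep_local = sorted(set(range(len(surviving))) - set(drop_local))
        surviving = [surviving[i] for i in keep_local]
    for f in surviving:
        rounds[feature_ids[f]] = round_no + 1
    order_idx = surviving + tail
    order = [feature_ids[i] for i in order_idx]
    return FeatureRanking(order=order, rounds=rounds)


def loo_error_curve(
    X: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    params: RfeParams | None = None,
    rerank_per_fold: bool = True,
    ranking: FeatureRanking | None = None,
) -> ErrorCurve:
    """Leave-one-patient-out error for each survivor-schedule panel size.

    For every fold the features are z-scored with training-fold statistics
    and, by default, re-ranked by RFE on the training fold alone; the
    held-out patient is predicted with a linear SVM (``cv_cost``) on the
    top-k features.  ``rerank_per_fold=False`` reuses ``ranking`` (computed
    on all patients) inside the folds — an optimistic variant kept only for
    comparison, because the held-out patient then leaks into selection.
    """
    if params is None:
        params = RfeParams()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    if not rerank_per_fold and ranking is None:
        raise ValueError("rerank_per_fold=False requires a precomputed ranking")

    sizes = sorted(set(survivor_schedule(X.shape[1], params.reduction_factor)))
    errors = np.zeros(len(sizes))
    id_index = {f: i for i, f in enumerate(feature_ids)}
    for held in range(n):
        train_idx = [i for i in range(n) if i != held]
        X_tr, y_tr = X[train_idx], labels[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a fold lost one class entirely; labels too unbalanced")
        X_trz, X_tez = _zscore_train(X_tr, X[held][None, :])
        if rerank_per_fold:
            fold_rank = svm_rfe_rank(X_tr, y_tr, feature_ids, params)
        else:
            fold_rank = ranking
        top_idx = [id_index[f] for f in fold_rank.order]
        for s_i, k in enumerate(sizes):
            cols = top_idx[:k]
            clf = _fit_linear_svm(X_trz[:, cols], y_tr, params.cv_cost)
            pred = clf.predict(X_tez[:, cols])[0]
            if pred != labels[held]:
                errors[s_i] += 1
    return ErrorCurve(sizes=sizes, errors=list(errors / n))


def minimal_feature_set(
    curve: ErrorCurve, ranking: FeatureRanking
) -> tuple[int, float, list[str]]:
    """Smallest panel size attaining the global minimum LOO error.

    Returns (size, error, top-size proteins of the full-data ranking).
    """
    if not curve.sizes:
        raise ValueError("empty error curve")
    best_err = min(curve.errors)
    for size, err in zip(curve.sizes, curve.errors):  # sizes ascending
        if err == best_err:
            return size, err, ranking.top(size)
    raise AssertionError("unreachable")


class RfeSvmModel:
    """Minimal-classifier search over a patient-level protein matrix.

    Parameters
    ----------
    X
        patients x proteins array (complete, log2 or z-scored).
    labels
        group label per patient.
    feature_ids
        protein identifier per column.

    ``fit()`` ranks all proteins on the full data, estimates the LOO error
    curve with per-fold re-ranking, and selects the smallest panel attaining
    the minimal error.
    """

    def __init__(
        self,
        X: np.ndarray,
        labels: np.ndarray,
        feature_ids: list[str],
        params: RfeParams | None = None,
        **kwargs,
    ) -> None:
        if params is None:
            params = RfeParams(**kwargs)
        elif kwargs:
            raise TypeError("pass either params or keyword overrides, not both")
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(labels)
        self.feature_ids = list(feature_ids)
        self.params = params

    def fit(self, rerank_per_fold: bool = True) -> "RfeSvmResults":
        ranking = svm_rfe_rank(self.X, self.labels, self.feature_ids, self.params)
        curve = loo_error_curve(
            self.X,
            self.labels,
            self.feature_ids,
            self.params,
            rerank_per_fold=rerank_per_fold,
            ranking=ranking,
        )
        size, err, selected = minimal_feature_set(curve, ranking)
        return RfeSvmResults(self, ranking, curve, size, err, selected)


class RfeSvmResults:
    """Ranking, LOO error curve and the selected minimal panel."""

    def __init__(self, model, ranking, curve, selected_size, min_error, selected):
        self.model = model
        self.ranking: FeatureRanking = ranking
        self.error_curve: ErrorCurve = curve
        self.selected_size: int = selected_size
        self.min_error: float = min_error
        self.selected: list[str] = selected

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.ranking.order,
                "rank": np.arange(1, len(self.ranking.order) + 1),
                "round_eliminated": [self.ranking.rounds[f] for f in self.ranking.order],
            }
        )

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "RFE-SVM minimal classifier panel",
            "=" * 48,
            f"proteins ranked       {len(self.ranking.order):>8d}",
            f"patients              {len(self.model.labels):>8d}",
            f"rank / CV cost        {p.rank_cost:>8.3g} / {p.cv_cost:.3g}",
            f"reduction factor      {p.reduction_factor:>8.3f}",
            f"minimal LOO error     {self.min_error:>8.3f}",
            f"selected panel size   {self.selected_size:>8d}",
            f"top proteins          {', '.join(self.selected[: min(5, len(self.selected))])}",
        ]
        return "\n".join(lines)
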