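"""PCA overview and SIMCA class modelling for adulterated-oil detection.

SIMCA (soft independent modelling of class analogy) fits one PCA model per
class on unit-variance-scaled features and judges membership of a new sample
by its normalized orthogonal distance to the class subspace (DModX) against
an F-distribution critical limit (DCrit at alpha = 0.05). A sample accepted
by no model, or by several, is assigned the class with the smallest
DModX/DCrit ratio. The module also provides the evaluation statistics used
for such models: one-vs-rest confusion counts, TPR/FNR/PPV/FDR/accuracy, and
rank-based ROC AUC with DModX as the score.

All linear algebra is plain SVD on the scaled matrix; Q2 (cross-validated
explained variance) uses Wold-style element-wise deletion with an EM
imputation of the held-out cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

__all__ = [
    "UnitVarianceScaler",
    "PrincipalComponents",
    "SimcaClassModel",
    "SimcaClassifier",
    "ConfusionCounts",
    "ClassMetrics",
    "fit_uv_scaler",
    "apply_scaler",
    "fit_pca",
    "q2_cross_validation",
    "fit_simca_class",
    "detect_outliers",
    "simca_classify",
    "confusion_from_labels",
    "classification_metrics",
    "overall_accuracy",
    "roc_auc",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# Unit-variance (auto) scaling
# ---------------------------------------------------------------------------

class UnitVarianceScaler(TransformerMixin, BaseEstimator):
    """Column-wise centring and scaling to unit variance (ddof = 1).

    Constant columns are rejected by name rather than silently producing
    zero-variance divisions.
    """

    def fit(self, X, y=None) -> "UnitVarianceScaler":
        M, cols = _as_matrix(X)
        if M.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate a variance")
        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=1)
        bad = np.where(self.scale_ <= 0)[0]
        if bad.size:
            names = ", ".join(cols[i] for i in bad)
            raise ValueError(f"constant column(s) cannot be unit-variance scaled: {names}")
        self.columns_ = cols
        self.n_features_in_ = M.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return (M - self.mean_) / self.scale_

    def inverse_transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def fit_uv_scaler(table) -> UnitVarianceScaler:
    return UnitVarianceScaler().fit(table)


def apply_scaler(model: UnitVarianceScaler, table) -> np.ndarray:
    return model.transform(table)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _svd_loadings(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SVD loadings with a deterministic sign convention (largest-magnitude
    coefficient of each loading positive), so results do not depend on row
    order or LAPACK sign choices."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    P = Vt.T
    for j in range(P.shape[1]):
        k = np.argmax(np.abs(P[:, j]))
        if P[k, j] < 0:
            P[:, j] = -P[:, j]
            U[:, j] = -U[:, j]
    return U * s, P  # scores (all), loadings (all)


class PrincipalComponents(BaseEstimator):
    """PCA of an already-scaled matrix via singular-value decomposition.

    Fitted attributes: ``loadings_`` (columns are orthonormal axes),
    ``scores_``, ``explained_variance_ratio_`` (per component, full
    spectrum), ``r2x_`` (cumulative share of the first ``n_components``) and
    ``r2x_per_component_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "PrincipalComponents":
        M, cols = _as_matrix(X)
        max_comp = min(M.shape[0] - 1, M.shape[1])
        if self.n_components > max_comp:
            raise ValueError(
                f"n_components={self.n_components} exceeds min(rows-1, columns)={max_comp}")
        scores, loadings = _svd_loadings(M)
        var = (scores**2).sum(axis=0)
        self.explained_variance_ratio_ = var / var.sum()
        A = self.n_components
        self.loadings_ = loadings[:, :A]
        self.scores_ = scores[:, :A]
        self.r2x_per_component_ = self.explained_variance_ratio_[:A].copy()
        self.r2x_ = float(self.r2x_per_component_.sum())
        self.columns_ = cols
        return self

    def transform(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return M @ self.loadings_

    def residuals(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return M - (M @ self.loadings_) @ self.loadings_.T


def fit_pca(scaled_table, n_components: int) -> PrincipalComponents:
    return PrincipalComponents(n_components=n_components).fit(scaled_table)


def _nipals_loadings_missing(X: np.ndarray, mask: np.ndarray, n_components: int,
                             max_iter: int = 500, tol: float = 1e-12,
                             floor: float = 0.25) -> np.ndarray:
    """Loadings of a PCA fitted with masked cells treated as missing.

    Classical NIPALS missing-data updates: per component, alternate score and
    loading regressions over the observed cells, deflate, repeat. The
    denominators (observed-cell sums of squares) are floored at ``floor``
    times their full-data value: when a loading concentrates on a row's
    missing columns the raw denominator collapses and the score would blow
    up, so the floor trades unbounded amplification for a bounded
    attenuation. On data consistent with the model the floor is inactive
    unless a single column dominates the component.
    """
    R = np.where(mask, 0.0, X).astype(float)
    obs = ~mask
    n, k = X.shape
    P = np.zeros((k, n_components))
    for a in range(n_components):
        j0 = int(np.argmax((R**2).sum(axis=0)))
        t = R[:, j0].copy()
        if not np.any(t):
            break
        p = np.zeros(k)
        for _ in range(max_iter):
            denom_p = (t[:, None] ** 2 * obs).sum(axis=0)
            denom_p = np.maximum(denom_p, floor * (t**2).sum())
            p = (R * t[:, None]).sum(axis=0) / denom_p
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = (p[None, :] ** 2 * obs).sum(axis=1)
            denom_t = np.maximum(denom_t, floor)  # ||p|| = 1
            t_new = (R * p[None, :]).sum(axis=1) / denom_t
            if np.max(np.abs(t_new - t)) < tol * max(1.0, float(np.max(np.abs(t_new)))):
                t = t_new
                break
            t = t_new
        jmax = int(np.argmax(np.abs(p)))
        if p[jmax] < 0:
            p, t = -p, -t
        P[:, a] = p
        R = np.where(obs, R - np.outer(t, p), 0.0)
    return P


def q2_cross_validation(scaled_table, n_components: int, folds: int = 7) -> float:
    """Cross-validated predictive share Q2 = 1 - PRESS/SS.

    Element-wise deletion in a diagonal pattern: cell (i, j) belongs to fold
    ``(i + j) mod folds``. For each fold the held-out cells are treated as
    missing, loadings are fitted to the remaining cells (NIPALS missing-data
    updates), each row's scores are estimated by least squares on its
    observed cells, and PRESS accumulates the squared prediction error of
    the held-out cells.
    """
    M, _ = _as_matrix(scaled_table)
    n, k = M.shape
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if folds > n * k:
        raise ValueError("more folds than matrix cells")
    A = n_components
    if A > min(n - 1, k):
        raise ValueError("n_components too large for the table")

    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(k), indexing="ij")
    fold_of = (i_idx + j_idx) % folds
    ss = float((M**2).sum())
    if ss == 0:
        raise ValueError("all-zero table has no variance to predict")
    press = 0.0
    for f in range(folds):
        mask = fold_of == f  # True = held out
        P = _nipals_loadings_missing(M, mask, A)
        # directions the observed cells barely constrain (relative singular
        # value < 0.15) are truncated rather than amplified into predictions
        pred = np.empty_like(M)
        for i in range(n):
            obs = ~mask[i]
            t_i, *_ = np.linalg.lstsq(P[obs], M[i, obs], rcond=0.15)
            pred[i] = P @ t_i
        press += float(((M - pred)[mask] ** 2).sum())
    return 1.0 - press / ss


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

@dataclass
class SimcaClassModel:
    """One class's PCA model with its residual scale and critical limit.

    ``s0`` is the pooled residual standard deviation with
    (N-A-1)(K-A) degrees of freedom; DModX of a new sample is
    sqrt(RSS/(K-A))/s0, and training-set distances carry the finite-sample
    correction sqrt(N/(N-A-1)) so their mean square is exactly 1. ``dcrit``
    is the square root of the 1-alpha quantile of F(K-A, (N-A-1)(K-A)).
    """

    label: str
    scaler: UnitVarianceScaler
    pca: PrincipalComponents
    s0: float
    dcrit: float
    training_dmodx: np.ndarray
    n_train: int
    alpha: float = 0.05
    q2: float | None = None
    score_min: np.ndarray | None = None
    score_max: np.ndarray | None = None

    def dmodx(self, X, training: bool = False, augmented: bool = False) -> np.ndarray:
        """Normalized distance to the class model.

        ``augmented=True`` adds, before normalization, the squared score
        distance outside the training score range component-wise (zero for
        samples inside the hull). This augmented form penalizes samples that
        sit on the class hyperplane but beyond the span of the training
        scores - e.g. a pure base oil extrapolating the mixing trend of an
        adulterated class - which plain residual distance cannot see.
        """
        Xs = self.scaler.transform(X)
        R = self.pca.residuals(Xs)
        K = Xs.shape[1]
        A = self.pca.n_components
        rss = (R**2).sum(axis=1)
        if augmented and self.score_min is not None:
            T = self.pca.transform(Xs)
            below = np.maximum(self.score_min - T, 0.0)
            above = np.maximum(T - self.score_max, 0.0)
            rss = rss + (below**2 + above**2).sum(axis=1)
        d = np.sqrt(rss / (K - A)) / self.s0
        if training:
            d = d * np.sqrt(self.n_train / (self.n_train - A - 1))
        return d


def fit_simca_class(
    class_table,
    n_components: int | None = None,
    alpha: float = 0.05,
    max_components: int = 7,
    q2_folds: int = 7,
    q2_tolerance: float = 0.05,
    label: str = "",
) -> SimcaClassModel:
    """Fit one SIMCA class model on that class's training samples only.

    With ``n_components=None`` the dimensionality is chosen from the
    element-wise cross-validated Q2 over 1..max_components (bounded so the
    residual degrees of freedom stay positive): the largest count whose Q2
    is within ``q2_tolerance`` of the maximum. Among models of equivalent
    predictive power the richer one is preferred because its residual
    distance is the more selective class boundary (instrument autofit
    behaves the same way, typically retaining 5-7 components per class).
    """
    M, cols = _as_matrix(class_table)
    N, K = M.shape
    cap = min(max_components, N - 2, K - 1)
    if cap < 1:
        raise ValueError(f"class {label!r} has too few samples ({N}) for a SIMCA model")
    scaler = UnitVarianceScaler().fit(class_table)
    Xs = scaler.transform(class_table)

    if n_components is None:
        q2s = [q2_cross_validation(Xs, a, folds=q2_folds) for a in range(1, cap + 1)]
        best = max(q2s)
        n_components = max(a + 1 for a, q in enumerate(q2s) if q >= best - q2_tolerance)
        q2 = float(q2s[n_components - 1])
    else:
        if N < n_components + 2:
            raise ValueError("class needs at least n_components + 2 samples")
        q2 = float(q2_cross_validation(Xs, n_components, folds=q2_folds))

    A = n_components
    pca = PrincipalComponents(n_components=A).fit(Xs)
    R = pca.residuals(Xs)
    dof = (N - A - 1) * (K - A)
    s0 = float(np.sqrt((R**2).sum() / dof))
    dcrit = float(np.sqrt(stats.f.ppf(1.0 - alpha, K - A, dof)))
    T = pca.scores_
    model = SimcaClassModel(
        label=label, scaler=scaler, pca=pca, s0=s0, dcrit=dcrit,
        training_dmodx=np.array([]), n_train=N, alpha=alpha, q2=q2,
        score_min=T.min(axis=0), score_max=T.max(axis=0),
    )
    model.training_dmodx = model.dmodx(class_table, training=True)
    return model


def detect_outliers(model: SimcaClassModel, table=None) -> np.ndarray:
    """Boolean flags: DModX above the class critical limit.

    With ``table=None`` the model's own training distances (which include
    the finite-sample correction) are tested.
    """
    if table is None:
        return model.training_dmodx > model.dcrit
    M, _ = _as_matrix(table)
    if M.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    return model.dmodx(table) > model.dcrit


def simca_classify(models: Sequence[SimcaClassModel], X, augmented: bool = True,
                   priority: str | None = None) -> pd.DataFrame:
    """Classify samples against a set of SIMCA class models.

    Returns a frame with the assigned single label (class of minimum
    DModX/DCrit ratio), the set of classes whose critical limit accepts the
    sample, and a ``forced`` flag set when no class accepted it. By default
    the score-augmented distance is used, so membership requires being close
    to the class hyperplane *within* the span of its training scores.

    ``priority`` names a class whose own acceptance decision overrides the
    ratio comparison: a sample under that class's critical limit is assigned
    to it directly. This is the authenticity-testing protocol - membership of
    the pure class is judged by the pure-class model alone, because every
    blend class contains near-pure samples on its own hyperplane and would
    otherwise absorb genuine pure samples.
    """
    if not models:
        raise ValueError("need at least one class model")
    M, _ = _as_matrix(X)
    ratios = np.column_stack([m.dmodx(M, augmented=augmented) / m.dcrit for m in models])
    labels = [m.label for m in models]
    best = np.argmin(ratios, axis=1)
    accepted = ratios <= 1.0
    assigned = [labels[b] for b in best]
    if priority is not None:
        if priority not in labels:
            raise ValueError(f"priority class {priority!r} not among the models")
        p = labels.index(priority)
        assigned = [priority if accepted[i, p] else assigned[i] for i in range(len(assigned))]
    return pd.DataFrame({
        "assigned": assigned,
        "accepted_by": [[labels[j] for j in np.where(row)[0]] for row in accepted],
        "min_ratio": ratios[np.arange(len(best)), best],
        "forced": ~accepted.any(axis=1),
    })


class SimcaClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class SIMCA as a scikit-learn classifier.

    Fits one :class:`SimcaClassModel` per class in ``y``; ``predict`` assigns
    the class of minimum DModX/DCrit ratio. ``decision_function`` returns
    the negative ratios (higher = more in-class), one column per class in
    ``classes_`` order.
    """

    def __init__(self, n_components: int | Mapping[str, int] | None = None,
                 alpha: float = 0.05, max_components: int = 7, q2_folds: int = 7,
                 augmented: bool = True, priority: str | None = None):
        self.n_components = n_components
        self.alpha = alpha
        self.max_components = max_components
        self.q2_folds = q2_folds
        self.augmented = augmented
        self.priority = priority

    def fit(self, X, y) -> "SimcaClassifier":
        M, _ = _as_matrix(X)
        y = np.asarray(y)
        if M.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.array(sorted(set(map(str, y))))
        self.models_ = {}
        for label in self.classes_:
            sub = M[np.asarray([str(v) == label for v in y])]
            if isinstance(self.n_components, Mapping):
                ncomp = self.n_components.get(label)
            else:
                ncomp = self.n_components
            self.models_[label] = fit_simca_class(
                sub, n_components=ncomp, alpha=self.alpha,
                max_components=self.max_components, q2_folds=self.q2_folds, label=label,
            )
        return self

    def _ratios(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return np.column_stack(
            [self.models_[c].dmodx(M, augmented=self.augmented) / self.models_[c].dcrit
             for c in self.classes_])

    def decision_function(self, X) -> np.ndarray:
        return -self._ratios(X)

    def predict(self, X) -> np.ndarray:
        return self.predict_detail(X)["assigned"].to_numpy()

    def predict_detail(self, X) -> pd.DataFrame:
        return simca_classify([self.models_[c] for c in self.classes_], X,
                              augmented=self.augmented, priority=self.priority)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion tally for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    """TPR, FNR, PPV, FDR and one-vs-rest accuracy; None where the
    denominator is zero (undefined, deliberately not reported as 0)."""

    tpr: float | None
    fnr: float | None
    ppv: float | None
    fdr: float | None
    accuracy: float | None


def classification_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """The standard one-vs-rest rates.

    TPR = TP/(TP+FN), FNR = FN/(TP+FN), PPV = TP/(TP+FP), FDR = FP/(TP+FP),
    accuracy = (TP+TN)/(TP+FN+FP+TN). TPR+FNR = 1 and PPV+FDR = 1 whenever
    defined.
    """
    pos = counts.tp + counts.fn
    pred_pos = counts.tp + counts.fp
    tot = counts.total
    return ClassMetrics(
        tpr=counts.tp / pos if pos else None,
        fnr=counts.fn / pos if pos else None,
        ppv=counts.tp / pred_pos if pred_pos else None,
        fdr=counts.fp / pred_pos if pred_pos else None,
        accuracy=(counts.tp + counts.tn) / tot if tot else None,
    )


def confusion_from_labels(y_true, y_pred) -> dict[str, ConfusionCounts]:
    """Per-class one-vs-rest confusion counts from label vectors."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have the same length")
    out = {}
    for cls in sorted(set(y_true) | set(y_pred)):
        tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
        fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
        fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
        tn = len(y_true) - tp - fp - fn
        out[cls] = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return out


def overall_accuracy(y_true, y_pred) -> float:
    """Multi-class accuracy: total correct / total samples."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if not y_true or len(y_true) != len(y_pred):
        raise ValueError("label vectors must be non-empty and of equal length")
    return sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)


def roc_auc(model: SimcaClassModel, in_class, out_class) -> float:
    """ROC area with DModX as the score (lower = more in-class).

    Mann-Whitney rank formulation with midranks for ties: the probability
    that a random in-class sample has smaller DModX than a random out-class
    sample.
    """
    d_in = model.dmodx(in_class)
    d_out = model.dmodx(out_class)
    return auc_from_scores(d_in, d_out)


def auc_from_scores(scores_in: np.ndarray, scores_out: np.ndarray) -> float:
    """AUC for 'in' scoring lower than 'out'; ties share midranks."""
    scores_in = np.asarray(scores_in, dtype=float)
    scores_out = np.asarray(scores_out, dtype=float)
    if scores_in.size == 0 or scores_out.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([scores_in, scores_out]))
    r_out = ranks[scores_in.size:].sum()
    n_in, n_out = scores_in.size, scores_out.size
    u = r_out - n_out * (n_out + 1) / 2.0
    return float(u / (n_in * n_out))
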