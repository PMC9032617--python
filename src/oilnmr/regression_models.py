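"""Quantification of adulteration level: PLSR, the Durbin-Watson linearity
gate, and RBF support vector regression for the nonlinear series.

The workhorse is PLS1 regression implemented with the NIPALS sequence
(weights from the X'y covariance, deflation after each latent variable); the
number of latent variables is picked from a 7-fold cross-validated RMSECV
curve with a plateau rule. A Durbin-Watson test on the calibration residuals
(ordered by adulteration level) decides whether the linear model is adequate;
when the permutation p-value drops below 0.05 the series is refit with an
epsilon-SVR on a radial-basis kernel, tuned by seeded grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR

from .classification import UnitVarianceScaler, _as_matrix
from .relaxometry import FEATURE_COLUMNS

__all__ = [
    "PLSRegressor",
    "TunedSVR",
    "RegressionMetrics",
    "fit_plsr",
    "rmsecv_curve",
    "select_latent_variables",
    "regression_metrics",
    "durbin_watson",
    "fit_svr",
    "quantify_pipeline",
    "split_regression_sets",
    "DEFAULT_SVR_GRID",
]

DEFAULT_SVR_GRID: dict[str, tuple] = {
    "C": (1.0, 10.0, 100.0),
    "gamma": (0.003, 0.01, 0.03, 0.1, 0.3, 1.0),
    "epsilon": (0.005, 0.01, 0.02),
}


# ---------------------------------------------------------------------------
# PLS regression (NIPALS, single response)
# ---------------------------------------------------------------------------

class PLSRegressor(RegressorMixin, BaseEstimator):
    """PLS1 regression via NIPALS with deflation.

    X is autoscaled (unit variance) and y centred before extraction; each
    latent variable has weight vector w proportional to X'y, scores t = Xw,
    loadings p = X't/(t't), and y-loading q = y't/(t't); X and y are deflated
    before the next component. Fitted attributes: ``x_weights_``,
    ``x_loadings_``, ``y_loadings_``, ``coef_`` (original X units),
    ``intercept_`` and ``standardized_coef_`` (per unit-variance X).
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "PLSRegressor":
        M, cols = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if M.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if self.n_components < 1:
            raise ValueError("n_components must be at least 1")
        rank = np.linalg.matrix_rank(M - M.mean(axis=0))
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank of X ({rank})")

        if self.scale:
            self._scaler = UnitVarianceScaler().fit(M)
            Xw = self._scaler.transform(M)
        else:
            self._x_mean = M.mean(axis=0)
            self._scaler = None
            Xw = M - self._x_mean
        self._y_mean = float(y.mean())
        yw = y - self._y_mean

        n, k = Xw.shape
        A = self.n_components
        W = np.zeros((k, A))
        P = np.zeros((k, A))
        q = np.zeros(A)
        for a in range(A):
            w = Xw.T @ yw
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                raise ValueError("y is orthogonal to the remaining X subspace; "
                                 f"cannot extract latent variable {a + 1}")
            w /= nw
            t = Xw @ w
            tt = float(t @ t)
            p = Xw.T @ t / tt
            qa = float(yw @ t / tt)
            Xw = Xw - np.outer(t, p)
            yw = yw - qa * t
            W[:, a], P[:, a], q[a] = w, p, qa

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        # regression vector in the (scaled, centred) space
        B = W @ np.linalg.solve(P.T @ W, q)
        self.standardized_coef_ = B
        if self.scale:
            self.coef_ = B / self._scaler.scale_
            self.intercept_ = self._y_mean - float(self._scaler.mean_ @ self.coef_)
        else:
            self.coef_ = B
            self.intercept_ = self._y_mean - float(self._x_mean @ self.coef_)
        self.columns_ = cols
        return self

    def predict(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return M @ self.coef_ + self.intercept_


def fit_plsr(X, y, n_latent: int) -> PLSRegressor:
    return PLSRegressor(n_components=n_latent).fit(X, y)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by response value.

    Samples sharing a level are shuffled (seeded) and dealt round-robin, so
    every fold sees every adulteration level where possible.
    """
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    next_fold = 0
    for val in np.unique(y):
        idx = np.where(y == val)[0]
        idx = rng.permutation(idx)
        for i in idx:
            assignment[i] = next_fold % folds
            next_fold += 1
    return assignment


def rmsecv_curve(X, y, max_latent: int, folds: int = 7, seed: int = 0) -> np.ndarray:
    """RMSECV as a function of the number of latent variables (1..max_latent).

    Out-of-fold predictions under level-stratified, seeded 7-fold CV. When
    ``max_latent`` exceeds what the fold training sets can support the curve
    is truncated with a warning.
    """
    M, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    assignment = _stratified_folds(y, folds, seed)
    # feasible components: limited by the worst fold's training rank
    feasible = max_latent
    for f in range(folds):
        tr = assignment != f
        r = np.linalg.matrix_rank(M[tr] - M[tr].mean(axis=0))
        feasible = min(feasible, r)
    if feasible < max_latent:
        warnings.warn(
            f"max_latent={max_latent} truncated to {feasible} (training-fold rank)",
            stacklevel=2)
    curve = np.empty(feasible)
    preds = np.empty((feasible, y.size))
    for f in range(folds):
        tr, te = assignment != f, assignment == f
        for a in range(1, feasible + 1):
            model = PLSRegressor(n_components=a).fit(M[tr], y[tr])
            preds[a - 1, te] = model.predict(M[te])
    for a in range(feasible):
        curve[a] = float(np.sqrt(np.mean((preds[a] - y) ** 2)))
    return curve


def select_latent_variables(curve: Sequence[float], rel_tol: float = 0.02) -> int:
    """Plateau rule: the smallest count after which RMSECV stops improving.

    Returns the smallest a with RMSECV(a) - RMSECV(a+1) < rel_tol * RMSECV(a)
    (an increase counts as a plateau); if the curve keeps improving to the
    end, returns its length.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    for a in range(curve.size - 1):
        if curve[a] - curve[a + 1] < rel_tol * curve[a]:
            return a + 1
    return int(curve.size)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionMetrics:
    """RMSE-family errors (level units) and squared correlations."""

    rmsec: float
    rmsep: float
    r2c: float | None
    r2p: float | None
    rmsecv: float | None = None


def _r2(observed: np.ndarray, predicted: np.ndarray, mode: str) -> float | None:
    if np.std(observed) == 0:
        return None
    if mode == "pearson":
        return float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    if mode == "ss":
        ss_res = float(((observed - predicted) ** 2).sum())
        ss_tot = float(((observed - observed.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown r2 mode {mode!r}")


def regression_metrics(model, calibration, validation, rmsecv: float | None = None,
                       r2_mode: str = "pearson") -> RegressionMetrics:
    """RMSEC/RMSEP and R2C/R2P for a fitted model.

    R-squared is the squared Pearson correlation between predicted and
    observed by default (``r2_mode='ss'`` gives 1 - SSres/SStot instead).
    """
    Xc, yc = calibration
    Xv, yv = validation
    yc = np.asarray(yc, dtype=float).ravel()
    yv = np.asarray(yv, dtype=float).ravel()
    pc = np.asarray(model.predict(Xc)).ravel()
    pv = np.asarray(model.predict(Xv)).ravel()
    return RegressionMetrics(
        rmsec=float(np.sqrt(np.mean((pc - yc) ** 2))),
        rmsep=float(np.sqrt(np.mean((pv - yv) ** 2))),
        r2c=_r2(yc, pc, r2_mode),
        r2p=_r2(yv, pv, r2_mode),
        rmsecv=rmsecv,
    )


# ---------------------------------------------------------------------------
# Durbin-Watson linearity gate
# ---------------------------------------------------------------------------

def durbin_watson(residuals, n_permutations: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Durbin-Watson statistic and a permutation p-value.

    DW = sum_{i>=2} (e_i - e_{i-1})^2 / sum_i e_i^2 on the residuals in the
    order given (callers order by adulteration level so lack-of-fit curvature
    appears as positive serial correlation). The exact DW null depends on the
    design matrix, so the p-value is estimated by permuting the residual
    order (two-sided on |DW - 2|): under exchangeability every ordering is
    equally likely.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    denom = float((e**2).sum())
    if denom == 0:
        raise ValueError("all-zero residuals; DW undefined")

    def dw_of(rows: np.ndarray) -> np.ndarray:
        return (np.diff(rows, axis=-1) ** 2).sum(axis=-1) / denom

    statistic = float(dw_of(e))
    rng = np.random.default_rng(seed)
    perms = np.tile(e, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    null = dw_of(perms)
    p = (1.0 + np.sum(np.abs(null - 2.0) >= abs(statistic - 2.0))) / (n_permutations + 1.0)
    return statistic, float(p)


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

class TunedSVR(RegressorMixin, BaseEstimator):
    """RBF epsilon-SVR on autoscaled features with grid-searched (C, gamma, epsilon).

    The search minimizes cross-validated RMSE over a seeded, level-stratified
    fold assignment; ties break toward the first combination in the sorted
    grid order, so the choice is deterministic.
    """

    def __init__(self, grid: Mapping[str, Sequence[float]] | None = None,
                 folds: int = 7, seed: int = 0):
        self.grid = grid
        self.folds = folds
        self.seed = seed

    def fit(self, X, y) -> "TunedSVR":
        M, _ = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if np.std(y) == 0:
            raise ValueError("degenerate response: y is constant")
        grid = dict(self.grid or DEFAULT_SVR_GRID)
        if not all(len(v) for v in grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        self.scaler_ = UnitVarianceScaler().fit(M)
        Xs = self.scaler_.transform(M)
        assignment = _stratified_folds(y, self.folds, self.seed)

        combos = [(c, g, eps)
                  for c in sorted(grid["C"])
                  for g in sorted(grid["gamma"])
                  for eps in sorted(grid.get("epsilon", (0.01,)))]
        best = None
        for c, g, eps in combos:
            pred = np.empty_like(y)
            for f in range(self.folds):
                tr, te = assignment != f, assignment == f
                svr = SVR(kernel="rbf", C=c, gamma=g, epsilon=eps)
                svr.fit(Xs[tr], y[tr])
                pred[te] = svr.predict(Xs[te])
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            if best is None or rmse < best[0] - 1e-15:
                best = (rmse, c, g, eps)
        self.cv_rmse_, self.C_, self.gamma_, self.epsilon_ = best
        self.svr_ = SVR(kernel="rbf", C=self.C_, gamma=self.gamma_, epsilon=self.epsilon_)
        self.svr_.fit(Xs, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.svr_.predict(self.scaler_.transform(X))


def fit_svr(X, y, folds: int = 7, grid: Mapping[str, Sequence[float]] | None = None,
            seed: int = 0) -> TunedSVR:
    return TunedSVR(grid=grid, folds=folds, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# Quantification pipeline
# ---------------------------------------------------------------------------

def split_regression_sets(features: pd.DataFrame, seed: int = 0,
                          validation_fraction: float = 0.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Level-stratified calibration/validation split of a feature table."""
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for _, group in features.groupby("level"):
        n_val = int(round(validation_fraction * len(group)))
        order = rng.permutation(len(group))
        val_idx.extend(group.index[order[:n_val]])
    val_mask = features.index.isin(val_idx)
    return features[~val_mask], features[val_mask]


@dataclass
class QuantifyReport:
    """Outcome of the PLSR -> (DW gate) -> SVR quantification of one series."""

    series: str
    n_calibration: int
    n_validation: int
    plsr_n_latent: int
    plsr: RegressionMetrics
    dw_statistic: float
    dw_p_value: float
    route: str  # "PLSR" or "SVR"
    svr: RegressionMetrics | None = None
    svr_hyperparameters: dict | None = None
    standardized_coefficients: pd.Series | None = None

    def as_rows(self) -> pd.DataFrame:
        rows = [{
            "series": self.series, "model": "PLSR",
            "n_latent_or_hyperparams": str(self.plsr_n_latent),
            "RMSEC": self.plsr.rmsec, "RMSECV": self.plsr.rmsecv, "RMSEP": self.plsr.rmsep,
            "R2C": self.plsr.r2c, "R2P": self.plsr.r2p,
            "DW": self.dw_statistic, "DW_p": self.dw_p_value,
        }]
        if self.svr is not None:
            hp = self.svr_hyperparameters or {}
            rows.append({
                "series": self.series, "model": "SVR",
                "n_latent_or_hyperparams": ";".join(f"{k}={v:g}" for k, v in hp.items()),
                "RMSEC": self.svr.rmsec, "RMSECV": self.svr.rmsecv, "RMSEP": self.svr.rmsep,
                "R2C": self.svr.r2c, "R2P": self.svr.r2p,
                "DW": np.nan, "DW_p": np.nan,
            })
        return pd.DataFrame(rows)


def quantify_pipeline(
    features: pd.DataFrame,
    adulterant: str = "SO",
    max_latent: int = 10,
    folds: int = 7,
    seed: int = 0,
    include_pure: bool = True,
    dw_alpha: float = 0.05,
    always_fit_svr: bool = False,
    svr_grid: Mapping[str, Sequence[float]] | None = None,
) -> QuantifyReport:
    """Quantify adulteration level for one series (or the pooled set).

    Selects the series rows from a labelled feature table, fits PLSR with a
    cross-validated latent-variable count, gates on the Durbin-Watson test of
    the level-ordered calibration residuals, and refits with SVR when the
    residuals are serially structured (p < ``dw_alpha``).

    ``adulterant`` is ``"SO"``, ``"CO"``, ``"RO"`` or ``"pooled"`` (all
    adulterated series together, adulterant identity unknown).
    """
    if adulterant == "pooled":
        wanted = {"AO-SO", "AO-CO", "AO-RO", "SO", "CO", "RO"}
    else:
        wanted = {f"AO-{adulterant}", adulterant}
    labels = set(features["label"])
    rows = features[features["label"].isin(wanted | {"AO"})].copy()
    if not include_pure:
        rows = rows[(rows["level"] > 0) & (rows["level"] < 1)]
    if rows.empty:
        raise ValueError(f"no samples for series {adulterant!r} (labels present: {sorted(labels)})")

    cal, val = split_regression_sets(rows, seed=seed)
    Xc, yc = cal[FEATURE_COLUMNS], cal["level"].to_numpy(dtype=float)
    Xv, yv = val[FEATURE_COLUMNS], val["level"].to_numpy(dtype=float)

    curve = rmsecv_curve(Xc, yc, max_latent=max_latent, folds=folds, seed=seed)
    n_latent = select_latent_variables(curve)
    plsr = PLSRegressor(n_components=n_latent).fit(Xc, yc)
    plsr_metrics = regression_metrics(plsr, (Xc, yc), (Xv, yv), rmsecv=float(curve[n_latent - 1]))

    resid = yc - plsr.predict(Xc)
    order = np.lexsort((plsr.predict(Xc), yc))  # ascending level, ties by prediction
    dw_stat, dw_p = durbin_watson(resid[order], seed=seed)

    report = QuantifyReport(
        series=adulterant,
        n_calibration=len(cal), n_validation=len(val),
        plsr_n_latent=n_latent, plsr=plsr_metrics,
        dw_statistic=dw_stat, dw_p_value=dw_p,
        route="PLSR",
        standardized_coefficients=pd.Series(plsr.standardized_coef_, index=FEATURE_COLUMNS),
    )
    if dw_p < dw_alpha or always_fit_svr:
        svr = TunedSVR(grid=svr_grid, folds=folds, seed=seed).fit(Xc, yc)
        report.svr = regression_metrics(svr, (Xc, yc), (Xv, yv), rmsecv=svr.cv_rmse_)
        report.svr_hyperparameters = {"C": svr.C_, "gamma": svr.gamma_, "epsilon": svr.epsilon_}
        if dw_p < dw_alpha:
            report.route = "SVR"
    return report
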