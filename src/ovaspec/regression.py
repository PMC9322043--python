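"""Calibration models: NIPALS PLSR and RBF-kernel LSSVM, with CV tooling.

Both learners follow the scikit-learn estimator contract (``fit``/``predict``,
``get_params``, fitted attributes with a trailing underscore) so they compose
with sklearn model selection.  The cross-validation helpers reproduce the
study design: seeded shuffled k-fold, out-of-fold predictions pooled before
computing R2/RMSE.

PLSR is the single-response NIPALS algorithm: per latent variable, the
loading weight w = X'y (normalized), score s = Xw, loadings p = X's/s's and
q = y's/s's, then rank-one deflation of X and y; the regression coefficients
are b = W (P'W)^-1 q on centered data.

LSSVM replaces the SVM inequality constraints by equalities, so training
reduces to one linear KKT system::

    [ 0   1'        ] [ b     ]   [ 0 ]
    [ 1   K + I/γ   ] [ alpha ] = [ y ]

with the RBF kernel K_ij = exp(-||x_i - x_j||^2 / (2 σ^2)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Metrics",
    "compute_metrics",
    "PLSRRegressor",
    "LSSVMRegressor",
    "fit_plsr",
    "fit_lssvm",
    "kfold_cv",
    "select_n_lv",
    "grid_search_lssvm",
    "LSSVMGridResult",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Metrics:
    """Determination coefficient and root-mean-square error (units of y)."""

    r2: float
    rmse: float


def compute_metrics(y_true, y_pred) -> Metrics:
    """R2 = 1 - SSE/SST and RMSE with an n denominator."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in y_true: R2 undefined")
    sse = float(np.sum((y_pred - y_true) ** 2))
    return Metrics(r2=1.0 - sse / sst, rmse=float(np.sqrt(sse / y_true.size)))


# ---------------------------------------------------------------------------
# PLSR


class PLSRRegressor(RegressorMixin, BaseEstimator):
    """Partial least squares regression (single response, NIPALS).

    Parameters
    ----------
    n_components : int
        Number of latent variables h, 1 <= h <= min(n-1, p).

    Attributes
    ----------
    x_weights_ : (p, h) loading weights W, unit-norm columns
    x_loadings_ : (p, h) X loadings P
    y_loadings_ : (h,) y loadings q
    x_scores_ : (n, h) training scores
    coef_ : (p,) regression coefficients on centered data
    x_mean_, y_mean_ : training centers
    """

    def __init__(self, n_components: int = 9):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per y entry")
        n, p = X.shape
        h = int(self.n_components)
        if not 1 <= h <= min(n - 1, p):
            raise ValueError(
                f"n_components={h} out of range [1, {min(n - 1, p)}] for X of shape {X.shape}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        W = np.empty((p, h))
        P = np.empty((p, h))
        q = np.empty(h)
        S = np.empty((n, h))
        for a in range(h):
            w = Xc.T @ yc
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                raise np.linalg.LinAlgError(
                    f"rank deficiency: zero loading weight at component {a + 1}"
                )
            w /= norm
            s = Xc @ w
            ss = float(s @ s)
            if ss < 1e-12:
                raise np.linalg.LinAlgError(
                    f"rank deficiency: zero-variance score at component {a + 1}"
                )
            pa = Xc.T @ s / ss
            qa = float(yc @ s) / ss
            Xc = Xc - np.outer(s, pa)
            yc = yc - qa * s
            W[:, a], P[:, a], q[a], S[:, a] = w, pa, qa, s

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = S
        self.coef_ = self.coefficients_for(h)
        self.n_features_in_ = p
        return self

    def coefficients_for(self, h: int) -> np.ndarray:
        """Regression coefficients using only the first ``h`` fitted LVs."""
        check_is_fitted(self, "x_weights_")
        if not 1 <= h <= self.x_weights_.shape[1]:
            raise ValueError("h exceeds the number of fitted components")
        W, P, q = self.x_weights_[:, :h], self.x_loadings_[:, :h], self.y_loadings_[:h]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_components: int | None = None):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b = self.coef_ if n_components is None else self.coefficients_for(n_components)
        return (X - self.x_mean_) @ b + self.y_mean_


def fit_plsr(X, y, n_lv: int) -> PLSRRegressor:
    """Functional wrapper around :class:`PLSRRegressor`."""
    return PLSRRegressor(n_components=n_lv).fit(X, y)


# ---------------------------------------------------------------------------
# LSSVM


class LSSVMRegressor(RegressorMixin, BaseEstimator):
    """Least-squares SVM regression with an RBF kernel.

    The response is standardized internally (centered, unit variance) so the
    regularization grid behaves comparably across data sets; predictions are
    returned on the original scale.

    Attributes
    ----------
    alpha_ : (n,) dual coefficients (standardized-y scale)
    bias_ : float, intercept of the dual expansion
    X_fit_ : (n, p) training inputs
    kkt_residual_ : float, max-norm residual of the KKT system
    """

    def __init__(self, gamma: float = 32.0, sigma: float = 1.0):
        self.gamma = gamma
        self.sigma = sigma

    def _kernel(self, A, B) -> np.ndarray:
        d2 = cdist(A, B, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.sigma**2))

    def fit(self, X, y):
        if self.gamma <= 0 or self.sigma <= 0:
            raise ValueError("gamma and sigma must be positive")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X rows and y entries must align")
        n = X.shape[0]
        self.y_mean_ = float(y.mean())
        sd = float(y.std())
        self.y_scale_ = sd if sd > 0 else 1.0
        z = (y - self.y_mean_) / self.y_scale_

        K = self._kernel(X, X)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.concatenate([[0.0], z])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular LSSVM KKT system; a smaller gamma (larger ridge jitter "
                "I/gamma) usually regularizes it"
            ) from err
        self.bias_ = float(sol[0])
        self.alpha_ = sol[1:]
        self.X_fit_ = X
        self.kkt_residual_ = float(np.max(np.abs(A @ sol - rhs)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = self._kernel(X, self.X_fit_) @ self.alpha_ + self.bias_
        return z * self.y_scale_ + self.y_mean_


def fit_lssvm(X, y, gamma: float, sigma: float) -> LSSVMRegressor:
    """Functional wrapper around :class:`LSSVMRegressor`."""
    return LSSVMRegressor(gamma=gamma, sigma=sigma).fit(X, y)


# ---------------------------------------------------------------------------
# Cross-validation and hyperparameter selection


def _folds(n: int, k: int, seed: int):
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def kfold_cv(learner, X, y, k: int = 5, seed: int = 0) -> Metrics:
    """Seeded k-fold CV; metrics computed once on pooled out-of-fold predictions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    pred = np.empty_like(y)
    for tr, te in _folds(len(y), k, seed):
        model = clone(learner).fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return compute_metrics(y, pred)


def _cv_rmse_per_lv(X, y, max_lv: int, k: int, seed: int) -> np.ndarray:
    """RMSECV for every LV count 1..max_lv with one PLSR fit per fold.

    The NIPALS coefficient path makes the truncated-h predictions of a
    max_lv-component fit identical to separate h-component fits.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    folds = _folds(len(y), k, seed)
    cap = min(max_lv, X.shape[1], min(len(tr) for tr, _ in folds) - 1)
    preds = np.empty((cap, len(y)))
    for tr, te in folds:
        model = PLSRRegressor(n_components=cap).fit(X[tr], y[tr])
        for h in range(1, cap + 1):
            preds[h - 1, te] = model.predict(X[te], n_components=h)
    return np.sqrt(np.mean((preds - y[None, :]) ** 2, axis=1))


def select_n_lv(
    X, y, max_lv: int = 16, tol: float = 0.02, k: int = 5, seed: int = 0,
    n_repeats: int = 5,
) -> int:
    """Smallest LV count whose RMSECV is within ``tol`` of the minimum.

    Encodes the usual plateau rule: past the elbow the RMSECV decrease is no
    longer meaningful, so prefer the most parsimonious model on the plateau.
    The RMSECV curve is averaged over ``n_repeats`` fold reshuffles so the
    choice does not ride the noise of a single CV split.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % 2**31
    rmse = np.mean(
        [_cv_rmse_per_lv(X, y, max_lv, k, int(s)) for s in rep_seeds], axis=0
    )
    return plateau_lv(rmse, tol)


def plateau_lv(rmsecv: np.ndarray, tol: float = 0.02) -> int:
    """First LV count (1-based) whose RMSECV is within ``tol`` of the minimum."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    ok = np.flatnonzero(rmsecv <= (1.0 + tol) * rmsecv.min())
    return int(ok[0]) + 1


@dataclass
class LSSVMGridResult:
    """Two-stage grid search outcome in log2 coordinates."""

    log2_gamma: float
    log2_inv_sigma2: float
    rmsecv: float
    coarse_log2_gamma: float
    coarse_log2_inv_sigma2: float
    coarse_rmsecv: float
    n_coarse_evals: int
    n_fine_evals: int

    @property
    def gamma(self) -> float:
        return float(2.0**self.log2_gamma)

    @property
    def inv_sigma2(self) -> float:
        return float(2.0**self.log2_inv_sigma2)

    @property
    def sigma(self) -> float:
        return float(1.0 / np.sqrt(self.inv_sigma2))


def _lssvm_cv_rmse_factory(X, y, k: int, seed: int):
    """CV objective over (log2 gamma, log2 1/sigma^2), reusing the pairwise
    squared distances across all candidate pairs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    d2 = cdist(X, X, metric="sqeuclidean")
    folds = _folds(len(y), k, seed)

    def objective(lg: float, ls: float) -> float:
        gamma = 2.0**lg
        K = np.exp(-0.5 * d2 * 2.0**ls)
        pred = np.empty_like(y)
        for tr, te in folds:
            ym = y[tr].mean()
            ysd = y[tr].std() or 1.0
            z = (y[tr] - ym) / ysd
            m = len(tr)
            A = np.zeros((m + 1, m + 1))
            A[0, 1:] = 1.0
            A[1:, 0] = 1.0
            A[1:, 1:] = K[np.ix_(tr, tr)] + np.eye(m) / gamma
            sol = np.linalg.solve(A, np.concatenate([[0.0], z]))
            pred[te] = (K[np.ix_(te, tr)] @ sol[1:] + sol[0]) * ysd + ym
        return float(np.sqrt(np.mean((pred - y) ** 2)))

    return objective


def grid_search_lssvm(
    X,
    y,
    log2_range=(-8.0, 8.0),
    k: int = 5,
    seed: int = 0,
    coarse_step: float = 1.0,
    fine_step: float = 0.1,
    objective=None,
) -> LSSVMGridResult:
    """Two-stage grid search for (gamma, 1/sigma^2) minimizing 5-fold RMSECV.

    A coarse unit-step grid over ``log2_range`` squared locates the basin;
    a 0.1-step fine grid spanning +/-1 around the coarse optimum (clipped to
    the range) refines it.  ``objective`` may replace the CV criterion for
    testing.
    """
    lo, hi = map(float, log2_range)
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError("log2_range must be a finite increasing pair")
    if objective is None:
        objective = _lssvm_cv_rmse_factory(X, y, k, seed)

    def sweep(g_axis, s_axis):
        best = (np.inf, g_axis[0], s_axis[0])
        for g in g_axis:
            for s in s_axis:
                val = objective(float(g), float(s))
                if val < best[0]:
                    best = (val, float(g), float(s))
        return best

    n_steps = int(round((hi - lo) / coarse_step))
    axis = lo + coarse_step * np.arange(n_steps + 1)
    c_val, c_g, c_s = sweep(axis, axis)

    def fine_axis(center):
        a = center + fine_step * np.arange(-round(1.0 / fine_step), round(1.0 / fine_step) + 1)
        return np.clip(a, lo, hi)

    fg, fs = fine_axis(c_g), fine_axis(c_s)
    f_val, f_g, f_s = sweep(fg, fs)

    return LSSVMGridResult(
        log2_gamma=f_g,
        log2_inv_sigma2=f_s,
        rmsecv=f_val,
        coarse_log2_gamma=c_g,
        coarse_log2_inv_sigma2=c_s,
        coarse_rmsecv=c_val,
        n_coarse_evals=(n_steps + 1) ** 2,
        n_fine_evals=len(fg) * len(fs),
    )


# ---------------------------------------------------------------------------
# Serialization


def save_model(model, path, preprocessing: dict | None = None) -> None:
    """Persist a fitted model plus its preprocessing state to one HDF5 file.

    ``preprocessing`` records whatever the prediction path needs to replay
    (wavelength subset indices, SNV flag, crop cutoff, ...).
    """
    check_is_fitted(model)
    with h5py.File(path, "w") as f:
        f.attrs["model_class"] = type(model).__name__
        f.attrs["params"] = json.dumps(model.get_params())
        f.attrs["preprocessing"] = json.dumps(preprocessing or {})
        for name, value in vars(model).items():
            if not name.endswith("_") or name.startswith("_"):
                continue
            if isinstance(value, np.ndarray):
                f.create_dataset(name, data=value)
            else:
                f.attrs[name] = value


def load_model(path):
    """Inverse of :func:`save_model`; returns (model, preprocessing dict)."""
    classes = {"PLSRRegressor": PLSRRegressor, "LSSVMRegressor": LSSVMRegressor}
    with h5py.File(path, "r") as f:
        cls = classes[f.attrs["model_class"]]
        model = cls(**json.loads(f.attrs["params"]))
        for name in f.keys():
            setattr(model, name, f[name][()])
        for name, value in f.attrs.items():
            if name.endswith("_"):
                setattr(model, name, value)
        preprocessing = json.loads(f.attrs["preprocessing"])
    return model, preprocessing
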