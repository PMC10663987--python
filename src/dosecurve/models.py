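"""Per-gene dose-response models.

Three model families, exposed as scikit-learn style estimators:

* :class:`PenalizedSplineGAM` — a generalized additive model of log2
  expression against log10 concentration, ``y_i = f(x_i) + eps_i``, with
  ``f`` a penalized thin-plate regression spline. With several time levels
  each level gets its own coefficient vector over one shared basis,
  ``y_i = sum_k f_k(x_i) 1[t_i = k] + eps_i``. The smoothing parameter is
  chosen by generalized cross-validation (GCV).
* :class:`HuberANOVA` — a robust cell-means ANOVA ``y_mkj = mu_mk + eps_mkj``
  fitted by Huber M-estimation (IRLS), used when the number of distinct
  nonzero concentrations is small (C <= 4).
* :class:`OLSANOVA` — the same cell-means model by ordinary least squares;
  kept as the non-robust baseline for robustness comparisons.

All estimators accept ``X`` of shape (n, 1) (log10 dose) or (n, 2)
(log10 dose, integer time code) and expose fitted coefficients ``coef_``,
their covariance ``cov_``, residual scale ``scale_``, residual degrees of
freedom ``df_resid_`` and, for the GAM, the effective degrees of freedom
``edf_`` (trace of the influence matrix).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

import statsmodels.api as sm

from .basis import build_spline_basis
from .design import DoseDesign

__all__ = [
    "PenalizedSplineGAM",
    "HuberANOVA",
    "OLSANOVA",
    "select_model_kind",
    "fit_gam",
    "fit_rlm",
    "fit_lm",
    "predict_with_se",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a model cannot be fitted to the data."""


def _split_X(X) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] not in (1, 2):
        raise ValueError("X must have shape (n, 1) or (n, 2)")
    x = X[:, 0]
    t = X[:, 1].astype(int) if X.shape[1] == 2 else np.zeros(len(x), dtype=int)
    return x, t


class PenalizedSplineGAM(RegressorMixin, BaseEstimator):
    """Penalized thin-plate spline regression with GCV-selected smoothing.

    Parameters
    ----------
    basis_dim : int, default 4
        Total spline basis dimension per time level, including the
        2-dimensional linear null space.
    log10_lambda_bounds : tuple, default (-8, 8)
        Search interval for log10 of the smoothing parameter.

    Attributes
    ----------
    coef_ : ndarray, shape (K * basis_dim,)
        Stacked per-time-level spline coefficients.
    cov_ : ndarray
        Bayesian posterior covariance ``sigma^2 (X'X + lambda*S)^{-1}``.
    scale_ : float
        Residual standard deviation, ``sqrt(RSS / (n - edf))``.
    lambda_ : float
        Selected smoothing parameter.
    edf_ : float
        Effective degrees of freedom (trace of the influence matrix).
    df_resid_ : float
        ``n - edf``.
    """

    kind = "GAM"

    def __init__(self, basis_dim: int = 4, log10_lambda_bounds: tuple = (-8.0, 8.0),
                 coef_cov: str = "bayesian", gcv_gamma: float = 1.0):
        self.basis_dim = basis_dim
        self.log10_lambda_bounds = log10_lambda_bounds
        self.coef_cov = coef_cov
        self.gcv_gamma = gcv_gamma

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        x, t = _split_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != x.size:
            raise ValueError("X and y length mismatch")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in X or y")

        self.time_levels_ = np.unique(t)
        K = self.time_levels_.size
        basis = build_spline_basis(x, J=self.basis_dim)
        J = basis.J
        p = K * J

        B = basis.evaluate(x)                       # (n, J)
        Xd = np.zeros((x.size, p))
        for k, lev in enumerate(self.time_levels_):
            rows = t == lev
            Xd[rows, k * J:(k + 1) * J] = B[rows]
        S = np.kron(np.eye(K), basis.S)

        n = y.size
        if n <= K * basis.nullspace_dim:
            raise FitError(f"too few samples (n={n}) for {K} time level(s)")

        XtX = Xd.T @ Xd
        try:
            R = linalg.cholesky(XtX, lower=False)
        except linalg.LinAlgError as exc:
            raise FitError("rank-deficient design (a time level lacks "
                           "enough distinct doses)") from exc
        Rinv = linalg.solve_triangular(R, np.eye(p), lower=False)
        M = Rinv.T @ S @ Rinv
        d_eig, V_eig = linalg.eigh(0.5 * (M + M.T))
        d_eig = np.clip(d_eig, 0.0, None)
        T = Rinv @ V_eig                            # reparametrization
        Q = Xd @ T                                  # orthonormal columns
        z = Q.T @ y
        rss_perp = max(float(y @ y - z @ z), 0.0)

        # gcv_gamma > 1 charges extra per effective df, the standard guard
        # against GCV's tendency to undersmooth at small n
        gamma = self.gcv_gamma

        def gcv(rho: float) -> float:
            lam = 10.0 ** rho
            a = 1.0 / (1.0 + lam * d_eig)
            rss = rss_perp + float(((1.0 - a) ** 2) @ (z ** 2))
            tr = float(a.sum())
            denom = n - gamma * tr
            if denom <= 0:
                return np.inf
            return n * rss / denom ** 2

        lo, hi = self.log10_lambda_bounds
        grid = np.linspace(lo, hi, 33)
        vals = [gcv(r) for r in grid]
        i0 = int(np.argmin(vals))
        a_lo = grid[max(i0 - 1, 0)]
        a_hi = grid[min(i0 + 1, len(grid) - 1)]
        if a_lo < a_hi:
            res = optimize.minimize_scalar(
                gcv, bounds=(a_lo, a_hi), method="bounded",
                options={"xatol": 1e-4})
            rho = float(res.x) if res.fun <= vals[i0] else float(grid[i0])
        else:
            rho = float(grid[i0])
        if not np.isfinite(gcv(rho)):
            raise FitError("GCV search failed to locate a finite optimum")

        lam = 10.0 ** rho
        a = 1.0 / (1.0 + lam * d_eig)
        coef = T @ (a * z)
        edf = float(a.sum())
        rss = rss_perp + float(((1.0 - a) ** 2) @ (z ** 2))
        df_resid = n - edf
        if df_resid <= 0:
            raise FitError("no residual degrees of freedom")
        sigma2 = rss / df_resid
        # coefficient covariance in the eigen parametrization: with
        # G = (X'X + lambda S)^(-1) = T diag(a) T' and T'X'XT = I,
        # the frequentist sandwich G X'X G is T diag(a^2) T' while the
        # Bayesian posterior form is T diag(a) T'
        if self.coef_cov == "sandwich":
            cov = sigma2 * (T * a ** 2) @ T.T
        elif self.coef_cov == "bayesian":
            cov = sigma2 * (T * a) @ T.T
        else:
            raise ValueError("coef_cov must be 'sandwich' or 'bayesian'")

        self.basis_ = basis
        self.coef_ = coef
        self.cov_ = 0.5 * (cov + cov.T)
        self.scale_ = float(np.sqrt(sigma2))
        self.lambda_ = lam
        self.edf_ = edf
        self.df_resid_ = float(df_resid)
        self.n_samples_ = int(n)
        self.x_min_ = float(np.min(x))
        self.x_max_ = float(np.max(x))
        self.converged_ = True
        X_arr = np.asarray(X)
        self.n_features_in_ = int(X_arr.shape[1]) if X_arr.ndim == 2 else 1
        return self

    # -- prediction --------------------------------------------------------

    def _check_range(self, x: np.ndarray) -> None:
        tol = 1e-9
        if np.any(x < self.x_min_ - tol) or np.any(x > self.x_max_ + tol):
            raise ValueError(
                f"query x outside the fitted dose range "
                f"[{self.x_min_:.4g}, {self.x_max_:.4g}]: splines do not extrapolate"
            )

    def _time_code(self, time_level) -> int:
        # fit wrappers attach time_map_ translating design labels (e.g. 24 h)
        # to the integer codes the estimator was fitted on
        tmap = getattr(self, "time_map_", None)
        if tmap is not None and time_level in tmap:
            return tmap[time_level]
        return int(time_level)

    def basis_row(self, x: float, time_level=0) -> np.ndarray:
        """Full-length coefficient-space row vector b(x) for one time level."""
        check_is_fitted(self, "coef_")
        time_level = self._time_code(time_level)
        k = int(np.searchsorted(self.time_levels_, time_level))
        if k >= self.time_levels_.size or self.time_levels_[k] != time_level:
            raise ValueError(f"unknown time level {time_level!r}")
        J = self.basis_.J
        row = np.zeros(self.coef_.size)
        row[k * J:(k + 1) * J] = self.basis_.evaluate(x)[0]
        return row

    def curve(self, x, time_level=0, check_range: bool = True) -> np.ndarray:
        """Fitted values f_k(x) for one time level."""
        check_is_fitted(self, "coef_")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if check_range:
            self._check_range(x)
        k = int(np.searchsorted(self.time_levels_, self._time_code(time_level)))
        J = self.basis_.J
        beta = self.coef_[k * J:(k + 1) * J]
        return self.basis_.evaluate(x) @ beta

    def curve_deriv(self, x, time_level=0) -> np.ndarray:
        """First derivative f_k'(x) for one time level."""
        check_is_fitted(self, "coef_")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = int(np.searchsorted(self.time_levels_, self._time_code(time_level)))
        J = self.basis_.J
        beta = self.coef_[k * J:(k + 1) * J]
        return self.basis_.derivative(x) @ beta

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x, t = _split_X(X)
        self._check_range(x)
        out = np.empty_like(x)
        for lev in np.unique(t):
            rows = t == lev
            out[rows] = self.curve(x[rows], time_level=lev)
        return out

    def predict_se(self, X) -> np.ndarray:
        """Pointwise standard error of the fitted curve."""
        check_is_fitted(self, "coef_")
        x, t = _split_X(X)
        self._check_range(x)
        se = np.empty_like(x)
        for i in range(x.size):
            row = self.basis_row(x[i], t[i])
            se[i] = np.sqrt(max(row @ self.cov_ @ row, 0.0))
        return se


class _CellMeansMixin:
    """Shared cell-index machinery of the ANOVA estimators."""

    def _cells(self, x: np.ndarray, t: np.ndarray):
        key = np.column_stack([x, t.astype(float)])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        return uniq, inv

    def _time_code(self, time_level) -> int:
        tmap = getattr(self, "time_map_", None)
        if tmap is not None and time_level in tmap:
            return tmap[time_level]
        return int(time_level)

    def _cell_index(self, x: float, time_level=0) -> int:
        check_is_fitted(self, "coef_")
        match = (np.isclose(self.cells_[:, 0], x, atol=1e-8)
                 & (self.cells_[:, 1] == float(self._time_code(time_level))))
        idx = np.flatnonzero(match)
        if idx.size != 1:
            raise ValueError(
                f"x={x!r}, time={time_level!r} is not a fitted design cell "
                "(cell-means models only predict at design points)")
        return int(idx[0])

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x, t = _split_X(X)
        return np.array([self.coef_[self._cell_index(xi, ti)]
                         for xi, ti in zip(x, t)])

    def predict_se(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        x, t = _split_X(X)
        return np.array([
            np.sqrt(max(self.cov_[j, j], 0.0))
            for j in (self._cell_index(xi, ti) for xi, ti in zip(x, t))
        ])


class HuberANOVA(_CellMeansMixin, RegressorMixin, BaseEstimator):
    """Robust one/two-way cell-means ANOVA by Huber M-estimation.

    Each (concentration, time) cell receives its own mean, estimated by IRLS
    with the Huber psi function (tuning constant 1.345) and MAD residual
    scale, which bounds the influence of gross outliers. With no residual
    beyond the Huber threshold the estimates coincide with OLS.
    """

    kind = "RLM"

    def __init__(self, huber_t: float = 1.345, tol: float = 1e-8, maxiter: int = 50):
        self.huber_t = huber_t
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, X, y):
        x, t = _split_X(X)
        y = np.asarray(y, dtype=float).ravel()
        cells, inv = self._cells(x, t)
        p = cells.shape[0]
        n = y.size
        if n <= p:
            raise FitError(f"no residual degrees of freedom (n={n}, cells={p})")
        D = np.zeros((n, p))
        D[np.arange(n), inv] = 1.0

        self.degenerate_ = False
        means = np.array([y[inv == j].mean() for j in range(p)])
        resid = y - means[inv]
        mad_scale = sm.robust.scale.mad(resid, center=0)
        if mad_scale <= 0 or not np.isfinite(mad_scale):
            # all replicates (essentially) identical: exact means, zero scale
            self.coef_ = means
            self.cov_ = np.zeros((p, p))
            self.scale_ = 0.0
            self.degenerate_ = True
            self.converged_ = True
        else:
            model = sm.RLM(y, D, M=sm.robust.norms.HuberT(t=self.huber_t))
            res = model.fit(scale_est="mad", conv="coefs",
                            tol=self.tol, maxiter=self.maxiter)
            self.coef_ = np.asarray(res.params)
            self.cov_ = np.asarray(res.bcov_scaled)
            self.scale_ = float(res.scale)
            self.converged_ = bool(getattr(res, "converged", True))

        self.cells_ = cells
        self.time_levels_ = np.unique(t)
        self.df_resid_ = float(n - p)
        self.edf_ = float(p)
        self.n_samples_ = int(n)
        self.n_params_ = p
        return self


class OLSANOVA(_CellMeansMixin, RegressorMixin, BaseEstimator):
    """Cell-means ANOVA by ordinary least squares (non-robust baseline)."""

    kind = "LM"

    def fit(self, X, y):
        x, t = _split_X(X)
        y = np.asarray(y, dtype=float).ravel()
        cells, inv = self._cells(x, t)
        p = cells.shape[0]
        n = y.size
        if n <= p:
            raise FitError(f"no residual degrees of freedom (n={n}, cells={p})")
        counts = np.bincount(inv, minlength=p).astype(float)
        means = np.bincount(inv, weights=y, minlength=p) / counts
        rss = float(np.sum((y - means[inv]) ** 2))
        sigma2 = rss / (n - p)
        self.coef_ = means
        self.cov_ = np.diag(sigma2 / counts)
        self.scale_ = float(np.sqrt(sigma2))
        self.cells_ = cells
        self.time_levels_ = np.unique(t)
        self.df_resid_ = float(n - p)
        self.edf_ = float(p)
        self.n_samples_ = int(n)
        self.n_params_ = p
        self.converged_ = True
        self.degenerate_ = sigma2 == 0.0
        return self


def select_model_kind(C: int) -> str:
    """Model-family gate: spline GAM for C > 4 distinct nonzero doses, robust ANOVA otherwise."""
    C = int(C)
    if C < 1:
        raise ValueError("C must be at least 1")
    return "GAM" if C > 4 else "RLM"


# -- thin functional wrappers over the estimators --------------------------

def _design_Xy(design: DoseDesign, y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    if y.size != design.n:
        raise ValueError("y length does not match the design")
    return design.design_matrix_input(), y


def fit_gam(design: DoseDesign, y, basis_dim: int = 4,
            log10_lambda_bounds: tuple = (-8.0, 8.0)) -> PenalizedSplineGAM:
    X, y = _design_Xy(design, y)
    est = PenalizedSplineGAM(basis_dim=basis_dim,
                             log10_lambda_bounds=log10_lambda_bounds).fit(X, y)
    est.cp_ = design.cp
    est.time_map_ = {t: k for k, t in enumerate(design.time_levels.tolist())}
    return est


def fit_rlm(design: DoseDesign, y, huber_t: float = 1.345) -> HuberANOVA:
    X, y = _design_Xy(design, y)
    est = HuberANOVA(huber_t=huber_t).fit(X, y)
    est.cp_ = design.cp
    est.time_map_ = {t: k for k, t in enumerate(design.time_levels.tolist())}
    return est


def fit_lm(design: DoseDesign, y) -> OLSANOVA:
    X, y = _design_Xy(design, y)
    est = OLSANOVA().fit(X, y)
    est.cp_ = design.cp
    est.time_map_ = {t: k for k, t in enumerate(design.time_levels.tolist())}
    return est


def predict_with_se(fit, x: float, time_level=0) -> tuple[float, float]:
    """Fitted value and its standard error at one design/query point."""
    X = np.array([[float(x), float(time_level)]])
    return float(fit.predict(X)[0]), float(fit.predict_se(X)[0])
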