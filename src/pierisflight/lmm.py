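"""Random-intercept linear mixed models with Satterthwaite inference.

The comparative analyses use one random-effect structure throughout:
a Gaussian random intercept per individual,

    y = X beta + Z u + e,   u ~ N(0, sigma_g^2 I_m),  e ~ N(0, sigma_e^2 I_n)

which admits a fast profiled-REML fit: for a given variance ratio
lambda = sigma_g^2 / sigma_e^2 the GLS estimates and the profiled
criterion are closed-form block computations, so the fit reduces to a
1-D optimization.  Denominator degrees of freedom for t/F tests use the
Satterthwaite approximation (delta method on the REML variance-
component covariance), mirroring the fractional dfs conventional in
this literature.  ML log-likelihoods (for AIC/AICc model selection)
are available from the same machinery.

statsmodels' MixedLM fits the identical model and serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

SINGULAR_TOL = 1e-8


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    _, inv = np.unique(groups, return_inverse=True)
    return [np.flatnonzero(inv == g) for g in range(inv.max() + 1)]


class RandomInterceptModel:
    """Linear mixed model with one random intercept per group.

    Parameters
    ----------
    y : array, shape (n,)
    X : array, shape (n, p)
        Fixed-effects design matrix (including intercept).
    groups : array, shape (n,)
        Group labels for the random intercept.
    exog_names : list of str, optional
        Column names for the coefficient table.
    """

    def __init__(self, y, X, groups, exog_names=None, design_info=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.groups = np.asarray(groups)
        self.n, self.p = self.X.shape
        if len(self.y) != self.n or len(self.groups) != self.n:
            raise ValueError("y, X and groups must have matching lengths")
        self.idx = _group_indices(self.groups)
        self.m = len(self.idx)
        if self.n < self.m:
            raise ValueError("more groups than observations")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.p)])
        self.design_info = design_info
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effects design matrix is rank deficient")

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str):
        """Build from a patsy formula and a grouping column name."""
        import patsy

        y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
        rows = X_dm.index
        return cls(np.asarray(y_dm).ravel(), np.asarray(X_dm),
                   data.loc[rows, groups].to_numpy(),
                   exog_names=list(X_dm.columns),
                   design_info=X_dm.design_info)

    # -- GLS pieces for a given variance ratio ------------------------------

    def _gls(self, lam: float):
        """GLS quantities at ratio lam; W = sigma_e^2 V^{-1}."""
        XtWX = self.X.T @ self.X
        XtWy = self.X.T @ self.y
        for ix in self.idx:
            ni = len(ix)
            c = lam / (1.0 + lam * ni)
            sx = self.X[ix].sum(axis=0)
            sy = self.y[ix].sum()
            XtWX = XtWX - c * np.outer(sx, sx)
            XtWy = XtWy - c * sx * sy
        beta = np.linalg.solve(XtWX, XtWy)
        r = self.y - self.X @ beta
        rWr = float(r @ r)
        for ix in self.idx:
            ni = len(ix)
            c = lam / (1.0 + lam * ni)
            rWr -= c * r[ix].sum() ** 2
        logdet_blocks = float(sum(np.log1p(lam * len(ix)) for ix in self.idx))
        return beta, XtWX, rWr, logdet_blocks

    def _profiled_crit(self, lam: float, reml: bool) -> float:
        _, XtWX, rWr, logdet = self._gls(lam)
        if rWr <= 0:
            return np.inf
        if reml:
            sign, logdet_xwx = np.linalg.slogdet(XtWX)
            return ((self.n - self.p) * np.log(rWr) + logdet + logdet_xwx)
        return self.n * np.log(rWr) + logdet

    def _loglik(self, lam: float, reml: bool) -> float:
        _, XtWX, rWr, logdet = self._gls(lam)
        if reml:
            df = self.n - self.p
            s2 = rWr / df
            _, logdet_xwx = np.linalg.slogdet(XtWX)
            return -0.5 * (df * np.log(2 * np.pi * s2) + df + logdet
                           + logdet_xwx - self.p * np.log(s2))
        s2 = rWr / self.n
        return -0.5 * (self.n * np.log(2 * np.pi * s2) + self.n + logdet)

    def _optimize_lambda(self, reml: bool) -> float:
        obj = lambda loglam: self._profiled_crit(np.exp(loglam), reml)
        res = minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                              options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        if self._profiled_crit(0.0, reml) <= res.fun:
            lam = 0.0
        return lam

    def fit(self, reml: bool = True) -> "MixedLMResult":
        """Profiled (RE)ML fit.  A near-zero random-intercept variance
        is flagged singular (the model degenerates to OLS)."""
        lam = self._optimize_lambda(reml)
        beta, XtWX, rWr, _ = self._gls(lam)
        dof = self.n - self.p if reml else self.n
        sigma_e2 = rWr / dof
        sigma_g2 = lam * sigma_e2
        cov = np.linalg.inv(XtWX) * sigma_e2
        singular = sigma_g2 <= SINGULAR_TOL * max(sigma_e2, 1e-300)
        if singular:
            warnings.warn(
                "random-intercept variance estimated at the zero "
                "boundary; inference is OLS-like", stacklevel=2)
        ll_reml = self._loglik(lam, reml=True)
        # ML quantities for information criteria
        lam_ml = self._optimize_lambda(reml=False) if reml else lam
        ll_ml = self._loglik(lam_ml, reml=False)
        return MixedLMResult(
            model=self, reml=reml, params=beta, cov_params=cov,
            sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2),
            loglik_reml=float(ll_reml), loglik_ml=float(ll_ml),
            singular=bool(singular))

    # -- variance of a contrast as a function of the variance components ----

    def _contrast_var(self, c: np.ndarray, sigma_g2: float,
                      sigma_e2: float) -> float:
        A = self.X.T @ self.X / sigma_e2
        for ix in self.idx:
            ni = len(ix)
            w = sigma_g2 / (sigma_e2 * (sigma_e2 + sigma_g2 * ni))
            sx = self.X[ix].sum(axis=0)
            A -= w * np.outer(sx, sx)
        return float(c @ np.linalg.solve(A, c))

    def _reml_loglik_theta(self, sigma_g2: float, sigma_e2: float) -> float:
        """REML log-likelihood at arbitrary (sigma_g2, sigma_e2) >= 0."""
        if sigma_e2 <= 0 or sigma_g2 < 0:
            return -np.inf
        lam = sigma_g2 / sigma_e2
        _, XtWX, rWr, logdet = self._gls(lam)
        logdet_V = self.n * np.log(sigma_e2) + logdet
        _, ld_xwx = np.linalg.slogdet(XtWX / sigma_e2)
        quad = rWr / sigma_e2
        return -0.5 * (logdet_V + ld_xwx + quad
                       + (self.n - self.p) * np.log(2 * np.pi))


@dataclass
class MixedLMResult:
    """Fitted random-intercept model with Satterthwaite inference."""

    model: RandomInterceptModel
    reml: bool
    params: np.ndarray
    cov_params: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    loglik_ml: float
    singular: bool
    _theta_cov: np.ndarray | None = field(default=None, repr=False)

    # -- basic quantities ----------------------------------------------------

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def n_obs(self) -> int:
        return self.model.n

    @property
    def n_groups(self) -> int:
        return self.model.m

    @property
    def df_resid(self) -> int:
        return self.model.n - self.model.p

    @property
    def k_params(self) -> int:
        return self.model.p + 2  # fixed effects + two variances

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik_ml + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.n_obs
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    # -- Satterthwaite machinery --------------------------------------------

    def _theta_covariance(self) -> np.ndarray:
        """Asymptotic covariance of (sigma_g2, sigma_e2) from the
        numeric REML Hessian."""
        if self._theta_cov is not None:
            return self._theta_cov
        th = np.array([max(self.sigma_g2, 0.0), self.sigma_e2])
        h = np.maximum(1e-4 * np.abs(th), 1e-10)
        if th[0] - h[0] < 0:  # boundary: one-sided step for sigma_g2
            h[0] = max(th[0] / 2.0, 1e-10)

        def ll(t):
            return self.model._reml_loglik_theta(max(t[0], 0.0), t[1])

        H = np.empty((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    ll(th + ei + ej) - ll(th + ei - ej)
                    - ll(th - ei + ej) + ll(th - ei - ej)
                ) / (4.0 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        if not np.all(np.isfinite(cov)):
            cov = np.zeros((2, 2))
        self._theta_cov = cov
        return cov

    def contrast_df(self, c: np.ndarray) -> float:
        """Satterthwaite denominator df for the contrast c' beta."""
        c = np.asarray(c, dtype=float)
        th = np.array([max(self.sigma_g2, 0.0), self.sigma_e2])
        f0 = self.model._contrast_var(c, th[0], th[1])
        h = np.maximum(1e-5 * np.maximum(th, self.sigma_e2), 1e-12)
        grad = np.empty(2)
        for i in range(2):
            tp, tm = th.copy(), th.copy()
            tp[i] += h[i]
            tm[i] = max(tm[i] - h[i], 0.0)
            grad[i] = (self.model._contrast_var(c, *tp)
                       - self.model._contrast_var(c, *tm)) / (tp[i] - tm[i])
        denom = float(grad @ self._theta_covariance() @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.df_resid)
        df = 2.0 * f0 ** 2 / denom
        return float(np.clip(df, 1.0, 10.0 * self.n_obs))

    def t_test(self, c: np.ndarray) -> tuple[float, float, float, float]:
        """(estimate, se, satterthwaite df, p) for contrast c' beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov_params @ c))
        df = self.contrast_df(c)
        t = est / se if se > 0 else np.nan
        p = 2.0 * sps.t.sf(abs(t), df)
        return est, se, df, p

    def coef_table(self) -> pd.DataFrame:
        """Per-coefficient table with Satterthwaite df, F (= t^2) and p."""
        rows = []
        for j, name in enumerate(self.exog_names):
            c = np.zeros(self.model.p)
            c[j] = 1.0
            est, se, df, p = self.t_test(c)
            rows.append({"term": name, "estimate": est, "se": se,
                         "df": df, "F": (est / se) ** 2, "p": p})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.coef_table()
        lines = [
            "Random-intercept linear mixed model "
            f"({'REML' if self.reml else 'ML'})",
            f"  n_obs = {self.n_obs}, n_groups = {self.n_groups}",
            f"  sigma^2 (individual) = {self.sigma_g2:.5g}"
            + ("  [singular]" if self.singular else ""),
            f"  sigma^2 (residual)   = {self.sigma_e2:.5g}",
            f"  logLik (REML) = {self.loglik_reml:.3f}, "
            f"AICc (ML) = {self.aicc:.2f}",
            "",
            tab.to_string(index=False,
                          float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
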