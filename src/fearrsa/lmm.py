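"""Random-intercept linear mixed models with Satterthwaite degrees of freedom.

The analyses in this package all share one model family: a Gaussian response
with fixed factorial effects and a random intercept per participant,

    y = X beta + Z b + e,   b ~ N(0, tau^2 I_g),   e ~ N(0, sigma^2 I_n),

estimated by restricted maximum likelihood (REML). Denominator degrees of
freedom for fixed-effect t and F tests use the Satterthwaite approximation:
for a contrast l the df is 2 f(theta)^2 / (g' A g), where f(theta) =
l' Cov(beta_hat; theta) l, g its gradient in theta = (sigma^2, tau^2), and A
the asymptotic covariance of theta_hat (inverse observed REML information).
Multi-df terms combine single-contrast dfs over the eigenvectors of L C L'.

The random-intercept structure admits closed-form per-group linear algebra
(V_j = sigma^2 I + tau^2 11'), so fits are exact and fast; only the scalar
variance ratio is optimized numerically.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LMMResult",
    "TermTest",
    "CoefTest",
    "fit_random_intercept",
    "build_factorial_design",
    "anova_lmm",
    "SingularFitWarning",
]


class SingularFitWarning(UserWarning):
    """The random-intercept variance hit the boundary (model is effectively OLS)."""


@dataclass
class CoefTest:
    name: str
    estimate: float
    se: float
    tstat: float
    df: float
    pvalue: float


@dataclass
class TermTest:
    term: str
    fstat: float
    df_num: float
    df_den: float
    pvalue: float


@dataclass
class LMMResult:
    """Fitted random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    loglik_reml: float
    n_obs: int
    n_groups: int
    column_names: list[str]
    singular: bool
    _X: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _group_slices: list[np.ndarray] = field(repr=False)

    # ---- internal REML machinery -------------------------------------

    def _gls_pieces(self, sigma2: float, tau2: float):
        """Return (XtViX, XtViy, ytViy, logdetV) for V = s2 I + t2 11' per group."""
        p = self._X.shape[1]
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdetV = 0.0
        for idx in self._group_slices:
            Xg = self._X[idx]
            yg = self._y[idx]
            nj = len(idx)
            # V_j^{-1} = (1/s2) [I - (t2/(s2 + nj t2)) 11']
            c = tau2 / (sigma2 + nj * tau2)
            sx = Xg.sum(axis=0)
            sy = yg.sum()
            XtViX += (Xg.T @ Xg - c * np.outer(sx, sx)) / sigma2
            XtViy += (Xg.T @ yg - c * sx * sy) / sigma2
            ytViy += (yg @ yg - c * sy * sy) / sigma2
            logdetV += nj * np.log(sigma2) + np.log1p(nj * tau2 / sigma2)
        return XtViX, XtViy, ytViy, logdetV

    def neg2_reml(self, sigma2: float, tau2: float) -> float:
        """-2 × REML log-likelihood at (sigma2, tau2), up to an additive constant."""
        if sigma2 <= 0 or tau2 < 0:
            return np.inf
        XtViX, XtViy, ytViy, logdetV = self._gls_pieces(sigma2, tau2)
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        yPy = ytViy - XtViy @ beta
        return logdetV + logdetXVX + yPy

    def _cov_beta_at(self, sigma2: float, tau2: float) -> np.ndarray:
        XtViX, *_ = self._gls_pieces(sigma2, tau2)
        return np.linalg.inv(XtViX)

    def _theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of (sigma2, tau2): 2 × inverse Hessian of -2 REML ll."""
        th = np.array([self.sigma2, self.tau2])
        h = np.maximum(1e-4 * np.maximum(np.abs(th), 1e-8), 1e-10)
        H = np.zeros((2, 2))
        f0 = self.neg2_reml(*th)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                fpp = self.neg2_reml(*(th + ei + ej))
                fpm = self.neg2_reml(*(th + ei - ej))
                fmp = self.neg2_reml(*(th - ei + ej))
                fmm = self.neg2_reml(*(th - ei - ej))
                if not np.isfinite([fpp, fpm, fmp, fmm]).all():
                    # boundary (tau2 ~ 0): one-sided second difference
                    fp = self.neg2_reml(*(th + ei + ej))
                    f1 = self.neg2_reml(*(th + ei))
                    f2 = self.neg2_reml(*(th + ej))
                    H[i, j] = H[j, i] = (fp - f1 - f2 + f0) / (h[i] * h[j])
                    continue
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        # Hessian of -2ll -> information = H/2; Var(theta) = 2 H^{-1}
        try:
            A = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            A = np.full((2, 2), np.nan)
        return A

    def _satterthwaite_df(self, ell: np.ndarray, A: np.ndarray) -> float:
        """Satterthwaite df for the scalar contrast ell' beta."""
        th = np.array([self.sigma2, self.tau2])

        def f(theta):
            return float(ell @ self._cov_beta_at(theta[0], max(theta[1], 0.0)) @ ell)

        h = np.maximum(1e-4 * np.maximum(np.abs(th), 1e-8), 1e-10)
        g = np.zeros(2)
        for i in range(2):
            e = np.eye(2)[i] * h[i]
            if th[i] - h[i] <= 0 and i == 0:
                g[i] = (f(th + e) - f(th)) / h[i]
            elif th[i] - h[i] < 0:
                g[i] = (f(th + e) - f(th)) / h[i]
            else:
                g[i] = (f(th + e) - f(th - e)) / (2 * h[i])
        denom = float(g @ A @ g)
        fval = f(th)
        if not np.isfinite(denom) or denom <= 0:
            return float(self.n_obs - len(self.beta))
        df = 2.0 * fval**2 / denom
        return float(np.clip(df, 1.0, self.n_obs - len(self.beta)))

    # ---- public tests -------------------------------------------------

    def contrast_ttest(self, ell: np.ndarray, name: str = "contrast") -> CoefTest:
        """t test of the scalar contrast ell' beta with Satterthwaite df."""
        ell = np.asarray(ell, dtype=float)
        est = float(ell @ self.beta)
        se = float(np.sqrt(ell @ self.cov_beta @ ell))
        A = self._theta_cov()
        df = self._satterthwaite_df(ell, A)
        t = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        return CoefTest(name, est, se, t, df, p)

    def coef_tests(self) -> list[CoefTest]:
        A = self._theta_cov()
        out = []
        for i, nm in enumerate(self.column_names):
            ell = np.zeros(len(self.beta))
            ell[i] = 1.0
            est = float(self.beta[i])
            se = float(np.sqrt(self.cov_beta[i, i]))
            df = self._satterthwaite_df(ell, A)
            t = est / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            out.append(CoefTest(nm, est, se, t, df, p))
        return out

    def term_ftest(self, L: np.ndarray, term: str = "term") -> TermTest:
        """F test of L beta = 0 with the eigenvector-combined Satterthwaite df.

        Follows the standard multi-df construction: eigendecompose
        M = L C L', convert to q independent single-df contrasts, take each
        contrast's Satterthwaite df nu_i, and combine through
        E = sum nu_i/(nu_i - 2), df_den = 2E/(E - q).
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        M = L @ self.cov_beta @ L.T
        evals, evecs = np.linalg.eigh(M)
        keep = evals > 1e-12 * evals.max()
        evals, evecs = evals[keep], evecs[:, keep]
        q_eff = len(evals)
        Lb = L @ self.beta
        t2 = (evecs.T @ Lb) ** 2 / evals
        F = float(t2.sum() / q_eff)
        A = self._theta_cov()
        nus = []
        for i in range(q_eff):
            ell = L.T @ evecs[:, i]
            nus.append(self._satterthwaite_df(ell, A))
        nus = np.asarray(nus)
        good = nus > 2
        if good.any():
            E = float((nus[good] / (nus[good] - 2)).sum())
            df_den = 2 * E / (E - q_eff) if E > q_eff else float(self.n_obs - len(self.beta))
        else:
            df_den = float(self.n_obs - len(self.beta))
        p = float(stats.f.sf(F, q_eff, df_den))
        return TermTest(term, F, float(q_eff), df_den, p)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    column_names: list[str] | None = None,
) -> LMMResult:
    """REML fit of ``y = X beta + (1|group) + e``.

    Profiles the variance ratio lambda = tau^2/sigma^2 and optimizes it on a
    log grid with Brent refinement; beta and sigma^2 then follow in closed
    form. A boundary solution (tau^2 -> 0) is flagged as a singular fit and
    warned about — the fit then coincides with ordinary least squares, whose
    F tests remain valid, so no separate fallback model is needed.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if len(y) != n or len(groups) != n:
        raise ValueError("y, X, groups must have matching lengths")
    uniq, inv = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    if np.ptp(y) == 0.0:
        raise ValueError("response is constant; the model is undefined")
    if column_names is None:
        column_names = [f"x{i}" for i in range(p)]
    slices = [np.flatnonzero(inv == g) for g in range(len(uniq))]

    res = LMMResult(
        beta=np.zeros(p), cov_beta=np.eye(p), sigma2=1.0, tau2=0.0,
        loglik_reml=np.nan, n_obs=n, n_groups=len(uniq),
        column_names=list(column_names), singular=False,
        _X=X, _y=y, _group_slices=slices,
    )

    def profiled(log_lam: float) -> float:
        lam = np.exp(log_lam)
        # work at sigma2 = 1, then profile sigma2 out
        XtViX, XtViy, ytViy, logdetV0 = res._gls_pieces(1.0, lam)
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - XtViy @ beta
        if rss <= 0:
            return np.inf
        s2 = rss / (n - p)
        return (n - p) * np.log(s2) + logdetV0 + logdetXVX + (n - p)

    grid = np.linspace(-14, 10, 49)
    vals = [profiled(g) for g in grid]
    i0 = int(np.nanargmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    opt = optimize.minimize_scalar(profiled, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(opt.x))

    XtViX, XtViy, ytViy, _ = res._gls_pieces(1.0, lam)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - XtViy @ beta
    sigma2 = float(rss / (n - p))
    tau2 = float(lam * sigma2)
    singular = lam < 1e-5
    if singular:
        tau2 = 0.0
        warnings.warn(
            "random-intercept variance estimated at the boundary (singular fit); "
            "the model reduces to OLS",
            SingularFitWarning,
            stacklevel=2,
        )
    res.beta = beta
    res.sigma2 = sigma2
    res.tau2 = tau2
    res.cov_beta = res._cov_beta_at(sigma2, tau2)
    res.loglik_reml = -0.5 * res.neg2_reml(sigma2, max(tau2, 1e-300 if singular else tau2))
    res.singular = singular
    return res


def build_factorial_design(
    data: pd.DataFrame,
    factors: list[str],
    interactions: bool = True,
    covariates: list[str] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Sum-coded (deviation) design matrix for categorical factors.

    Returns ``(X, column_names, term_columns)`` where ``term_columns`` maps
    each model term (including interactions and the intercept) to its column
    indices in X. Sum coding makes term-wise F tests orthogonal to lower-order
    terms under balance (classic factorial ANOVA semantics).
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    term_columns: dict[str, list[int]] = {"Intercept": [0]}
    main_blocks: dict[str, list[int]] = {}

    for fac in factors:
        levels = sorted(pd.unique(data[fac].astype(str)))
        block = []
        for lev in levels[:-1]:
            col = (data[fac].astype(str) == lev).astype(float).to_numpy()
            col = col - (data[fac].astype(str) == levels[-1]).astype(float).to_numpy()
            cols.append(col)
            names.append(f"{fac}[{lev}]")
            block.append(len(cols) - 1)
        term_columns[fac] = block
        main_blocks[fac] = block

    for cov in covariates or []:
        v = data[cov].to_numpy(dtype=float)
        cols.append(v)
        names.append(cov)
        term_columns[cov] = [len(cols) - 1]
        main_blocks[cov] = [len(cols) - 1]

    if interactions:
        for fa, fb in itertools.combinations(list(factors) + list(covariates or []), 2):
            block = []
            for ia in main_blocks[fa]:
                for ib in main_blocks[fb]:
                    cols.append(cols[ia] * cols[ib])
                    names.append(f"{names[ia]}:{names[ib]}")
                    block.append(len(cols) - 1)
            term_columns[f"{fa}:{fb}"] = block

    X = np.column_stack(cols)
    return X, names, term_columns


def anova_lmm(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    group: str,
    interactions: bool = True,
    covariates: list[str] | None = None,
) -> tuple[LMMResult, list[TermTest]]:
    """Fit a factorial random-intercept LMM and return term-wise F tests."""
    X, names, term_cols = build_factorial_design(
        data, factors, interactions=interactions, covariates=covariates
    )
    res = fit_random_intercept(
        data[response].to_numpy(dtype=float), X, data[group].to_numpy(), names
    )
    tests = []
    for term, idx in term_cols.items():
        if term == "Intercept" or not idx:
            continue
        L = np.zeros((len(idx), X.shape[1]))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        tests.append(res.term_ftest(L, term))
    return res, tests
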