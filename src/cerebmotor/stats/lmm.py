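"""Random-intercept linear mixed models with Satterthwaite F-tests.

Variance components are estimated by REML via ``statsmodels`` MixedLM; on
top of that this module computes, in closed form for the random-intercept
structure ``V = sigma_e^2 I + sigma_b^2 Z Z'``:

* GLS fixed effects and their covariance ``C = (X' V^-1 X)^-1``;
* per-term Wald F statistics with Satterthwaite denominator df, obtained by
  differentiating ``L C L'`` with respect to the variance components and
  weighting by the inverse observed information of the REML criterion (this
  reproduces the fractional denominator df reported by lmerTest);
* maximum-likelihood likelihood-ratio tests for iterative interaction
  pruning (highest-order terms first, one removal per pass, largest p
  first), with main effects never removed and a two-way term protected
  while a containing three-way term remains.

Singular random-intercept fits (boundary estimate sigma_b^2 ~ 0) fall back
to ordinary least squares with the residual df, and non-hierarchical
families skip the random term entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .design import ModelSpec, encode_design, term_columns

_SINGULAR_REL_TOL = 1e-6


class _RandomInterceptInference:
    """Closed-form REML quantities for a fitted random-intercept model."""

    def __init__(self, X: np.ndarray, y: np.ndarray, group_labels: np.ndarray):
        self.X, self.y = X, y
        _, idx = np.unique(group_labels, return_inverse=True)
        order = np.argsort(idx, kind="stable")
        self.X_s, self.y_s = X[order], y[order]
        counts = np.bincount(idx)
        self.bounds = np.concatenate(([0], np.cumsum(counts)))
        self.n, self.p = X.shape

    def _accumulate(self, s2b: float, s2e: float):
        p = self.p
        A = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        logdet = 0.0
        for g in range(len(self.bounds) - 1):
            i, j = self.bounds[g], self.bounds[g + 1]
            Xi, yi = self.X_s[i:j], self.y_s[i:j]
            ni = j - i
            c = s2b / (s2e + ni * s2b)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            A += (Xi.T @ Xi - c * np.outer(sx, sx)) / s2e
            Xty += (Xi.T @ yi - c * sx * sy) / s2e
            yty += (yi @ yi - c * sy * sy) / s2e
            logdet += (ni - 1) * np.log(s2e) + np.log(s2e + ni * s2b)
        return A, Xty, yty, logdet

    def beta_cov(self, s2b: float, s2e: float):
        A, Xty, _, _ = self._accumulate(s2b, s2e)
        C = np.linalg.inv(A)
        return C @ Xty, C

    def reml_nll(self, theta: np.ndarray) -> float:
        s2b, s2e = float(theta[0]), float(theta[1])
        if s2e <= 0 or s2b < 0:
            return np.inf
        A, Xty, yty, logdet = self._accumulate(s2b, s2e)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, Xty)
        rss = yty - beta @ Xty
        return 0.5 * (logdet + logdetA + rss)

    def theta_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Asymptotic Var(theta_hat): inverse Hessian of the REML criterion."""
        h = 1e-4 * (np.abs(theta) + 1e-3 * theta[1])
        H = np.zeros((2, 2))
        f0 = self.reml_nll(theta)
        for a in range(2):
            for b in range(a, 2):
                ea = np.zeros(2)
                eb = np.zeros(2)
                ea[a], eb[b] = h[a], h[b]
                if a == b:
                    H[a, a] = (
                        self.reml_nll(theta + ea) - 2 * f0 + self.reml_nll(theta - ea)
                    ) / h[a] ** 2
                else:
                    H[a, b] = H[b, a] = (
                        self.reml_nll(theta + ea + eb)
                        - self.reml_nll(theta + ea - eb)
                        - self.reml_nll(theta - ea + eb)
                        + self.reml_nll(theta - ea - eb)
                    ) / (4 * h[a] * h[b])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)

    def satterthwaite_df(self, L: np.ndarray, theta: np.ndarray, theta_cov: np.ndarray) -> float:
        """Denominator df for a 1-row contrast L (Satterthwaite)."""
        s2b, s2e = theta

        def f(th):
            _, C = self.beta_cov(max(th[0], 0.0), th[1])
            return float(L @ C @ L)

        h = 1e-4 * (np.abs(theta) + 1e-3 * s2e)
        g = np.zeros(2)
        for a in range(2):
            e = np.zeros(2)
            e[a] = h[a]
            g[a] = (f(theta + e) - f(theta - e)) / (2 * h[a])
        denom = float(g @ theta_cov @ g)
        fval = f(theta)
        if denom <= 0:
            return float(self.n - self.p)
        return 2.0 * fval**2 / denom


@dataclass
class FittedModel:
    spec: ModelSpec
    method: str  # "lmm" or "ols"
    params: pd.Series  # fixed effects incl. intercept
    cov: pd.DataFrame  # fixed-effect covariance
    terms: pd.DataFrame  # term, beta, se, F, df_num, df_den, p
    sigma2_b: float
    sigma2_e: float
    loglike: float  # REML (lmm) or ML (ols) log-likelihood of the final fit
    converged: bool
    n_obs: int
    n_groups: int
    pruning_trace: list = field(default_factory=list)
    _inference: _RandomInterceptInference | None = None

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """(estimate, SE, denominator df) for a fixed-effect contrast."""
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov.to_numpy() @ c))
        if self.method == "lmm" and self._inference is not None:
            theta = np.array([self.sigma2_b, self.sigma2_e])
            df = self._inference.satterthwaite_df(
                c, theta, self._inference.theta_covariance(theta)
            )
        else:
            df = float(self.n_obs - len(self.params))
        return est, se, df


def _design(spec: ModelSpec, data: pd.DataFrame):
    enc = encode_design(data)
    y = enc[spec.outcome].to_numpy(dtype=float)
    names = ["Intercept"] + list(spec.fixed_terms)
    cols = [np.ones(len(enc))] + [term_columns(t, enc) for t in spec.fixed_terms]
    X = np.column_stack(cols)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    groups = enc[spec.group_col].to_numpy()
    return X[mask], y[mask], groups[mask], names


def _fit_variance_components(X, y, groups, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=reml, method="lbfgs")
            if not res.converged:
                raise RuntimeError
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=2000)
    s2e = float(res.scale)
    s2b = float(np.atleast_2d(res.cov_re)[0, 0])
    return s2b, s2e, bool(res.converged), float(res.llf)


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """REML fit with per-term F tests (Satterthwaite denominator df)."""
    X, y, groups, names = _design(spec, data)
    use_lmm = spec.random_intercept and len(np.unique(groups)) < len(y)
    if use_lmm:
        s2b, s2e, converged, llf = _fit_variance_components(X, y, groups, reml=True)
        if s2b <= _SINGULAR_REL_TOL * np.var(y):
            use_lmm = False

    if use_lmm:
        inf = _RandomInterceptInference(X, y, groups)
        beta, C = inf.beta_cov(s2b, s2e)
        theta = np.array([s2b, s2e])
        theta_cov = inf.theta_covariance(theta)
        rows = []
        for k, name in enumerate(names):
            if name == "Intercept":
                continue
            L = np.zeros(len(names))
            L[k] = 1.0
            se = float(np.sqrt(C[k, k]))
            F = (beta[k] / se) ** 2
            df_den = inf.satterthwaite_df(L, theta, theta_cov)
            rows.append(
                {
                    "term": name,
                    "beta": beta[k],
                    "se": se,
                    "F": F,
                    "df_num": 1.0,
                    "df_den": df_den,
                    "p": float(sps.f.sf(F, 1, df_den)),
                }
            )
        return FittedModel(
            spec=spec,
            method="lmm",
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(C, index=names, columns=names),
            terms=pd.DataFrame(rows),
            sigma2_b=s2b,
            sigma2_e=s2e,
            loglike=llf,
            converged=converged,
            n_obs=len(y),
            n_groups=len(np.unique(groups)),
            _inference=inf,
        )

    # OLS path: non-hierarchical family or singular random intercept
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    df_den = float(res.df_resid)
    rows = []
    for k, name in enumerate(names):
        if name == "Intercept":
            continue
        F = float(res.tvalues[k] ** 2)
        rows.append(
            {
                "term": name,
                "beta": float(res.params[k]),
                "se": float(res.bse[k]),
                "F": F,
                "df_num": 1.0,
                "df_den": df_den,
                "p": float(sps.f.sf(F, 1, df_den)),
            }
        )
    return FittedModel(
        spec=spec,
        method="ols",
        params=pd.Series(res.params, index=names),
        cov=pd.DataFrame(res.cov_params(), index=names, columns=names),
        terms=pd.DataFrame(rows),
        sigma2_b=0.0,
        sigma2_e=float(res.scale),
        loglike=float(res.llf),
        converged=True,
        n_obs=len(y),
        n_groups=len(np.unique(groups)),
    )


def _ml_loglike(spec: ModelSpec, data: pd.DataFrame) -> float:
    X, y, groups, _ = _design(spec, data)
    if spec.random_intercept and len(np.unique(groups)) < len(y):
        _, _, _, llf = _fit_variance_components(X, y, groups, reml=False)
        return llf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sm.OLS(y, X).fit().llf)


def _order(term: str) -> int:
    return term.count(":") + 1


def _removable(spec: ModelSpec) -> list[str]:
    """Interactions not contained in a higher-order interaction still present."""
    out = []
    for t in spec.interactions:
        parts = set(t.split(":"))
        contained = any(
            o != t and parts < set(o.split(":")) for o in spec.interactions
        )
        if not contained:
            out.append(t)
    # highest order first
    return sorted(out, key=_order, reverse=True)


def prune_interactions(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> FittedModel:
    """Iteratively drop interactions that do not improve fit (ML LRT).

    At each pass the removable terms of the highest remaining order are
    tested by a 1-df maximum-likelihood likelihood-ratio test against the
    model without them; the term with the largest non-significant p
    (p >= alpha) is removed and the process repeats.  The final model is
    refit by REML.  The removal trace (term, chi2, p) is attached.
    """
    current = spec
    trace: list[dict] = []
    while True:
        candidates = _removable(current)
        if not candidates:
            break
        ll_full = _ml_loglike(current, data)
        removed = False
        for order in sorted({_order(t) for t in candidates}, reverse=True):
            tested = []
            for term in (t for t in candidates if _order(t) == order):
                ll_red = _ml_loglike(current.drop(term), data)
                chi2 = max(0.0, 2.0 * (ll_full - ll_red))
                tested.append((term, chi2, float(sps.chi2.sf(chi2, 1))))
            tested.sort(key=lambda r: r[2], reverse=True)
            term, chi2, p = tested[0]
            if p >= alpha:
                current = current.drop(term)
                trace.append({"term": term, "chi2": chi2, "p": p})
                removed = True
                break
        if not removed:
            break
    fitted = fit_model(current, data)
    fitted.pruning_trace = trace
    return fitted
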