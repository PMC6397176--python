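"""Count regression of call concordance on the six factor covariates.

The response is CC, the number of pipelines that called a variant, modelled
as an unbounded count with a log link:

    log E[CC] = beta_0 + X beta

where X dummy-codes the six factors against fixed reference levels
(common MAF, modifier impact, non-repetitive, unbiased GC, normal coverage,
good MAPQ).  Two families are supported — Poisson, and negative binomial
(NB2, variance mu + mu^2/theta) with the dispersion theta estimated by
maximum likelihood — and a boundary-corrected likelihood-ratio test
compares them.  CC has a ceiling at the number of pipelines; the count
model ignores the ceiling, which is accepted as mild misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .factors import FACTOR_LEVELS, FACTORS, REFERENCE_LEVELS

WALD_ALPHA = 0.001  # significance flag threshold for effect tables


def build_design(profiles: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the six factors; one 0/1 column per non-reference level.

    Column names are ``factor[level]``.  A profile at all reference levels
    maps to an all-zero row (intercept only).  Unknown levels raise.
    """
    cols: dict[str, np.ndarray] = {}
    for f in FACTORS:
        values = pd.Categorical(profiles[f], categories=FACTOR_LEVELS[f])
        if values.isna().any():
            bad = sorted(set(profiles[f].astype(str)) - set(FACTOR_LEVELS[f]))
            raise ValueError(f"unseen level(s) {bad} for factor {f!r}")
        for level in FACTOR_LEVELS[f]:
            if level == REFERENCE_LEVELS[f]:
                continue
            cols[f"{f}[{level}]"] = (np.asarray(values) == level).astype(float)
    return pd.DataFrame(cols, index=profiles.index)


class NonConvergenceError(RuntimeError):
    pass


def _nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    from scipy.special import gammaln

    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    theta: float | None = None,
    start: np.ndarray | None = None,
    maxiter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Iteratively reweighted least squares for a log-link count GLM.

    ``theta=None`` gives Poisson weights mu; otherwise NB2 weights
    mu / (1 + mu/theta).  Returns (beta, covariance, mu, converged);
    the covariance is (X' W X)^-1 at the solution.
    """
    n, p = X.shape
    beta = (
        start.copy()
        if start is not None
        else np.r_[np.log(max(y.mean(), 1e-8)), np.zeros(p - 1)]
    )
    eta = X @ beta
    mu = np.exp(eta)
    H = None
    converged = False
    for _ in range(maxiter):
        W = mu if theta is None else mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        H = X.T @ WX
        beta_new = np.linalg.solve(H, WX.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        if step < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    return beta, np.linalg.inv(H), mu, converged


THETA_CAP = 1e8  # dispersion this large is operationally Poisson


def _profile_theta(y: np.ndarray, mu: np.ndarray, theta0: float) -> float:
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lt: -_nb2_loglik(y, mu, float(np.exp(lt))),
        bounds=(np.log(1e-4), np.log(THETA_CAP)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


@dataclass
class ConcordanceGLMResults:
    """Fitted coefficients, their uncertainty, and likelihood diagnostics."""

    family: str
    params: pd.Series  # log-scale coefficients incl. "const"
    bse: pd.Series
    llf: float
    theta: float | None  # NB dispersion; None for Poisson
    theta_se: float | None
    nobs: int
    converged: bool

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def wald_pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def effect_table(self, alpha: float = WALD_ALPHA) -> pd.DataFrame:
        """Rate ratios exp(beta) with 95 % Wald CIs and significance flags.

        One row per non-reference factor level; reference levels have rate
        ratio 1 by construction and are omitted.
        """
        ci = self.conf_int()
        p = self.wald_pvalues()
        rows = []
        for name in self.params.index:
            if name == "const":
                continue
            factor, level = name.split("[", 1)
            rows.append(
                {
                    "factor": factor,
                    "level": level.rstrip("]"),
                    "rate_ratio": float(np.exp(self.params[name])),
                    "ci_lower": float(np.exp(ci.loc[name, "lower"])),
                    "ci_upper": float(np.exp(ci.loc[name, "upper"])),
                    "wald_p": float(p[name]),
                    "significant": bool(p[name] < alpha),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Call-concordance GLM ({self.family}), n = {self.nobs}",
            f"log-likelihood = {self.llf:.3f}"
            + (f", theta = {self.theta:.4f}" if self.theta is not None else ""),
            f"{'term':<28}{'coef':>10}{'se':>10}{'RR':>10}{'p':>12}",
        ]
        p = self.wald_pvalues()
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{np.exp(self.params[name]):>10.4f}{p[name]:>12.3g}"
            )
        return "\n".join(lines)


class ConcordanceGLM:
    """Log-link count model of CC given a design matrix.

    Parameters
    ----------
    cc : array of positive integer counts (one per variant).
    design : DataFrame from :func:`build_design` (no intercept column; one
        is added internally).
    family : "poisson" or "negbin".
    """

    def __init__(self, cc, design: pd.DataFrame, family: str = "negbin"):
        cc = np.asarray(cc)
        if cc.ndim != 1 or len(cc) != len(design):
            raise ValueError("cc and design must align")
        if (cc < 1).any():
            raise ValueError("CC counts must be >= 1")
        self.cc = cc.astype(float)
        self.design = design
        if family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family

    @classmethod
    def from_profiles(cls, cc, profiles: pd.DataFrame, family: str = "negbin"):
        return cls(cc, build_design(profiles), family=family)

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> ConcordanceGLMResults:
        """Maximum-likelihood fit.

        The negative-binomial dispersion is estimated by alternating IRLS
        for the coefficients (GLM with theta held fixed) with 1-D profile
        maximization of the NB2 log-likelihood over log(theta), iterated to
        a relative theta change below ``tol`` (at most ``maxiter`` outer
        rounds) — the same scheme R's glm.nb uses.
        """
        exog = sm.add_constant(self.design.to_numpy(), prepend=True)
        names = ["const"] + list(self.design.columns)
        # levels absent from the sample give all-zero columns; drop them
        # from the fit and report NaN coefficients (R's NA convention)
        keep = np.asarray(exog.std(axis=0) > 0)
        keep[0] = True
        dropped = [n for n, k in zip(names, keep) if not k]
        if dropped:
            import warnings

            warnings.warn(
                f"levels absent from the data dropped from the fit: {dropped}",
                stacklevel=2,
            )
        exog = exog[:, keep]
        names_fit = [n for n, k in zip(names, keep) if k]
        y = self.cc
        params, cov, mu, ok = _irls(y, exog)
        if not ok:
            raise NonConvergenceError("Poisson IRLS did not converge")
        if self.family == "poisson":
            return ConcordanceGLMResults(
                family="poisson",
                params=pd.Series(params, index=names_fit).reindex(names),
                bse=pd.Series(np.sqrt(np.diag(cov)), index=names_fit).reindex(names),
                llf=_poisson_loglik(y, mu),
                theta=None,
                theta_se=None,
                nobs=len(y),
                converged=True,
            )
        # moment start for theta (method-of-moments on Pearson residuals)
        excess = float(np.mean(((y - mu) ** 2 - mu) / mu**2))
        theta = 1.0 / max(excess, 1e-4)
        converged = False
        ll_prev = -np.inf
        for _ in range(maxiter):
            params, cov, mu, ok = _irls(y, exog, theta=theta, start=params)
            if not ok:
                raise NonConvergenceError("negbin IRLS did not converge")
            theta = _profile_theta(y, mu, theta)
            ll = _nb2_loglik(y, mu, theta)
            if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
                converged = True
                break
            ll_prev = ll
        if not converged:
            raise NonConvergenceError(
                f"negbin theta loop did not converge in {maxiter} iterations "
                f"(last theta = {theta:.4g})"
            )
        params, cov, mu, _ = _irls(y, exog, theta=theta, start=params)
        llf = _nb2_loglik(y, mu, theta)
        # curvature of the log-likelihood in log(theta) at the optimum
        h = 1e-4
        d2 = (
            _nb2_loglik(y, mu, theta * np.exp(h))
            - 2 * llf
            + _nb2_loglik(y, mu, theta * np.exp(-h))
        ) / h**2
        theta_se = theta / np.sqrt(-d2) if d2 < 0 else float("inf")
        return ConcordanceGLMResults(
            family="negbin",
            params=pd.Series(params, index=names_fit).reindex(names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names_fit).reindex(names),
            llf=float(llf),
            theta=float(theta),
            theta_se=float(theta_se),
            nobs=len(y),
            converged=True,
        )


def likelihood_ratio_poisson_vs_negbin(
    fit_p: ConcordanceGLMResults, fit_nb: ConcordanceGLMResults
) -> tuple[float, float]:
    """Boundary-corrected LRT of Poisson against negative binomial.

    Poisson is the theta -> infinity boundary of NB2, so the null
    distribution of 2 (llf_nb - llf_p) is the 50:50 mixture of a point mass
    at zero and chi-square(1); p = 0.5 * P(chi2_1 > stat) for stat > 0.
    """
    if fit_p.family != "poisson" or fit_nb.family != "negbin":
        raise ValueError("pass (poisson fit, negbin fit)")
    if fit_p.nobs != fit_nb.nobs or len(fit_p.params) != len(fit_nb.params):
        raise ValueError("fits must share the same design and response")
    stat = 2.0 * (fit_nb.llf - fit_p.llf)
    stat = max(stat, 0.0)  # clip tiny negative values from convergence slack
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p
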