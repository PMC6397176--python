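"""Pipeline ensembles: concordance-threshold and mixture-model filtering.

Two ways to distil a consensus call set out of many pipelines:

1. **Concordance filter** — keep a variant iff at least ``cutoff`` pipelines
   called it; sweeping the cutoff traces a performance curve.

2. **Mixture filter** — a two-component mixture over call concordance (CC)
   and the six factor covariates.  One component captures true variants
   (high CC), the other calling errors.  Within a component the variables
   are independent; CC gets a Gaussian density and each categorical factor
   its own probability table:

       p(cc, f_1..f_k) = sum_i  pi_i  N(cc; mu_i, sigma_i^2)  prod_j  p_i(f_j)

   Parameters are learned by EM with the component variance of CC floored
   (default 1.0) so that a component cannot collapse onto a single CC
   value, and with additive smoothing of the categorical tables.  The
   posterior probability of the true-variant component ranks variants for
   filtering.

Variables enter the mixture only if a logistic regression of gold-standard
membership on all variables finds them associated (Wald p < 0.005), which
in practice drops IMPACT for indels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logsumexp

from .factors import FACTOR_LEVELS, FACTORS, REFERENCE_LEVELS

logger = logging.getLogger(__name__)

SELECTION_ALPHA = 0.005
WEIGHT_COLLAPSE = 1e-6


def concordance_filter(cc: np.ndarray, cutoff: int) -> np.ndarray:
    """Boolean keep mask: cc >= cutoff."""
    return np.asarray(cc) >= cutoff


def posterior_filter(scores: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean keep mask: posterior score >= cutoff."""
    return np.asarray(scores) >= cutoff


# ---------------------------------------------------------------------------
# Variable selection


class SeparationFallbackWarning(UserWarning):
    pass


def _selection_design(
    features: pd.DataFrame, variables: list[str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    cols: list[np.ndarray] = []
    terms: list[tuple[str, str]] = []  # (variable, term label)
    for var in variables:
        if var == "cc":
            cols.append(np.asarray(features["cc"], dtype=float))
            terms.append(("cc", "cc"))
        else:
            vals = pd.Categorical(features[var], categories=FACTOR_LEVELS[var])
            for level in FACTOR_LEVELS[var]:
                if level == REFERENCE_LEVELS[var]:
                    continue
                col = (np.asarray(vals) == level).astype(float)
                if col.any():  # drop empty levels from the selection fit
                    cols.append(col)
                    terms.append((var, f"{var}[{level}]"))
    return np.column_stack(cols), terms


def select_variables(
    features: pd.DataFrame,
    gold_labels: np.ndarray,
    candidates: list[str] | None = None,
    alpha: float = SELECTION_ALPHA,
) -> list[str]:
    """Variables associated with gold-standard membership.

    Fits one logistic regression of the label on CC plus the dummy-coded
    factors and keeps a variable iff any of its terms has Wald p < alpha.
    CC is always retained.  Perfect separation falls back to an L2-penalized
    fit with Wald statistics from the penalized information matrix.
    """
    y = np.asarray(gold_labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("gold labels must contain both classes")
    if candidates is None:
        candidates = ["cc"] + [f for f in FACTORS if f in features.columns]
    X, terms = _selection_design(features, candidates)
    exog = sm.add_constant(X, prepend=True)
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    pvals = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False):
            pvals = res.pvalues[1:]
    except Exception:  # separation / non-convergence
        pvals = None
    if pvals is None:
        warnings.warn(
            "logistic selection fit failed to converge; using an L2-penalized "
            "fit for Wald statistics",
            SeparationFallbackWarning,
            stacklevel=2,
        )
        pvals = _penalized_wald_pvalues(y, exog)[1:]
    selected = {"cc"}
    for (var, _), p in zip(terms, pvals):
        if p < alpha:
            selected.add(var)
    return [v for v in candidates if v in selected]


def _penalized_wald_pvalues(y: np.ndarray, exog: np.ndarray) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    lam = 1.0
    lr = LogisticRegression(C=1.0 / lam, fit_intercept=False, max_iter=1000)
    lr.fit(exog, y)
    beta = lr.coef_.ravel()
    mu = 1.0 / (1.0 + np.exp(-exog @ beta))
    W = mu * (1 - mu)
    info = exog.T @ (exog * W[:, None]) + lam * np.eye(exog.shape[1])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return 2 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# Mixture model


@dataclass
class MixtureResults:
    """Fitted two-component mixture over CC and categorical factors."""

    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2,) Gaussian means of CC
    variances: np.ndarray  # (2,) clamped at the floor
    tables: dict[str, np.ndarray]  # factor -> (2, n_levels), rows sum to 1
    included: list[str]
    true_component: int  # index in {0, 1}
    variance_floor: float
    smoothing: float
    loglik_path: list[float] = field(default_factory=list)
    penalized_path: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    nobs: int = 0

    @property
    def llf(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else float("nan")

    def _log_prior(self) -> float:
        """Dirichlet smoothing log-prior over the categorical tables.

        The categorical M-step is a MAP update under a symmetric
        Dirichlet(1 + smoothing) prior, and the variance clamp is a
        constrained M-step, so loglik + this prior — the penalized
        objective stored in ``penalized_path`` — is what EM ascends.
        """
        total = 0.0
        for f in self.included:
            if f == "cc":
                continue
            total += self.smoothing * float(np.log(self.tables[f]).sum())
        return total

    def _log_density(self, features: pd.DataFrame) -> np.ndarray:
        """(n, 2) per-component log pi_i + log p_i(x)."""
        cc = np.asarray(features["cc"], dtype=float)
        ll = np.empty((len(cc), 2))
        for i in range(2):
            ll[:, i] = np.log(self.weights[i]) + stats.norm.logpdf(
                cc, self.means[i], np.sqrt(self.variances[i])
            )
        for f in self.included:
            if f == "cc":
                continue
            codes = pd.Categorical(
                features[f], categories=FACTOR_LEVELS[f]
            ).codes
            if (codes < 0).any():
                raise ValueError(f"unknown level in factor {f!r}")
            for i in range(2):
                ll[:, i] += np.log(self.tables[f][i][codes])
        return ll

    def posterior(self, features: pd.DataFrame) -> np.ndarray:
        """Per-variant probability of the true-variant component."""
        ll = self._log_density(features)
        return np.exp(
            ll[:, self.true_component] - logsumexp(ll, axis=1)
        )

    def responsibilities(self, features: pd.DataFrame) -> np.ndarray:
        ll = self._log_density(features)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))

    def loglikelihood(self, features: pd.DataFrame) -> float:
        return float(logsumexp(self._log_density(features), axis=1).sum())

    def summary(self) -> str:
        t = self.true_component
        lines = [
            f"Two-component CC mixture, n = {self.nobs}, "
            f"{self.n_iter} EM iterations"
            + ("" if self.converged else " (NOT converged)")
            + (" [degenerate]" if self.degenerate else ""),
            f"included variables: {', '.join(self.included)}",
            f"true component: {t + 1}",
        ]
        for i in range(2):
            tag = "true " if i == t else "error"
            lines.append(
                f"  comp {i + 1} ({tag}): pi = {self.weights[i]:.4f}, "
                f"CC ~ N({self.means[i]:.3f}, {self.variances[i]:.3f})"
            )
        for f in self.included:
            if f == "cc":
                continue
            for i in range(2):
                cells = ", ".join(
                    f"{lvl}={p:.3f}"
                    for lvl, p in zip(FACTOR_LEVELS[f], self.tables[f][i])
                )
                lines.append(f"  {f} | comp {i + 1}: {cells}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "tables": {f: t.tolist() for f, t in self.tables.items()},
                "included": self.included,
                "true_component": self.true_component,
                "variance_floor": self.variance_floor,
                "smoothing": self.smoothing,
                "loglik_path": self.loglik_path,
                "penalized_path": self.penalized_path,
                "converged": self.converged,
                "degenerate": self.degenerate,
                "n_iter": self.n_iter,
                "nobs": self.nobs,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureResults":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            tables={f: np.asarray(t) for f, t in d["tables"].items()},
            included=d["included"],
            true_component=d["true_component"],
            variance_floor=d["variance_floor"],
            smoothing=d["smoothing"],
            loglik_path=d["loglik_path"],
            penalized_path=d.get("penalized_path", []),
            converged=d["converged"],
            degenerate=d["degenerate"],
            n_iter=d["n_iter"],
            nobs=d["nobs"],
        )


class DegenerateFitError(RuntimeError):
    pass


class CallConcordanceMixture:
    """EM estimator for the two-component CC + factors mixture.

    Parameters
    ----------
    features : DataFrame with a numeric ``cc`` column and categorical factor
        columns.
    included : variables to model; defaults to ``cc`` plus every factor
        column present (use :func:`select_variables` to choose them from a
        gold standard).
    variance_floor : lower bound on the CC component variance (the EM is
        penalized so sigma^2 never drops below it; default 1.0).
    smoothing : additive pseudo-count per categorical cell (default 0.5).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        included: list[str] | None = None,
        variance_floor: float = 1.0,
        smoothing: float = 0.5,
    ):
        if "cc" not in features.columns:
            raise ValueError("features must contain a 'cc' column")
        if included is None:
            included = ["cc"] + [f for f in FACTORS if f in features.columns]
        if "cc" not in included:
            included = ["cc"] + list(included)
        self.features = features
        self.included = list(included)
        self.variance_floor = float(variance_floor)
        self.smoothing = float(smoothing)
        self._cc = np.asarray(features["cc"], dtype=float)
        self._codes = {
            f: pd.Categorical(features[f], categories=FACTOR_LEVELS[f]).codes
            for f in self.included
            if f != "cc"
        }
        for f, codes in self._codes.items():
            if (codes < 0).any():
                raise ValueError(f"unknown level in factor {f!r}")

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 500,
        raise_on_collapse: bool = False,
    ) -> MixtureResults:
        """Run EM to convergence of the relative log-likelihood change.

        The initial responsibility of the first component is cc / max(cc),
        putting high-concordance variants into component 1, so component
        labels are stable without random restarts.
        """
        cc = self._cc
        n = len(cc)
        if n == 0:
            raise ValueError("no variants to fit")
        if np.unique(cc).size < 2:
            logger.warning("constant CC input: mixture fit is degenerate")
        r1 = cc / cc.max()
        resp = np.column_stack([r1, 1.0 - r1])

        weights = np.empty(2)
        means = np.empty(2)
        variances = np.empty(2)
        tables: dict[str, np.ndarray] = {}
        loglik_path: list[float] = []
        penalized_path: list[float] = []
        degenerate = False
        converged = False
        it = 0

        for it in range(1, max_iter + 1):
            # M-step
            nk = resp.sum(axis=0)
            if nk.min() / n < WEIGHT_COLLAPSE:
                degenerate = True
                if raise_on_collapse:
                    raise DegenerateFitError(
                        f"component weight collapsed to {nk.min() / n:.2e}"
                    )
                nk = np.maximum(nk, WEIGHT_COLLAPSE * n)
            weights = nk / nk.sum()
            for i in range(2):
                w = resp[:, i]
                means[i] = (w * cc).sum() / nk[i]
                var = (w * (cc - means[i]) ** 2).sum() / nk[i]
                variances[i] = max(var, self.variance_floor)
            for f, codes in self._codes.items():
                k = len(FACTOR_LEVELS[f])
                tab = np.empty((2, k))
                for i in range(2):
                    counts = np.bincount(codes, weights=resp[:, i], minlength=k)
                    tab[i] = (counts + self.smoothing) / (
                        nk[i] + self.smoothing * k
                    )
                tables[f] = tab

            # E-step + observed-data log-likelihood under the penalized fit
            interim = MixtureResults(
                weights=weights.copy(),
                means=means.copy(),
                variances=variances.copy(),
                tables={f: t.copy() for f, t in tables.items()},
                included=self.included,
                true_component=0,
                variance_floor=self.variance_floor,
                smoothing=self.smoothing,
            )
            ll_mat = interim._log_density(self.features)
            ll = float(logsumexp(ll_mat, axis=1).sum())
            loglik_path.append(ll)
            penalized_path.append(ll + interim._log_prior())
            resp = np.exp(ll_mat - logsumexp(ll_mat, axis=1, keepdims=True))
            if len(penalized_path) >= 2:
                prev = penalized_path[-2]
                if abs(penalized_path[-1] - prev) <= tol * (abs(prev) + 1.0):
                    converged = True
                    break
        if not converged:
            logger.warning("EM reached max_iter=%d without converging", max_iter)

        hard = resp.argmax(axis=1)
        at_max = cc == cc.max()
        votes = [int(((hard == i) & at_max).sum()) for i in range(2)]
        true_component = int(np.argmax(votes))

        return MixtureResults(
            weights=weights,
            means=means,
            variances=variances,
            tables=tables,
            included=self.included,
            true_component=true_component,
            variance_floor=self.variance_floor,
            smoothing=self.smoothing,
            loglik_path=loglik_path,
            penalized_path=penalized_path,
            converged=converged,
            degenerate=degenerate,
            n_iter=it,
            nobs=n,
        )
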