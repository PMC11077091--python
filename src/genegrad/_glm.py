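"""Negative-binomial offset GLM fitting shared by the regression stages.

The NB2 dispersion parameter alpha (variance = mu + alpha*mu^2) is profiled:
we alternate a GLM fit at fixed alpha with a one-dimensional maximum-likelihood
update of alpha given the fitted means, which is fast and stable even when the
data are effectively Poisson (alpha on the boundary near 0).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

_ALPHA_MIN = 1e-8
_ALPHA_MAX = 1e3


def nb2_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; the alpha -> 0 limit is evaluated as Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-300, None)
    if alpha < _ALPHA_MIN:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1)
            + inv * np.log(inv / (inv + mu))
            + y * np.log(mu / (inv + mu))
        )
    )


def _mle_alpha(y: np.ndarray, mu: np.ndarray, lo=_ALPHA_MIN, hi=_ALPHA_MAX) -> float:
    res = minimize_scalar(
        lambda la: -nb2_loglik(y, mu, np.exp(la)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    alpha = float(np.exp(res.x))
    # prefer the Poisson boundary when it is at least as good
    if nb2_loglik(y, mu, 0.0) >= nb2_loglik(y, mu, alpha) - 1e-9:
        return 0.0
    return alpha


@dataclasses.dataclass
class GLMFit:
    """A fitted count GLM with log link and offset."""

    params: np.ndarray
    bse: np.ndarray
    llf: float
    alpha: float  # NB2 dispersion; 0 means Poisson
    converged: bool
    model: str  # "nb" or "poisson"
    fitted: np.ndarray
    cov: np.ndarray

    @property
    def theta(self) -> float:
        """NB size parameter (1/alpha); inf for Poisson."""
        return np.inf if self.alpha <= 0 else 1.0 / self.alpha

    def predict(self, X: np.ndarray, offset_log: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(X) @ self.params + np.asarray(offset_log))


def fit_count_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset_log: np.ndarray,
    model: str = "nb",
    max_outer: int = 25,
    alpha_tol: float = 1e-5,
) -> GLMFit:
    """Fit ``log mu = X @ beta + offset_log`` with Poisson or NB2 errors.

    For ``model="nb"`` the dispersion is estimated by profiled maximum
    likelihood; a fit that fails falls back to Poisson with ``model`` flagged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset_log = np.asarray(offset_log, dtype=float)

    def _glm(family) -> sm.GLM:
        return sm.GLM(y, X, family=family, offset=offset_log)

    poisson_res = _glm(sm.families.Poisson()).fit()
    if model == "poisson":
        return GLMFit(
            params=np.asarray(poisson_res.params),
            bse=np.asarray(poisson_res.bse),
            llf=nb2_loglik(y, poisson_res.fittedvalues, 0.0),
            alpha=0.0,
            converged=bool(poisson_res.converged),
            model="poisson",
            fitted=np.asarray(poisson_res.fittedvalues),
            cov=np.asarray(poisson_res.cov_params()),
        )
    if model != "nb":
        raise ValueError(f"unknown model {model!r}")

    try:
        mu = np.asarray(poisson_res.fittedvalues)
        alpha = _mle_alpha(y, mu)
        res = poisson_res
        for _ in range(max_outer):
            if alpha <= _ALPHA_MIN:
                break
            res = _glm(sm.families.NegativeBinomial(alpha=alpha)).fit(
                start_params=res.params
            )
            mu = np.asarray(res.fittedvalues)
            new_alpha = _mle_alpha(y, mu)
            if abs(np.log((new_alpha + _ALPHA_MIN) / (alpha + _ALPHA_MIN))) < alpha_tol:
                alpha = new_alpha
                break
            alpha = new_alpha
        if alpha > _ALPHA_MIN:
            res = _glm(sm.families.NegativeBinomial(alpha=alpha)).fit(
                start_params=res.params
            )
            mu = np.asarray(res.fittedvalues)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite coefficients")
        return GLMFit(
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            llf=nb2_loglik(y, mu, alpha),
            alpha=max(alpha, 0.0) if alpha > _ALPHA_MIN else 0.0,
            converged=bool(res.converged),
            model="nb",
            fitted=mu,
            cov=np.asarray(res.cov_params()),
        )
    except Exception:
        return GLMFit(
            params=np.asarray(poisson_res.params),
            bse=np.asarray(poisson_res.bse),
            llf=nb2_loglik(y, poisson_res.fittedvalues, 0.0),
            alpha=0.0,
            converged=False,
            model="poisson",
            fitted=np.asarray(poisson_res.fittedvalues),
            cov=np.asarray(poisson_res.cov_params()),
        )
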