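"""Sandwich variance estimators and Wald inference for the stratified fit.

Two asymptotic regimes are covered:

* **finite strata** — a handful of large strata (e.g. sex groups): each
  stratum's pairwise U-statistic is linearized by its Hoeffding projection,
  and the projections are combined across independent strata;
* **diverging strata** — many small strata (matched pairs at the extreme):
  each stratum's whole pair sum is treated as one independent summand and
  the Lindeberg-Feller CLT applies, so the middle ("meat") matrix is simply
  the sum of squared stratum scores.

Both produce Var(beta_hat) = B M B with B the inverse of the summed
Jacobian blocks; they differ only in M.  The meat M is also the variance
estimate of the estimating function itself, which the score-process
diagnostics use as their standardization constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .fit import SPWFit

logger = logging.getLogger(__name__)


class RegimeError(ValueError):
    """Raised when a variance regime's preconditions are not met."""


@dataclass
class InferenceResult:
    """Covariance, standard errors and Wald inference for one fit."""

    covariance: np.ndarray
    se: np.ndarray
    ci_beta: np.ndarray        # (p, 2)
    ci_win_ratio: np.ndarray   # (p, 2)
    wald_z: np.ndarray
    p_values: np.ndarray
    regime: str
    alpha: float
    covariate_names: list[str]
    score_covariance: np.ndarray | None = None  # meat: Var{U(tau; beta_hat)}
    beta: np.ndarray | None = None

    def summary_frame(self) -> pd.DataFrame:
        """Result table: covariate, win ratio, CI, p-value."""
        level = int(round(100 * (1 - self.alpha)))
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "log_win_ratio": self.beta,
                "se": self.se,
                "win_ratio": np.exp(self.beta),
                f"wr_ci{level}_lower": self.ci_win_ratio[:, 0],
                f"wr_ci{level}_upper": self.ci_win_ratio[:, 1],
                "p_value": self.p_values,
            }
        )

    def __str__(self) -> str:
        return self.summary_frame().to_string(index=False, float_format="%.4g")


def _bread(fit: SPWFit) -> np.ndarray:
    A = fit.jacobian  # sum of A_l, negative semi-definite
    return np.linalg.inv(A)


def _pair_residuals(sp, beta):
    mu = expit(sp.dz @ beta)
    return sp.w - mu


def finite_strata_meat(fit: SPWFit) -> np.ndarray:
    """Hoeffding-projection variance of the estimating function.

    4 * sum_l n_l^{-2} sum_i kappa_hat_l(O_li)^{x2}, where kappa_hat_l(O_li)
    averages (Z_li - Z_lj) h_l M_li,lj over the partners j of i.
    """
    p = len(fit.beta)
    meat = np.zeros((p, p))
    for sp in fit._pairs:
        if sp.n_l < 2:
            raise RegimeError(
                "finite-strata variance needs every stratum of size >= 2; "
                "use the diverging-strata estimator"
            )
        resid = _pair_residuals(sp, fit.beta)
        contrib = sp.dz * (sp.weight * resid)[:, None]  # (m, p)
        kappa = np.zeros((sp.n_l, p))
        np.add.at(kappa, sp.ii, contrib)
        np.add.at(kappa, sp.jj, contrib)  # (Z_j - Z_i) M_ji == (Z_i - Z_j) M_ij
        kappa /= sp.n_l - 1
        meat += (kappa.T @ kappa) / sp.n_l**2
    return 4.0 * meat


def diverging_strata_meat(fit: SPWFit) -> np.ndarray:
    """Sum of squared stratum scores (Lindeberg-Feller regime)."""
    p = len(fit.beta)
    meat = np.zeros((p, p))
    for sp in fit._pairs:
        resid = _pair_residuals(sp, fit.beta)
        g = sp.scale * (sp.dz.T @ resid)
        meat += np.outer(g, g)
    return meat


def _finish(fit, covariance, meat, regime, alpha) -> InferenceResult:
    covariance = 0.5 * (covariance + covariance.T)
    se = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
    z = norm.ppf(1 - alpha / 2)
    lo = fit.beta - z * se
    hi = fit.beta + z * se
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, fit.beta / se, np.nan)
    pvals = 2 * norm.sf(np.abs(wald))
    return InferenceResult(
        covariance=covariance,
        se=se,
        ci_beta=np.column_stack([lo, hi]),
        ci_win_ratio=np.exp(np.column_stack([lo, hi])),
        wald_z=wald,
        p_values=pvals,
        regime=regime,
        alpha=alpha,
        covariate_names=fit.covariate_names,
        score_covariance=meat,
        beta=fit.beta,
    )


def finite_strata_covariance(fit: SPWFit, alpha: float = 0.05) -> InferenceResult:
    """Sandwich variance for a small number of large strata.

    With a single stratum this reduces to the usual (unstratified)
    projection-based sandwich of the proportional win-fractions model.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    B = _bread(fit)
    meat = finite_strata_meat(fit)
    return _finish(fit, B @ meat @ B, meat, "finite", alpha)


def diverging_strata_covariance(fit: SPWFit, alpha: float = 0.05) -> InferenceResult:
    """Sandwich variance for many small strata (valid for matched pairs)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if len(fit._pairs) < 2:
        raise RegimeError(
            "diverging-strata variance needs at least two informative strata"
        )
    B = _bread(fit)
    meat = diverging_strata_meat(fit)
    cond = np.linalg.cond(meat)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "stratum-score covariance is numerically singular; using a "
            "pseudo-inverse-consistent sandwich",
            RuntimeWarning,
        )
    return _finish(fit, B @ meat @ B, meat, "diverging", alpha)


def choose_regime(fit_or_dataset, policy: str = "auto") -> str:
    """Pick a variance regime.

    ``auto`` selects ``diverging`` when the median stratum size is <= 5 or
    the number of strata exceeds sqrt(n); both regimes remain available by
    explicit request.
    """
    if policy in ("finite", "diverging"):
        return policy
    if policy != "auto":
        raise ValueError("policy must be 'auto', 'finite' or 'diverging'")
    if isinstance(fit_or_dataset, SPWFit):
        sizes = np.array(list(fit_or_dataset.n_per_stratum.values()))
        n = fit_or_dataset.dataset.n
    else:
        sizes = np.array([len(v) for v in fit_or_dataset.strata().values()])
        n = fit_or_dataset.n
    L = len(sizes)
    if np.median(sizes) <= 5 or L > np.sqrt(n):
        return "diverging"
    return "finite"


def wald_inference(fit: SPWFit, regime: str = "auto", alpha: float = 0.05) -> InferenceResult:
    """Convenience wrapper: choose a regime and build the full inference."""
    regime = choose_regime(fit, regime)
    if regime == "finite":
        return finite_strata_covariance(fit, alpha=alpha)
    return diverging_strata_covariance(fit, alpha=alpha)
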