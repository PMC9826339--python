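"""Score-process diagnostics for the proportionality assumption.

The model assumes covariate-specific win ratios that are constant over
follow-up time.  Under that assumption the pairwise residual process has
conditional mean zero at every horizon t, so the partial score

    U(t; beta_hat) = sum_l h_l / C(n_l, 2) sum_{i<j} (Z_li - Z_lj) M_li,lj(t)

(with h_l = n_l / n) fluctuates around zero, vanishes exactly at the
analysis horizon tau (it is the estimating function there), and — once
standardized by the square root of the corresponding diagonal of
Var{U(tau; beta_hat)} — behaves like a time-rescaled Brownian bridge.
A standardized component wandering outside [-2, 2] flags a covariate whose
win ratio drifts over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .fit import SPWFit
from .variance import diverging_strata_meat, finite_strata_meat, choose_regime
from .wins import pair_histories


@dataclass
class ScoreProcess:
    """U(t; beta_hat) on a time grid, optionally standardized."""

    grid: np.ndarray            # ordered times in [0, tau]
    raw: np.ndarray             # (p, len(grid))
    covariate_names: list[str]
    standardized: np.ndarray | None = None
    flag: np.ndarray | None = None  # per covariate: sup |std| > 2
    assessable: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long plot-data table: covariate, t, raw (and standardized) value."""
        frames = []
        vals = self.standardized if self.standardized is not None else self.raw
        for k, name in enumerate(self.covariate_names):
            frames.append(
                pd.DataFrame(
                    {"covariate": name, "t": self.grid, "value": vals[k]}
                )
            )
        return pd.concat(frames, ignore_index=True)


def score_process(fit: SPWFit, grid=None) -> ScoreProcess:
    """Evaluate the score process at beta_hat on a time grid.

    The default grid is the set of distinct pair-status jump times (plus 0
    and tau), on which the process is exact; between jump times it is
    piecewise constant.  Pass an array to evaluate on a custom grid instead
    (e.g. a uniform grid for plotting).
    """
    beta = fit.beta
    p = len(beta)
    tau = fit.tau
    # accumulate step increments: at each pair-status change the pair's
    # contribution dz * (delta_ij(t) - mu) changes by a known amount
    times = []
    increments = []
    for sp in fit._pairs:
        ii, jj, changes = pair_histories(fit.dataset, sp.idx, fit.rule, tau)
        if len(ii) == 0:
            continue
        dz = fit.dataset.Z[sp.idx[ii]] - fit.dataset.Z[sp.idx[jj]]
        mu = expit(dz @ beta)
        for k, seg in enumerate(changes):
            prev = None
            for (t, dij) in seg:
                new = dij - mu[k]
                delta = new - (prev if prev is not None else 0.0)
                times.append(t)
                increments.append(sp.scale * dz[k] * delta)
                prev = new
    if times:
        times = np.asarray(times)
        increments = np.asarray(increments)  # (m, p)
        order = np.argsort(times, kind="stable")
        times = times[order]
        increments = increments[order]
        jump_t, starts = np.unique(times, return_index=True)
        cum = np.cumsum(increments, axis=0)
        ends = np.append(starts[1:], len(times)) - 1
        u_at_jumps = cum[ends]  # value for t > jump_t[k]
    else:
        jump_t = np.empty(0)
        u_at_jumps = np.empty((0, p))

    if grid is None:
        grid = np.unique(np.concatenate([[0.0], jump_t, [tau]]))
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty evaluation grid")
        grid = np.sort(grid)
    # status at exactly a jump time is the post-jump value (cadlag convention)
    pos = np.searchsorted(jump_t, grid, side="right") - 1
    raw = np.zeros((p, len(grid)))
    if len(jump_t):
        valid = pos >= 0
        raw[:, valid] = u_at_jumps[pos[valid]].T
    return ScoreProcess(grid=grid, raw=raw, covariate_names=fit.covariate_names)


def standardize(sp: ScoreProcess, score_covariance: np.ndarray) -> ScoreProcess:
    """Standardize each component by sqrt of the meat's diagonal.

    ``score_covariance`` is Var{U(tau; beta_hat)}, the middle matrix of the
    sandwich variance (``InferenceResult.score_covariance``).  Components
    with a zero normalizer are flagged non-assessable.
    """
    diag = np.clip(np.diag(np.asarray(score_covariance, dtype=float)), 0.0, None)
    assessable = diag > 0
    denom = np.where(assessable, np.sqrt(np.where(assessable, diag, 1.0)), np.nan)
    std = sp.raw / denom[:, None]
    flag = np.zeros(len(sp.covariate_names), dtype=bool)
    for k in range(len(flag)):
        if assessable[k]:
            flag[k] = np.nanmax(np.abs(std[k])) > 2.0
    return ScoreProcess(
        grid=sp.grid,
        raw=sp.raw,
        covariate_names=sp.covariate_names,
        standardized=std,
        flag=flag,
        assessable=assessable,
    )


def proportionality_check(fit: SPWFit, regime: str = "auto", grid=None) -> ScoreProcess:
    """Score process standardized with the regime-matched variance meat."""
    regime = choose_regime(fit, regime)
    meat = finite_strata_meat(fit) if regime == "finite" else diverging_strata_meat(fit)
    return standardize(score_process(fit, grid=grid), meat)
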