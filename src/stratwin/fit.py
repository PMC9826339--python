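"""Stratified win-fractions regression: the estimating equation and its solver.

Model: within each stratum l, the covariate-specific win ratio for subjects
i, j is exp(beta' (Z_li - Z_lj)), shared across strata.  Equivalently the
conditional win fraction given determinacy is the logistic link

    mu(Z_li, Z_lj; beta) = expit(beta' (Z_li - Z_lj)).

The score sums, over within-stratum pairs, (Z_li - Z_lj) times the pair
residual delta_ij - R_ij * mu, where delta_ij is the observed win indicator
at the analysis horizon and R_ij = delta_ij + delta_ji flags determinacy.
Each stratum's pair sum is averaged over its C(n_l, 2) pairs and weighted by
h_l = n_l / n (the Mantel-Haenszel-style size weight).  With this
time-constant weight the time integral of the residual process collapses to
the end-of-follow-up pair statuses, which is what the fitter uses.

Indeterminate pairs (neither subject's win decidable by the censored pair
horizon) contribute exactly zero and are dropped up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.special import expit

from .data import Dataset
from .wins import pair_table

logger = logging.getLogger(__name__)


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the pair-difference design is (numerically) collinear."""


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails; carries the last iterate."""

    def __init__(self, message, beta, score):
        super().__init__(message)
        self.beta = beta
        self.score = score


@dataclass
class _StratumPairs:
    """Determinate pairs of one stratum, cached for variance/diagnostics."""

    label: object
    idx: np.ndarray        # subject indices into the dataset
    ii: np.ndarray         # local pair indices (ii < jj)
    jj: np.ndarray
    w: np.ndarray          # win indicator delta_ij at the horizon
    dz: np.ndarray         # Z_i - Z_j per pair, (m, p)
    n_l: int
    weight: float          # h_l = n_l / n
    scale: float           # h_l / C(n_l, 2)


@dataclass
class SPWFit:
    """A converged stratified win-fractions regression fit."""

    beta: np.ndarray
    covariate_names: list[str]
    jacobian_blocks: dict  # stratum label -> A_l (p x p)
    score: np.ndarray
    n_per_stratum: dict
    weights: dict
    converged: bool
    iterations: int
    rule: object
    tau: float
    dataset: Dataset = field(repr=False)
    _pairs: list[_StratumPairs] = field(repr=False, default_factory=list)

    @property
    def jacobian(self) -> np.ndarray:
        """Sum of the per-stratum Jacobian blocks (negative semi-definite)."""
        return sum(self.jacobian_blocks.values())

    @property
    def win_ratios(self) -> np.ndarray:
        return np.exp(self.beta)


def win_fraction_link(z_i, z_j, beta) -> float:
    """Conditional win fraction mu = expit(beta' (z_i - z_j)).

    Overflow-safe; swapping the two subjects maps mu to 1 - mu.
    """
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return float(expit(beta @ (z_i - z_j)))


def pair_residual(pair, z_i, z_j, beta) -> float:
    """Residual delta_ij - R * mu for one compared pair; 0 if indeterminate."""
    mu = win_fraction_link(z_i, z_j, beta)
    return pair.delta_ij - pair.r * mu


def _build_pairs(dataset: Dataset, rule, tau: float) -> list[_StratumPairs]:
    n = dataset.n
    out = []
    n_degenerate = 0
    for label, idx in dataset.strata().items():
        n_l = len(idx)
        if n_l < 2:
            n_degenerate += 1
            continue
        ii, jj, w = pair_table(dataset, idx, rule, tau)
        if len(ii) == 0:
            n_degenerate += 1
            continue
        dz = dataset.Z[idx[ii]] - dataset.Z[idx[jj]]
        h_l = n_l / n
        out.append(
            _StratumPairs(
                label=label,
                idx=idx,
                ii=ii,
                jj=jj,
                w=w,
                dz=dz,
                n_l=n_l,
                weight=h_l,
                scale=h_l / comb(n_l, 2),
            )
        )
    if n_degenerate:
        logger.info(
            "%d strata carry no determinate pair (size < 2 or all "
            "comparisons censored) and contribute nothing",
            n_degenerate,
        )
    return out


def _score_info(pairs: list[_StratumPairs], beta: np.ndarray):
    """Score vector and (positive) curvature matrix at beta."""
    p = len(beta)
    score = np.zeros(p)
    info = np.zeros((p, p))
    for sp in pairs:
        eta = sp.dz @ beta
        mu = expit(eta)
        score += sp.scale * (sp.dz.T @ (sp.w - mu))
        info += sp.scale * ((sp.dz * (mu * (1 - mu))[:, None]).T @ sp.dz)
    return score, info


def estimating_function(dataset: Dataset, beta, rule="pocock", tau=None) -> np.ndarray:
    """Evaluate the stratified pairwise score at ``beta``.

    Sum over strata of h_l / C(n_l, 2) times the within-stratum sum of
    (Z_li - Z_lj) (delta_ij - R_ij mu_ij); strata with fewer than two
    subjects contribute zero.
    """
    if dataset.p == 0:
        raise ValueError("at least one covariate is required")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    tau = dataset.tau if tau is None else float(tau)
    pairs = _build_pairs(dataset, rule, tau)
    score, _ = _score_info(pairs, beta)
    return score


def fit(
    dataset: Dataset,
    rule="pocock",
    tau: float | None = None,
    weight_scheme: str = "size",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> SPWFit:
    """Solve the stratified estimating equation by Newton-Raphson.

    Starts at beta = 0, stops when the score sup-norm falls below ``tol``,
    and halves the step whenever the score norm would increase.  The fit is
    deterministic given the data.
    """
    if dataset.p == 0:
        raise ValueError("at least one covariate is required")
    if weight_scheme != "size":
        raise NotImplementedError("only the n_l/n size weight is implemented")
    tau = dataset.tau if tau is None else float(tau)
    pairs = _build_pairs(dataset, rule, tau)
    if not pairs:
        raise ValueError("no stratum contains a determinate pair")

    p = dataset.p
    beta = np.zeros(p)
    score, info = _score_info(pairs, beta)
    it = 0
    converged = np.max(np.abs(score)) < tol
    while not converged and it < max_iter:
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            null = _null_covariates(info, dataset.covariate_names)
            raise SingularFitError(
                "singular Jacobian: pair differences are collinear in "
                f"covariates {null}"
            ) from None
        norm0 = np.max(np.abs(score))
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            score_c, info_c = _score_info(pairs, cand)
            if np.max(np.abs(score_c)) < norm0 or lam < 1e-6:
                break
            lam /= 2.0
        beta, score, info = cand, score_c, info_c
        it += 1
        converged = np.max(np.abs(score)) < tol
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(score sup-norm {np.max(np.abs(score)):.3e})",
            beta=beta,
            score=score,
        )

    # per-stratum Jacobian blocks A_l at the solution
    blocks = {}
    for sp in pairs:
        mu = expit(sp.dz @ beta)
        blocks[sp.label] = -sp.scale * (
            (sp.dz * (mu * (1 - mu))[:, None]).T @ sp.dz
        )
    return SPWFit(
        beta=beta,
        covariate_names=list(dataset.covariate_names),
        jacobian_blocks=blocks,
        score=score,
        n_per_stratum={sp.label: sp.n_l for sp in pairs},
        weights={sp.label: sp.weight for sp in pairs},
        converged=True,
        iterations=it,
        rule=rule,
        tau=tau,
        dataset=dataset,
        _pairs=pairs,
    )


def _null_covariates(info: np.ndarray, names) -> list[str]:
    """Covariates spanning the (near-)null space of the curvature matrix."""
    vals, vecs = np.linalg.eigh(info)
    tolerance = max(info.shape) * np.finfo(float).eps * max(vals.max(), 1.0)
    flagged = set()
    for k in np.flatnonzero(vals <= tolerance):
        for j in np.flatnonzero(np.abs(vecs[:, k]) > 1e-8):
            flagged.add(names[j])
    return sorted(flagged) or list(names)
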