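"""Constrained maximum likelihood with model averaging (cML-MA-BIC).

The estimator treats each instrument j as having a true exposure effect
gamma_j and a direct (pleiotropic) outcome effect alpha_j, with observed
summary effects

    beta_exp_j ~ N(gamma_j, se_exp_j^2)
    beta_out_j ~ N(theta * gamma_j + alpha_j, se_out_j^2).

For each candidate number K of invalid instruments the likelihood is
maximized subject to "at most K of the alpha_j are nonzero" by coordinate
updates: given theta, the K instruments with the largest squared
standardized residuals receive a free alpha (their contribution to the
likelihood then vanishes, since gamma_j = beta_exp_j and alpha_j absorbs the
rest), the remaining gammas are profiled analytically, and theta is updated
by weighted regression on the alpha = 0 set. BIC(K) = K log(n_eff) - 2
loglik selects K; estimates are also model-averaged with weights
proportional to exp(-BIC/2). Multiple seeded restarts guard against local
optima of the combinatorial invalid-set choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .sumstats import HarmonizedIV

__all__ = ["CMLFit", "CMLResult", "cml_ma_bic", "profile_loglik"]


@dataclass(frozen=True)
class CMLFit:
    """Constrained-ML fit for one candidate invalid count K."""

    k_invalid: int
    beta: float
    se: float
    bic: float
    loglik: float
    invalid_set: frozenset[str]
    converged: bool


@dataclass(frozen=True)
class CMLResult:
    """Full cML output: per-K fits, the BIC-selected fit, and the model average."""

    per_k: tuple[CMLFit, ...]
    selected_k: int
    selected_beta: float
    selected_se: float
    selected_pvalue: float
    ma_beta: float
    ma_se: float
    ma_pvalue: float
    ma_weights: tuple[float, ...]
    converged: bool

    @property
    def invalid_set(self) -> frozenset[str]:
        """Invalid instruments at the BIC-selected K."""
        for fit in self.per_k:
            if fit.k_invalid == self.selected_k:
                return fit.invalid_set
        raise RuntimeError("selected_k not among per_k fits")


def profile_loglik(theta: float, bx, by, sx, sy, valid_mask) -> float:
    """Log-likelihood (constants dropped) profiled over the gammas.

    For a valid instrument, maximizing over gamma_j at fixed theta leaves
    -(by_j - theta bx_j)^2 / (2 (sy_j^2 + theta^2 sx_j^2)); invalid
    instruments contribute zero (their gamma and alpha absorb both
    residuals).
    """
    bxv, byv = bx[valid_mask], by[valid_mask]
    sxv, syv = sx[valid_mask], sy[valid_mask]
    denom = syv**2 + theta**2 * sxv**2
    return float(-0.5 * np.sum((byv - theta * bxv) ** 2 / denom))


def _fit_one_k(bx, by, sx, sy, snp_ids, K, theta0, max_iter, tol):
    """Coordinate-update fit at fixed invalid count K from a given start."""
    k = len(bx)
    theta = theta0
    invalid = np.zeros(k, dtype=bool)
    converged = False
    for _ in range(max_iter):
        # rank by squared standardized residual at current theta
        resid2 = (by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)
        invalid_new = np.zeros(k, dtype=bool)
        if K > 0:
            invalid_new[np.argsort(-resid2, kind="stable")[:K]] = True
        valid = ~invalid_new
        # profile gammas on the valid set, then refit theta by weighted
        # regression of by on the profiled gammas
        gam = (bx[valid] / sx[valid] ** 2 + theta * by[valid] / sy[valid] ** 2) / (
            1.0 / sx[valid] ** 2 + theta**2 / sy[valid] ** 2
        )
        denom = float(np.sum(gam**2 / sy[valid] ** 2))
        if denom == 0.0:
            break
        theta_new = float(np.sum(gam * by[valid] / sy[valid] ** 2)) / denom
        if np.array_equal(invalid_new, invalid) and abs(theta_new - theta) < tol * max(1.0, abs(theta)):
            theta, invalid = theta_new, invalid_new
            converged = True
            break
        theta, invalid = theta_new, invalid_new
    valid = ~invalid
    ll = profile_loglik(theta, bx, by, sx, sy, valid)
    # SE from the curvature of the profile log-likelihood at theta-hat
    h = 1e-4 * max(1.0, abs(theta))
    d2 = (
        profile_loglik(theta + h, bx, by, sx, sy, valid)
        - 2.0 * ll
        + profile_loglik(theta - h, bx, by, sx, sy, valid)
    ) / (h * h)
    if d2 < 0:
        se = math.sqrt(-1.0 / d2)
    else:  # flat likelihood (degenerate); fall back to IVW-style variance
        se = math.sqrt(1.0 / np.sum(bx[valid] ** 2 / sy[valid] ** 2))
    inv_ids = frozenset(str(snp_ids[i]) for i in np.nonzero(invalid)[0])
    return theta, se, ll, inv_ids, converged


def _two_sided_p(z: float) -> float:
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))


def cml_ma_bic(
    ivs: Sequence[HarmonizedIV],
    n_eff: int,
    k_max: int | None = None,
    n_restart: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CMLResult:
    """Constrained-ML causal estimate with BIC selection and model averaging.

    Parameters
    ----------
    ivs:
        Harmonized instruments (at least 2).
    n_eff:
        Effective sample size entering the BIC penalty; conventionally the
        smaller of the exposure and outcome GWAS sizes.
    k_max:
        Largest invalid count considered; defaults to n_snp - 2 so at least
        two instruments always remain valid.
    n_restart:
        Random restarts per K (the first start is the IVW estimate, the rest
        perturb it), guarding against local optima.
    """
    k = len(ivs)
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "cml_ma_bic")
    if k_max is None:
        k_max = k - 2
    if not (0 <= k_max <= k - 2):
        raise ValueError(f"k_max = {k_max} must lie in [0, n_snp - 2] = [0, {k - 2}]")
    if n_eff < 2:
        raise ValueError(f"n_eff = {n_eff} must be at least 2")

    bx = np.array([iv.beta_exp for iv in ivs], dtype=float)
    by = np.array([iv.beta_out for iv in ivs], dtype=float)
    sx = np.array([iv.se_exp for iv in ivs], dtype=float)
    sy = np.array([iv.se_out for iv in ivs], dtype=float)
    snp_ids = [iv.snp_id for iv in ivs]

    w = 1.0 / (sy * sy)
    theta_ivw = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    se_ivw = math.sqrt(1.0 / float(np.sum(w * bx * bx)))
    rng = np.random.default_rng(seed)

    fits: list[CMLFit] = []
    for K in range(k_max + 1):
        best = None
        for r in range(max(1, n_restart)):
            theta0 = theta_ivw if r == 0 else float(rng.normal(theta_ivw, 5.0 * se_ivw + 0.1))
            theta, se, ll, inv_ids, conv = _fit_one_k(
                bx, by, sx, sy, snp_ids, K, theta0, max_iter, tol
            )
            if best is None or ll > best[2] + 1e-12:
                best = (theta, se, ll, inv_ids, conv)
        theta, se, ll, inv_ids, conv = best
        bic = K * math.log(n_eff) - 2.0 * ll
        fits.append(CMLFit(K, theta, se, bic, ll, inv_ids, conv))

    bics = np.array([f.bic for f in fits])
    sel = int(np.argmin(bics))
    selected = fits[sel]

    wts = np.exp(-(bics - bics.min()) / 2.0)
    wts = wts / wts.sum()
    ma_beta = float(np.sum(wts * np.array([f.beta for f in fits])))
    # Buckland model-averaged variance: within-model + between-model spread
    ma_se = float(
        math.sqrt(np.sum(wts * (np.array([f.se for f in fits]) ** 2
                                + (np.array([f.beta for f in fits]) - ma_beta) ** 2)))
    )
    return CMLResult(
        per_k=tuple(fits),
        selected_k=selected.k_invalid,
        selected_beta=selected.beta,
        selected_se=selected.se,
        selected_pvalue=_two_sided_p(selected.beta / selected.se),
        ma_beta=ma_beta,
        ma_se=ma_se,
        ma_pvalue=_two_sided_p(ma_beta / ma_se),
        ma_weights=tuple(float(x) for x in wts),
        converged=all(f.converged for f in fits),
    )
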