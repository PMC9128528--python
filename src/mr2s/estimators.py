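"""Causal-effect estimators for two-sample MR on harmonized instruments.

All estimators consume :class:`~mr2s.sumstats.HarmonizedIV` lists and return
:class:`MREstimate` on the log odds-ratio scale (per SD of the exposure),
with the exponentiated OR and a normal-theory 95% interval attached.

Implemented methods:

* Wald ratio — single-instrument estimate, outcome effect over exposure
  effect, first-order delta-method SE (second-order optional);
* IVW — inverse-variance-weighted meta-analysis of Wald ratios, identical
  to weighted least squares of the outcome effects on the exposure effects
  through the origin with weights 1/se_out^2; the multiplicative
  random-effects variant inflates the SE by sqrt(max(1, Q/(k-1)));
* weighted median — consistent when instruments carrying at least half the
  weight are valid; SE by seeded parametric bootstrap;
* MR-Egger — weighted regression with an intercept; the slope is the causal
  estimate and a nonzero intercept indicates directional pleiotropy.

The constrained-maximum-likelihood estimator lives in :mod:`mr2s.cml` and is
re-exported here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .sumstats import HarmonizedIV

__all__ = [
    "MREstimate",
    "EggerIntercept",
    "Z95",
    "make_estimate",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "weighted_median_point",
    "egger",
    "ratios_and_weights",
]

#: two-sided 97.5% normal quantile used for all 95% intervals
Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal-effect result.

    ``beta`` is the log odds ratio of the outcome per SD increase of the
    exposure; ``or_value`` and its bounds are the exponentiated counterparts.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_ci_low: float
    or_ci_high: float
    pvalue: float
    n_snp: int


@dataclass(frozen=True)
class EggerIntercept:
    """The MR-Egger intercept: average directional pleiotropy per instrument."""

    value: float
    se: float
    pvalue: float


def _two_sided_p(z: float) -> float:
    # clamp into (0, 1]: ``norm.sf`` underflows to 0 for |z| >~ 38
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))


def make_estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    """Wrap a (beta, se) pair with normal 95% CI, OR scale and two-sided p."""
    if se <= 0 or not math.isfinite(se):
        raise ValueError(f"{method}: standard error must be positive and finite, got {se}")
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        or_value=math.exp(beta),
        or_ci_low=math.exp(lo),
        or_ci_high=math.exp(hi),
        pvalue=_two_sided_p(beta / se),
        n_snp=n_snp,
    )


def _arrays(ivs: Sequence[HarmonizedIV]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([iv.beta_exp for iv in ivs], dtype=float)
    by = np.array([iv.beta_out for iv in ivs], dtype=float)
    sx = np.array([iv.se_exp for iv in ivs], dtype=float)
    sy = np.array([iv.se_out for iv in ivs], dtype=float)
    return bx, by, sx, sy


def ratios_and_weights(ivs: Sequence[HarmonizedIV]) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and their first-order inverse-variance weights.

    The ratio beta_out/beta_exp has first-order variance se_out^2/beta_exp^2,
    so the IVW weight on the ratio scale is beta_exp^2/se_out^2 — the same
    weighting as WLS through the origin with weights 1/se_out^2.
    """
    bx, by, _, sy = _arrays(ivs)
    if np.any(bx == 0.0):
        raise UndefinedRatioError("zero exposure effect among instruments")
    return by / bx, bx * bx / (sy * sy)


def wald_ratio(iv: HarmonizedIV, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta method se_out/|beta_exp|, which
    ignores the exposure-side uncertainty and matches the IVW weighting
    scheme. ``second_order=True`` adds the beta_out^2 se_exp^2 / beta_exp^4
    term.
    """
    if iv.beta_exp == 0.0:
        raise UndefinedRatioError(f"{iv.snp_id}: exposure effect is zero")
    beta = iv.beta_out / iv.beta_exp
    var = iv.se_out**2 / iv.beta_exp**2
    if second_order:
        var += iv.beta_out**2 * iv.se_exp**2 / iv.beta_exp**4
    return make_estimate("wald", beta, math.sqrt(var), 1)


def ivw(
    ivs: Sequence[HarmonizedIV],
    model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate from two or more instruments.

    Equivalent to WLS of beta_out on beta_exp through the origin with
    weights 1/se_out^2. Under ``multiplicative_random`` (the default
    headline model) the SE is inflated by sqrt(max(1, Q/(k-1))) where Q is
    Cochran's Q of the fit, so the random-effects SE can never fall below
    the fixed-effect one.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(ivs)
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "ivw (use wald_ratio for a single instrument)")
    bx, by, _, sy = _arrays(ivs)
    w = 1.0 / (sy * sy)
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se = math.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    method = "ivw_fixed"
    if model == "multiplicative_random":
        se *= math.sqrt(max(1.0, q / (k - 1)))
        method = "ivw_mre"
    return make_estimate(method, beta, se, k)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% weighted percentile of the ratio estimates.

    Weights are normalized to sum to one; cumulative weight is evaluated at
    the midpoint of each sorted observation's mass and the 0.5 crossing is
    linearly interpolated between neighbouring ratios.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    mid = np.cumsum(w) - 0.5 * w
    if 0.5 <= mid[0]:
        return float(r[0])
    if 0.5 >= mid[-1]:
        return float(r[-1])
    return float(np.interp(0.5, mid, r))


def weighted_median(
    ivs: Sequence[HarmonizedIV],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when instruments contributing at least 50% of the weight are
    valid. The SE resamples beta_exp and beta_out from their normal sampling
    distributions ``n_boot`` times (seeded, reproducible) and takes the
    standard deviation of the resampled medians.
    """
    k = len(ivs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "weighted_median")
    bx, by, sx, sy = _arrays(ivs)
    if np.any(bx == 0.0):
        raise UndefinedRatioError("zero exposure effect among instruments")
    w = bx * bx / (sy * sy)
    point = weighted_median_point(by / bx, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    bx_star = np.where(bx_star == 0.0, np.finfo(float).tiny, bx_star)
    ratios = by_star / bx_star
    weights = bx_star * bx_star / (sy * sy)
    # vectorized weighted median over bootstrap rows
    order = np.argsort(ratios, axis=1, kind="stable")
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    w_sorted = np.take_along_axis(weights, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    mid = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boot = np.empty(n_boot)
    for i in range(n_boot):  # np.interp has no axis argument
        boot[i] = np.interp(0.5, mid[i], r_sorted[i])
    se = float(np.std(boot, ddof=1))
    return make_estimate("weighted_median", point, se, k)


def egger(
    ivs: Sequence[HarmonizedIV],
    dist: str = "normal",
) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: slope (causal estimate) and pleiotropy intercept.

    Instruments are first oriented so every beta_exp is positive (both betas
    negated where needed; the fit is invariant to joint sign changes only
    through this convention). The fit is WLS of beta_out on beta_exp with an
    intercept and weights 1/se_out^2; coefficient SEs carry a multiplicative
    overdispersion factor max(1, sigma_hat) where sigma_hat^2 is the weighted
    residual mean square on k-2 df, so they never undershoot the
    fixed-effect SEs.

    ``dist`` chooses the reference distribution for the p-values: ``normal``
    (default) or ``t`` on k-2 df — reference implementations differ on this
    point.
    """
    k = len(ivs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "egger")
    if dist not in ("normal", "t"):
        raise ValueError(f"unknown reference distribution {dist!r}")
    bx, by, _, sy = _arrays(ivs)
    flip = np.sign(bx)
    flip[flip == 0.0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / (sy * sy)

    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swy = float(np.sum(w * y))
    swxx = float(np.sum(w * x * x))
    swxy = float(np.sum(w * x * y))
    det = sw * swxx - swx * swx
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = y - intercept - slope * x
    sigma2 = float(np.sum(w * resid * resid)) / (k - 2)
    infl = max(1.0, sigma2)
    var_slope = sw / det * infl
    var_int = swxx / det * infl

    se_slope = math.sqrt(var_slope)
    se_int = math.sqrt(var_int)
    if dist == "t":
        p_slope = float(min(1.0, max(2.0 * stats.t.sf(abs(slope / se_slope), k - 2), 5e-324)))
        p_int = float(min(1.0, max(2.0 * stats.t.sf(abs(intercept / se_int), k - 2), 5e-324)))
        est = MREstimate(
            method="egger_slope", beta=slope, se=se_slope,
            ci_low=slope - Z95 * se_slope, ci_high=slope + Z95 * se_slope,
            or_value=math.exp(slope),
            or_ci_low=math.exp(slope - Z95 * se_slope),
            or_ci_high=math.exp(slope + Z95 * se_slope),
            pvalue=p_slope, n_snp=k,
        )
        return est, EggerIntercept(intercept, se_int, p_int)
    est = make_estimate("egger_slope", slope, se_slope, k)
    return est, EggerIntercept(intercept, se_int, _two_sided_p(intercept / se_int))


# re-export so that the estimator suite is importable from one place
from .cml import CMLResult, cml_ma_bic  # noqa: E402,F401

__all__ += ["CMLResult", "cml_ma_bic"]
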