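"""Heterogeneity, outlier and influence diagnostics for an instrument set.

* Cochran's Q — chi-square heterogeneity of the per-instrument ratio
  estimates around a pooled value;
* MR-PRESSO — simulation-based residual-sum test that detects global
  horizontal pleiotropy, flags per-instrument outliers, re-estimates with
  outliers removed, and tests whether removal distorts the estimate;
* leave-one-out — the headline IVW estimate recomputed with each instrument
  excluded in turn;
* funnel/scatter exports — the numeric content of the standard diagnostic
  plots, as plain tables.

All stochastic procedures are seeded and bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, make_estimate, ratios_and_weights
from .exceptions import ConfigError, InsufficientInstrumentsError
from .sumstats import HarmonizedIV

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LooResult",
    "cochran_q",
    "presso",
    "leave_one_out",
    "funnel_scatter_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pvalue: float
    per_snp_pvalue: dict[str, float]
    outliers: frozenset[str]
    distortion_pvalue: float | None
    corrected: MREstimate | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class LooResult:
    rows: tuple[tuple[str, MREstimate], ...]
    full: MREstimate


def cochran_q(ivs: Sequence[HarmonizedIV], pooled_beta: float) -> HeterogeneityResult:
    """Cochran's Q of the per-instrument Wald ratios around ``pooled_beta``.

    Q = sum_j w_j (ratio_j - pooled)^2 with the first-order IVW weights
    w_j = beta_exp_j^2 / se_out_j^2; df = k - 1; upper-tail chi-square p.
    Q is minimized when ``pooled_beta`` is the fixed-effect IVW estimate.
    """
    k = len(ivs)
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "cochran_q")
    ratios, weights = ratios_and_weights(ivs)
    q = float(np.sum(weights * (ratios - pooled_beta) ** 2))
    return HeterogeneityResult(q=q, df=k - 1, pvalue=float(stats.chi2.sf(q, k - 1)))


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with each instrument left out, vectorized."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def presso(
    ivs: Sequence[HarmonizedIV],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares uses each instrument's prediction
    from the IVW fit that excludes it. The null distribution is built from
    ``n_sim`` parametric draws of (beta_exp, beta_out) around the
    leave-one-out fitted model, with the leave-one-out slopes refitted on
    every draw. The global p-value is the empirical exceedance; per-SNP
    p-values come from each instrument's simulated residual distribution,
    and outliers are declared at ``outlier_alpha`` Bonferroni-corrected over
    the instrument count (``outlier_alpha = 0`` therefore never declares
    outliers). When outliers are found, the outlier-removed IVW estimate is
    returned together with a distortion p-value comparing the observed shift
    against removal of random same-sized instrument subsets.
    """
    k = len(ivs)
    if k < 4:
        raise InsufficientInstrumentsError(4, k, "presso")
    if n_sim < 100:
        raise ConfigError(f"n_sim = {n_sim} too small for empirical p-values (need >= 100)")
    bx = np.array([iv.beta_exp for iv in ivs], dtype=float)
    by = np.array([iv.beta_out for iv in ivs], dtype=float)
    sx = np.array([iv.se_exp for iv in ivs], dtype=float)
    sy = np.array([iv.se_out for iv in ivs], dtype=float)
    ids = [iv.snp_id for iv in ivs]
    w = 1.0 / (sy * sy)

    theta_loo = _loo_thetas(bx, by, w)
    obs_res = w * (by - theta_loo * bx) ** 2
    obs_rss = float(np.sum(obs_res))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    s_xy = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_star * bx_star, axis=1, keepdims=True)
    theta_loo_star = (s_xy - w * bx_star * by_star) / (s_xx - w * bx_star * bx_star)
    sim_res = w * (by_star - theta_loo_star * bx_star) ** 2
    sim_rss = np.sum(sim_res, axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))
    per_p = (1 + np.sum(sim_res >= obs_res[None, :], axis=0)) / (n_sim + 1)
    per_snp_pvalue = {ids[j]: float(per_p[j]) for j in range(k)}

    cut = outlier_alpha / k
    outliers = frozenset(ids[j] for j in range(k) if per_p[j] < cut)

    corrected: MREstimate | None = None
    distortion_p: float | None = None
    if outliers:
        keep = [iv for iv in ivs if iv.snp_id not in outliers]
        if len(keep) >= 2:
            corrected = ivw(keep, model="multiplicative_random")
            full = ivw(ivs, model="multiplicative_random")
            if corrected.beta != 0.0:
                d_obs = abs(full.beta - corrected.beta) / abs(corrected.beta)
                n_out = len(outliers)
                d_null = np.empty(n_sim)
                w_xx = w * bx * bx
                w_xy = w * bx * by
                s_xx_full = float(np.sum(w_xx))
                s_xy_full = float(np.sum(w_xy))
                theta_full = s_xy_full / s_xx_full
                for i in range(n_sim):
                    drop = rng.choice(k, size=n_out, replace=False)
                    t_sub = (s_xy_full - w_xy[drop].sum()) / (s_xx_full - w_xx[drop].sum())
                    d_null[i] = abs(theta_full - t_sub) / abs(t_sub) if t_sub != 0 else np.inf
                distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))
    return PressoResult(
        global_rss=obs_rss,
        global_pvalue=global_p,
        per_snp_pvalue=per_snp_pvalue,
        outliers=outliers,
        distortion_pvalue=distortion_p,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(ivs: Sequence[HarmonizedIV]) -> LooResult:
    """Multiplicative-random-effects IVW with each instrument excluded in turn."""
    k = len(ivs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "leave_one_out")
    rows = []
    for i in range(k):
        subset = [iv for j, iv in enumerate(ivs) if j != i]
        rows.append((ivs[i].snp_id, ivw(subset, model="multiplicative_random")))
    return LooResult(rows=tuple(rows), full=ivw(ivs, model="multiplicative_random"))


def funnel_scatter_data(
    ivs: Sequence[HarmonizedIV],
    fits: Sequence[MREstimate] = (),
) -> dict[str, pd.DataFrame]:
    """Numeric funnel/scatter content: per-SNP rows plus one line per fit.

    Returns three frames: ``funnel`` (snp, ratio, precision = 1/se_ratio),
    ``scatter`` (snp, beta_exp, se_exp, beta_out, se_out), and ``lines``
    (method, slope, intercept — intercept 0 for through-origin fits).
    """
    funnel_rows = []
    scatter_rows = []
    for iv in ivs:
        ratio = iv.beta_out / iv.beta_exp if iv.beta_exp != 0 else float("nan")
        se_ratio = iv.se_out / abs(iv.beta_exp) if iv.beta_exp != 0 else float("nan")
        funnel_rows.append({"snp": iv.snp_id, "ratio": ratio,
                            "precision": 1.0 / se_ratio if se_ratio else float("nan")})
        scatter_rows.append({"snp": iv.snp_id, "beta_exp": iv.beta_exp, "se_exp": iv.se_exp,
                             "beta_out": iv.beta_out, "se_out": iv.se_out})
    lines = [{"method": f.method, "slope": f.beta, "intercept": 0.0} for f in fits]
    return {
        "funnel": pd.DataFrame(funnel_rows, columns=["snp", "ratio", "precision"]),
        "scatter": pd.DataFrame(scatter_rows,
                                columns=["snp", "beta_exp", "se_exp", "beta_out", "se_out"]),
        "lines": pd.DataFrame(lines, columns=["method", "slope", "intercept"]),
    }
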