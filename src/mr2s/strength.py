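"""Instrument-strength and statistical-power metrics.

PVE (proportion of exposure variance explained by one variant, on the
standardized scale) is 2 EAF (1 - EAF) beta^2; the F-statistic for a model
with k instruments and exposure sample size n is
[PVE (n - 1 - k)] / [(1 - PVE) k]. Binary-outcome power uses the standard
normal approximation behind the common online MR power calculators:

    power = Phi( sqrt(n * PVE * cf * (1 - cf)) * |log OR| - z_{1-alpha/2} )

with cf the case fraction of the outcome study. It is an approximation and
is labeled as such; it is monotone in n, PVE and |log OR|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .sumstats import HarmonizedIV, SumstatRecord

__all__ = ["StrengthResult", "pve", "f_statistic", "power_binary", "instrument_strength"]


@dataclass(frozen=True)
class StrengthResult:
    """PVE and F summaries for one instrument set.

    ``f_stat`` is the joint F for the k-instrument model; ``per_snp_f``
    evaluates each instrument alone (k = 1). ``n`` is the smallest exposure
    sample size among the instruments (they may differ per SNP in
    meta-analysed GWAS).
    """

    per_snp_pve: dict[str, float]
    total_pve: float
    f_stat: float
    per_snp_f: dict[str, float]
    n: int
    k: int


def pve(eaf: float, beta: float) -> float:
    """Variance in the standardized exposure explained by one variant."""
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf = {eaf} must lie in (0, 1)")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(total_pve: float, n: int, k: int) -> float:
    """F-statistic of a k-instrument model explaining ``total_pve`` at size n."""
    if not (0.0 <= total_pve < 1.0):
        raise ValueError(f"total_pve = {total_pve} must lie in [0, 1)")
    if k < 1:
        raise ValueError(f"k = {k} must be at least 1")
    if n <= k + 1:
        raise ValueError(f"n = {n} must exceed k + 1 = {k + 1}")
    return (total_pve * (n - 1 - k)) / ((1.0 - total_pve) * k)


def power_binary(
    total_pve: float,
    n: int,
    case_fraction: float,
    or_hypothesis: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power to detect ``or_hypothesis`` with a binary outcome.

    At OR = 1 this returns Phi(-z_{1-alpha/2}), the one-sided tail of the
    two-sided test (about 0.025 at alpha = 0.05).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha = {alpha} must lie in (0, 1)")
    if not (0.0 <= total_pve < 1.0):
        raise ValueError(f"total_pve = {total_pve} must lie in [0, 1)")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError(f"case_fraction = {case_fraction} must lie in (0, 1)")
    if or_hypothesis <= 0:
        raise ValueError(f"or_hypothesis = {or_hypothesis} must be positive")
    if n < 1:
        raise ValueError(f"n = {n} must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = math.sqrt(n * total_pve * case_fraction * (1.0 - case_fraction)) * abs(math.log(or_hypothesis))
    return float(stats.norm.cdf(ncp - z))


def instrument_strength(
    ivs: Sequence[HarmonizedIV] | Sequence[SumstatRecord],
    n: int | None = None,
) -> StrengthResult:
    """Per-SNP and joint PVE/F for a set of instruments.

    Accepts harmonized instruments (uses the exposure-side fields) or raw
    exposure records. ``n`` defaults to the smallest per-SNP exposure sample
    size available; it must be supplied when the records carry none.
    """
    per_pve: dict[str, float] = {}
    ns: list[int] = []
    for iv in ivs:
        if isinstance(iv, HarmonizedIV):
            per_pve[iv.snp_id] = pve(iv.eaf_exp, iv.beta_exp)
            if iv.n_exp is not None:
                ns.append(iv.n_exp)
        else:
            per_pve[iv.snp_id] = pve(iv.eaf, iv.beta)
            ns.append(iv.n)
    k = len(per_pve)
    if k == 0:
        raise ValueError("no instruments supplied")
    if n is None:
        if not ns:
            raise ValueError("sample size n not available from records; pass n explicitly")
        n = min(ns)
    total = sum(per_pve.values())
    return StrengthResult(
        per_snp_pve=per_pve,
        total_pve=total,
        f_stat=f_statistic(total, n, k),
        per_snp_f={s: f_statistic(p, n, 1) for s, p in per_pve.items()},
        n=n,
        k=k,
    )
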