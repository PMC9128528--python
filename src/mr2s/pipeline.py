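"""End-to-end orchestration of a multi-trait two-sample MR screen.

For each exposure trait the funnel runs significance filtering, LD clumping,
proxy substitution, outcome-pleiotropy and confounder exclusion, and allele
harmonization; the estimator suite is then chosen by surviving instrument
count:

* 0 instruments → no estimate (verdict ``insufficient``);
* 1 → Wald ratio;
* 2 → IVW and cML;
* >= 3 → IVW, weighted median, MR-Egger, cML (and MR-PRESSO from 4 up),
  plus Cochran's Q, leave-one-out and funnel/scatter exports.

The headline estimate is IVW with multiplicative random effects (the Wald
ratio for a single instrument). A trait's verdict is ``robust`` when the
headline p-value clears the Bonferroni threshold (0.05 over the number of
traits screened) with no contradiction from the sensitivity suite,
``suggestive`` at nominal 0.05, else ``null``. A contradiction is recorded
when any pleiotropy-robust estimator is nominally significant with the
opposite sign to the headline, or the Egger intercept is nominally
significant.

Reverse-direction (outcome-as-exposure) runs apply one extra filter first:
instruments inside the MHC region are excluded, since its extended LD and
pervasive pleiotropy make immune-disease instruments there untrustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    EggerIntercept, MREstimate, egger, ivw, wald_ratio, weighted_median,
)
from .cml import CMLResult, cml_ma_bic
from .exceptions import Mr2sError
from .selection import FunnelReport, SelectionConfig, harmonize_tables
from .sensitivity import (
    HeterogeneityResult, LooResult, PressoResult, cochran_q, leave_one_out, presso,
)
from .strength import StrengthResult, instrument_strength
from .sumstats import HarmonizedIV, LDReference, SumstatRecord

__all__ = [
    "EstimatorConfig",
    "TraitReport",
    "DEFAULT_MHC_REGION",
    "select_methods",
    "analyze_ivs",
    "run_forward",
    "run_reverse",
    "forest_data",
]

#: conventional MHC window (chromosome 6), overridable per call
DEFAULT_MHC_REGION = ("6", 25_000_000, 35_000_000)

VERDICTS = ("robust", "suggestive", "null", "insufficient")


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by the stochastic estimators and diagnostics."""

    seed: int = 0
    n_boot_median: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    cml_n_restart: int = 3
    cml_n_eff: int | None = None   # defaults to min(exposure n, outcome n) of the IVs


@dataclass
class TraitReport:
    """Everything the screen computed for one exposure-outcome pair."""

    trait: str
    n_iv_stage_counts: dict[str, int]
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    egger_intercept: EggerIntercept | None
    cml: CMLResult | None
    presso: PressoResult | None
    loo: LooResult | None
    strength: StrengthResult | None
    bonferroni_alpha: float
    verdict: str
    contradiction: bool
    funnel: FunnelReport | None = None
    mhc_excluded: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def headline(self) -> MREstimate | None:
        """The estimate the verdict is based on: IVW (MRE), or Wald for one IV."""
        for m in ("ivw_mre", "wald"):
            for e in self.estimates:
                if e.method == m:
                    return e
        return None


def select_methods(n_iv: int) -> list[str]:
    """Estimator suite for a given surviving instrument count."""
    if n_iv < 0:
        raise ValueError("n_iv must be nonnegative")
    if n_iv == 0:
        return []
    if n_iv == 1:
        return ["wald"]
    if n_iv == 2:
        return ["ivw", "cml"]
    methods = ["ivw", "weighted_median", "egger", "cml"]
    if n_iv >= 4:
        methods.append("presso")
    return methods


def _default_n_eff(ivs: Sequence[HarmonizedIV]) -> int:
    ns = [n for iv in ivs for n in (iv.n_exp, iv.n_out) if n is not None]
    return min(ns) if ns else 10_000


def analyze_ivs(
    trait: str,
    ivs: Sequence[HarmonizedIV],
    bonferroni_alpha: float,
    est_cfg: EstimatorConfig = EstimatorConfig(),
    funnel: FunnelReport | None = None,
    mhc_excluded: int = 0,
) -> TraitReport:
    """Run the method-selection rule, estimators, diagnostics and verdict."""
    n_iv = len(ivs)
    methods = select_methods(n_iv)
    estimates: list[MREstimate] = []
    het = egg_int = cml_res = presso_res = loo_res = strength_res = None
    notes: list[str] = []

    if n_iv >= 1:
        try:
            strength_res = instrument_strength(ivs)
        except ValueError as exc:
            notes.append(f"strength unavailable: {exc}")

    if "wald" in methods:
        estimates.append(wald_ratio(ivs[0]))
    if "ivw" in methods:
        estimates.append(ivw(ivs, model="multiplicative_random"))
        ivw_fixed = ivw(ivs, model="fixed")
        estimates.append(ivw_fixed)
        het = cochran_q(ivs, ivw_fixed.beta)
    if "weighted_median" in methods:
        estimates.append(weighted_median(ivs, n_boot=est_cfg.n_boot_median, seed=est_cfg.seed))
    if "egger" in methods:
        slope, egg_int = egger(ivs)
        estimates.append(slope)
    if "cml" in methods:
        n_eff = est_cfg.cml_n_eff or _default_n_eff(ivs)
        cml_res = cml_ma_bic(
            ivs, n_eff=n_eff, n_restart=est_cfg.cml_n_restart, seed=est_cfg.seed,
        )
        from .estimators import make_estimate
        estimates.append(make_estimate("cml_ma_bic", cml_res.ma_beta, cml_res.ma_se, n_iv))
        if not cml_res.converged:
            notes.append("cML did not converge for every candidate invalid count")
    if "presso" in methods:
        presso_res = presso(
            ivs, n_sim=est_cfg.presso_n_sim, seed=est_cfg.seed,
            outlier_alpha=est_cfg.presso_outlier_alpha,
        )
        if presso_res.corrected is not None:
            estimates.append(MREstimate(
                method="presso_corrected",
                beta=presso_res.corrected.beta, se=presso_res.corrected.se,
                ci_low=presso_res.corrected.ci_low, ci_high=presso_res.corrected.ci_high,
                or_value=presso_res.corrected.or_value,
                or_ci_low=presso_res.corrected.or_ci_low,
                or_ci_high=presso_res.corrected.or_ci_high,
                pvalue=presso_res.corrected.pvalue, n_snp=presso_res.corrected.n_snp,
            ))
    if n_iv >= 3:
        loo_res = leave_one_out(ivs)

    report = TraitReport(
        trait=trait,
        n_iv_stage_counts=dict(funnel.stage_counts) if funnel else {"harmonized": n_iv},
        estimates=estimates,
        heterogeneity=het,
        egger_intercept=egg_int,
        cml=cml_res,
        presso=presso_res,
        loo=loo_res,
        strength=strength_res,
        bonferroni_alpha=bonferroni_alpha,
        verdict="insufficient",
        contradiction=False,
        funnel=funnel,
        mhc_excluded=mhc_excluded,
        notes=notes,
    )
    _assign_verdict(report)
    return report


def _assign_verdict(report: TraitReport) -> None:
    head = report.headline
    if head is None:
        report.verdict = "insufficient"
        return
    contradiction = False
    for e in report.estimates:
        if e.method in ("weighted_median", "egger_slope", "cml_ma_bic", "presso_corrected"):
            if e.pvalue < 0.05 and np.sign(e.beta) != np.sign(head.beta) and e.beta != 0.0:
                contradiction = True
    if report.egger_intercept is not None and report.egger_intercept.pvalue < 0.05:
        contradiction = True
    report.contradiction = contradiction
    if head.pvalue < report.bonferroni_alpha and not contradiction:
        report.verdict = "robust"
    elif head.pvalue < 0.05:
        report.verdict = "suggestive"
    else:
        report.verdict = "null"


def run_forward(
    exposures: Mapping[str, Sequence[SumstatRecord]],
    outcome: Sequence[SumstatRecord],
    ld: LDReference,
    cfg: SelectionConfig = SelectionConfig(),
    confounders: Sequence[Sequence[SumstatRecord]] = (),
    est_cfg: EstimatorConfig = EstimatorConfig(),
    bonferroni_divisor: int | None = None,
) -> list[TraitReport]:
    """Forward MR of every exposure trait on one outcome.

    The Bonferroni threshold is 0.05 divided by the number of traits in this
    run (overridable). A trait whose funnel leaves zero instruments yields a
    report with verdict ``insufficient``, never an exception.
    """
    divisor = bonferroni_divisor if bonferroni_divisor is not None else max(1, len(exposures))
    alpha = 0.05 / divisor
    reports: list[TraitReport] = []
    for trait, records in exposures.items():
        ivs, funnel = harmonize_tables(records, outcome, ld, cfg, confounders=confounders)
        reports.append(analyze_ivs(trait, ivs, alpha, est_cfg, funnel=funnel))
    return reports


def run_reverse(
    outcome_as_exposure: Sequence[SumstatRecord],
    target_trait: Sequence[SumstatRecord],
    ld: LDReference,
    cfg: SelectionConfig = SelectionConfig(),
    mhc_region: tuple[str, int, int] = DEFAULT_MHC_REGION,
    confounders: Sequence[Sequence[SumstatRecord]] = (),
    est_cfg: EstimatorConfig = EstimatorConfig(),
    bonferroni_divisor: int = 1,
    trait_name: str = "reverse",
) -> TraitReport:
    """Reverse-direction MR with MHC instruments excluded before the funnel."""
    chrom, start, end = mhc_region
    if start > end:
        raise ValueError(f"malformed MHC region {mhc_region}")
    kept = [r for r in outcome_as_exposure
            if not (r.chrom == str(chrom) and start <= r.pos <= end)]
    n_excluded = len(outcome_as_exposure) - len(kept)
    ivs, funnel = harmonize_tables(kept, target_trait, ld, cfg, confounders=confounders)
    funnel.stage_counts = {"input": len(outcome_as_exposure),
                           "non_mhc": len(kept), **{k: v for k, v in funnel.stage_counts.items()
                                                    if k != "input"}}
    alpha = 0.05 / max(1, bonferroni_divisor)
    report = analyze_ivs(trait_name, ivs, alpha, est_cfg, funnel=funnel,
                         mhc_excluded=n_excluded)
    return report


def forest_data(reports: Sequence[TraitReport]) -> pd.DataFrame:
    """One row per (trait, method): the numeric content of a forest plot."""
    rows = []
    for rpt in reports:
        for e in rpt.estimates:
            rows.append({
                "trait": rpt.trait, "method": e.method,
                "beta": e.beta, "se": e.se,
                "or": e.or_value, "or_ci_low": e.or_ci_low, "or_ci_high": e.or_ci_high,
                "p": e.pvalue, "n_snp": e.n_snp, "verdict": rpt.verdict,
            })
    return pd.DataFrame(rows, columns=["trait", "method", "beta", "se", "or",
                                       "or_ci_low", "or_ci_high", "p", "n_snp", "verdict"])
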