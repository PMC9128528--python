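"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator instantiates exactly the data model the estimators assume.
Each variant j has a true standardized exposure effect gamma_j and a direct
(pleiotropic) outcome effect alpha_j; the observed summary effects are

    beta_exp_j ~ N(gamma_j,               se_exp_j^2)
    beta_out_j ~ N(theta gamma_j + alpha_j, se_out_j^2)

with independent noise in the two studies (two non-overlapping cohorts) and
standard-scale standard errors se = 1 / sqrt(2 maf (1 - maf) n). For a
binary outcome study n is the effective sample size 4 / (1/cases +
1/controls). Pleiotropy models: ``none`` (all alpha = 0), ``balanced``
(alpha ~ N(0, alpha_sd^2) on a random invalid subset), ``directional``
(alpha ~ N(alpha_mean, alpha_sd^2) *on the exposure-increasing allele* —
the direct effects share a sign once instruments are oriented the way MR
fits orient them, which is what makes this model bias slope estimators),
and ``correlated`` (InSIDE-violating: alpha = alpha_mean * gamma +
N(0, alpha_sd^2), so the direct effect scales with instrument strength).

Alleles are assigned with a configurable palindromic (A/T, C/G) fraction,
and the outcome study presents each variant on a randomly swapped allele
pair half the time, so harmonization is genuinely exercised. The LD
reference is block-diagonal: every pair inside a block shares the same r2.

Size presets carry the sample sizes of the three study classes the design
emulates: a very large blood-cell-trait meta-analysis (``bcx``, n=563,085),
a small founder-population immune-cell-profiling GWAS (``sardinian``,
n=3,757), and a large case-control disease GWAS (``imsgc``, 47,429 cases /
68,374 controls, used as its effective size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigError
from .selection import SelectionConfig, DroppedIV, harmonize_pair
from .sumstats import COMPLEMENT, HarmonizedIV, LDReference, SumstatRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "effective_n",
    "preset_sizes",
    "generate",
    "to_harmonized",
]

PLEIOTROPY_MODELS = ("none", "balanced", "directional", "correlated")

_NONPALINDROMIC_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b and COMPLEMENT[a] != b
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def effective_n(cases: int, controls: int) -> int:
    """Effective sample size of a case-control study, 4/(1/cases + 1/controls)."""
    return round(4.0 / (1.0 / cases + 1.0 / controls))


def preset_sizes(name: str) -> int:
    """Sample size presets for the emulated study classes."""
    sizes = {
        "bcx": 563_085,
        "sardinian": 3_757,
        "imsgc": effective_n(47_429, 68_374),
    }
    try:
        return sizes[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(sizes)}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters of one synthetic two-sample dataset.

    ``true_theta`` is the causal log odds ratio of the outcome per SD of the
    exposure; ``gamma_sd`` the spread of true per-SNP exposure effects on the
    standardized scale (0.02 is a realistic magnitude for a well-powered
    quantitative blood trait); ``prop_invalid`` the fraction of instruments
    given a nonzero direct effect under the chosen pleiotropy model. For the
    ``correlated`` model ``alpha_mean`` is reinterpreted as the slope of the
    direct effect on gamma. ``ld_block_sizes`` partitions the first SNPs into
    LD blocks (1 kb spacing within a block; blocks far apart); remaining
    SNPs are unlinked singletons.
    """

    n_snp: int = 30
    n_exposure: int = preset_sizes("bcx")
    n_outcome: int = preset_sizes("imsgc")
    true_theta: float = 0.2
    gamma_sd: float = 0.02
    pleiotropy_model: str = "none"
    prop_invalid: float = 0.0
    alpha_mean: float = 0.05
    alpha_sd: float = 0.02
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.2
    ld_block_sizes: tuple[int, ...] = ()
    within_block_r2: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_snp < 1 or self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigError("all counts must be positive")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ConfigError(f"prop_invalid = {self.prop_invalid} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range = {self.maf_range} must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigError("palindromic_fraction must lie in [0, 1]")
        if self.pleiotropy_model not in PLEIOTROPY_MODELS:
            raise ConfigError(
                f"pleiotropy_model {self.pleiotropy_model!r} not one of {PLEIOTROPY_MODELS}")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ConfigError("within_block_r2 must lie in [0, 1]")
        if sum(self.ld_block_sizes) > self.n_snp:
            raise ConfigError("ld_block_sizes sum exceeds n_snp")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    theta: float
    per_snp_gamma: dict[str, float]
    per_snp_alpha: dict[str, float]
    invalid_set: frozenset[str]
    palindromic_set: frozenset[str]
    warnings: tuple[str, ...] = ()


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-320, 1.0)


def generate(
    config: SyntheticConfig,
) -> tuple[list[SumstatRecord], list[SumstatRecord], LDReference, SyntheticTruth]:
    """Draw one synthetic dataset: exposure table, outcome table, LD, truth."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snp
    ids = [f"rs{i + 1:05d}" for i in range(m)]

    # block layout: 1 kb spacing within a block, blocks 1 Mb apart on cycling chromosomes
    block_of = np.zeros(m, dtype=int)
    idx = 0
    block = 0
    for size in config.ld_block_sizes:
        block_of[idx:idx + size] = block
        idx += size
        block += 1
    for j in range(idx, m):
        block_of[j] = block
        block += 1
    chroms = [str((b % 22) + 1) for b in block_of]
    offset_in_block = np.zeros(m, dtype=int)
    seen: dict[int, int] = {}
    for j in range(m):
        seen[block_of[j]] = seen.get(block_of[j], -1) + 1
        offset_in_block[j] = seen[block_of[j]]
    pos = 10_000_000 + (block_of // 22) * 1_000_000 + offset_in_block * 1_000

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    is_pal = rng.random(m) < config.palindromic_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    nonpal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea_is_minor = rng.random(m) < 0.5
    eaf = np.where(ea_is_minor, maf, 1.0 - maf)

    gamma = rng.normal(0.0, config.gamma_sd, size=m)
    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    warnings: list[str] = []
    if config.pleiotropy_model != "none" and config.prop_invalid > 0:
        n_invalid = round(config.prop_invalid * m)
        invalid[rng.choice(m, size=n_invalid, replace=False)] = True
        if config.pleiotropy_model == "balanced":
            alpha[invalid] = rng.normal(0.0, config.alpha_sd, size=invalid.sum())
        elif config.pleiotropy_model == "directional":
            # drawn on the exposure-increasing orientation, then mapped back
            # to the allele coding so the shared sign survives harmonization
            draw = rng.normal(config.alpha_mean, config.alpha_sd, size=invalid.sum())
            sign = np.where(gamma[invalid] >= 0.0, 1.0, -1.0)
            alpha[invalid] = sign * draw
        else:  # correlated / InSIDE-violating
            alpha[invalid] = (config.alpha_mean * gamma[invalid]
                              + rng.normal(0.0, config.alpha_sd, size=invalid.sum()))
    if config.gamma_sd == 0.0 and config.true_theta != 0.0:
        warnings.append("gamma_sd = 0 with nonzero causal effect: instruments are null, "
                        "ratio estimates are undefined in expectation")

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(config.true_theta * gamma + alpha, se_out)
    p_exp = _pvalues(beta_exp, se_exp)
    p_out = _pvalues(beta_out, se_out)

    swap_out = rng.random(m) < 0.5   # outcome study presents the other allele

    exposure: list[SumstatRecord] = []
    outcome: list[SumstatRecord] = []
    for j in range(m):
        if is_pal[j]:
            ea, oa = _PALINDROMIC_PAIRS[pal_choice[j]]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[nonpal_choice[j]]
        exposure.append(SumstatRecord(
            snp_id=ids[j], chrom=chroms[j], pos=int(pos[j]),
            effect_allele=ea, other_allele=oa, eaf=float(eaf[j]),
            beta=float(beta_exp[j]), se=float(se_exp[j]), pvalue=float(p_exp[j]),
            n=config.n_exposure,
        ))
        if swap_out[j]:
            o_ea, o_oa, o_beta, o_eaf = oa, ea, -beta_out[j], 1.0 - eaf[j]
        else:
            o_ea, o_oa, o_beta, o_eaf = ea, oa, beta_out[j], eaf[j]
        outcome.append(SumstatRecord(
            snp_id=ids[j], chrom=chroms[j], pos=int(pos[j]),
            effect_allele=o_ea, other_allele=o_oa, eaf=float(o_eaf),
            beta=float(o_beta), se=float(se_out[j]), pvalue=float(p_out[j]),
            n=config.n_outcome,
        ))

    ld = LDReference(positions={ids[j]: (chroms[j], int(pos[j])) for j in range(m)})
    for b in np.unique(block_of):
        members = np.nonzero(block_of == b)[0]
        for i_idx in range(len(members)):
            for j_idx in range(i_idx + 1, len(members)):
                ld.add(ids[members[i_idx]], ids[members[j_idx]], config.within_block_r2)

    truth = SyntheticTruth(
        theta=config.true_theta,
        per_snp_gamma={ids[j]: float(gamma[j]) for j in range(m)},
        per_snp_alpha={ids[j]: float(alpha[j]) for j in range(m)},
        invalid_set=frozenset(ids[j] for j in range(m) if invalid[j]),
        palindromic_set=frozenset(ids[j] for j in range(m) if is_pal[j]),
        warnings=tuple(warnings),
    )
    return exposure, outcome, ld, truth


def to_harmonized(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    cfg: SelectionConfig | None = None,
) -> list[HarmonizedIV]:
    """Harmonize matched exposure/outcome records pairwise, dropping ambiguous SNPs.

    Convenience for simulation studies that exercise the estimators without
    the selection funnel; pairs are matched by snp_id and harmonized with
    :func:`mr2s.selection.harmonize_pair`.
    """
    cfg = cfg or SelectionConfig()
    out_by_id = {r.snp_id: r for r in outcome}
    ivs: list[HarmonizedIV] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        res = harmonize_pair(exp, out, cfg)
        if not isinstance(res, DroppedIV):
            ivs.append(res)
    return ivs
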