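"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mr2s.selection import SelectionConfig
from mr2s.sumstats import HarmonizedIV, SumstatRecord


def make_record(
    snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
    eaf=0.3, beta=0.05, se=0.005, pvalue=1e-10, n=100_000,
) -> SumstatRecord:
    return SumstatRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


def make_iv(
    snp_id="rs1", beta_exp=0.05, se_exp=0.005, beta_out=0.01, se_out=0.005,
    eaf=0.3, **kw,
) -> HarmonizedIV:
    return HarmonizedIV(
        snp_id=snp_id, effect_allele="A", other_allele="G", eaf_exp=eaf,
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out, **kw,
    )


def make_ivs(bx, by, sx, sy) -> list[HarmonizedIV]:
    """Vector shorthand: one harmonized IV per element."""
    return [
        make_iv(snp_id=f"rs{i + 1:04d}", beta_exp=float(bx[i]), se_exp=float(sx[i]),
                beta_out=float(by[i]), se_out=float(sy[i]))
        for i in range(len(bx))
    ]


def random_ivs(rng: np.random.Generator, k: int = 10) -> list[HarmonizedIV]:
    """Random but well-behaved instrument sets for oracle comparisons."""
    bx = rng.uniform(0.02, 0.1, k) * rng.choice([-1.0, 1.0], k)
    by = rng.normal(0.2 * bx, 0.01)
    sx = rng.uniform(0.002, 0.01, k)
    sy = rng.uniform(0.002, 0.01, k)
    return make_ivs(bx, by, sx, sy)


@pytest.fixture
def sel_cfg() -> SelectionConfig:
    return SelectionConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
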