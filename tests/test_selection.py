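"""Instrument-selection funnel: filters, clumping, proxies, harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mr2s import simulate
from mr2s.selection import (
    DroppedIV, SelectionConfig, clump, exclude_by_trait, find_proxy,
    harmonize_pair, harmonize_tables, select_significant,
)
from mr2s.sumstats import LDReference

from conftest import make_record


# --- significance filter -------------------------------------------------

def test_significance_threshold_is_strict(sel_cfg):
    recs = [make_record("rs1", pvalue=1e-9), make_record("rs2", pvalue=1e-7)]
    kept = select_significant(recs, sel_cfg)
    assert [r.snp_id for r in kept] == ["rs1"]


def test_significance_filter_matches_brute_force(sel_cfg, rng):
    exposure, _, _, _ = simulate.generate(
        simulate.SyntheticConfig(n_snp=1000, gamma_sd=0.01, seed=11))
    kept = select_significant(exposure, sel_cfg)
    brute = [r for r in exposure if r.pvalue < 5e-8]
    assert kept == brute
    assert select_significant([], sel_cfg) == []


# --- clumping ------------------------------------------------------------

def _ld_from_pairs(pairs):
    ref = LDReference()
    for a, b, r2 in pairs:
        ref.add(a, b, r2)
    return ref


def test_clump_keeps_lowest_p_in_locus(sel_cfg):
    recs = [make_record("rs1", pos=1000, pvalue=1e-10),
            make_record("rs2", pos=6000, pvalue=1e-9)]
    ld = _ld_from_pairs([("rs1", "rs2", 0.9)])
    kept = clump(recs, ld, sel_cfg)
    assert [r.snp_id for r in kept] == ["rs1"]


def test_clump_window_rule_spares_distant_snps(sel_cfg):
    recs = [make_record("rs1", pos=1000, pvalue=1e-10),
            make_record("rs2", pos=501_000, pvalue=1e-9)]
    ld = _ld_from_pairs([("rs1", "rs2", 0.9)])
    kept = clump(recs, ld, sel_cfg)
    assert {r.snp_id for r in kept} == {"rs1", "rs2"}


def test_clump_tie_broken_by_snp_id(sel_cfg):
    recs = [make_record("rsB", pos=1000, pvalue=1e-10),
            make_record("rsA", pos=2000, pvalue=1e-10)]
    ld = _ld_from_pairs([("rsA", "rsB", 0.9)])
    kept = clump(recs, ld, sel_cfg)
    assert [r.snp_id for r in kept] == ["rsA"]


def _clump_oracle_check(records, ld, cfg, retained):
    """Exhaustive independence and greedy-dominance check of a clumped set."""
    window = cfg.clump_window_kb * 1000
    kept_ids = {r.snp_id for r in retained}
    by_id = {r.snp_id: r for r in records}

    def conflict(a, b):
        return (a.chrom == b.chrom and abs(a.pos - b.pos) <= window
                and ld.r2(a.snp_id, b.snp_id) >= cfg.clump_r2)

    # validity: retained SNPs are mutually independent
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            assert not conflict(a, b), (a.snp_id, b.snp_id)
    # maximality: every discarded SNP conflicts with a retained SNP of
    # lower (p, snp_id) rank
    for r in records:
        if r.snp_id in kept_ids:
            continue
        dominators = [k for k in retained if conflict(r, k)
                      and (k.pvalue, k.snp_id) < (r.pvalue, r.snp_id)]
        assert dominators, r.snp_id


def test_clump_matches_exhaustive_oracle_on_ld_blocks(sel_cfg):
    exposure, _, ld, _ = simulate.generate(simulate.SyntheticConfig(
        n_snp=50, ld_block_sizes=(10, 10, 10, 10, 10), within_block_r2=0.8, seed=5))
    retained = clump(exposure, ld, sel_cfg)
    _clump_oracle_check(exposure, ld, sel_cfg, retained)
    # one index SNP per 10-SNP block: block members are within 10 kb at r2 0.8
    assert len(retained) == 5


# --- proxy search --------------------------------------------------------

def test_proxy_argmax_and_threshold(sel_cfg):
    cands = [make_record("rsA", pvalue=1e-9), make_record("rsB", pvalue=1e-10)]
    ld = _ld_from_pairs([("target", "rsA", 0.85), ("target", "rsB", 0.95)])
    assert find_proxy("target", cands, ld, sel_cfg).snp_id == "rsB"
    ld_low = _ld_from_pairs([("target", "rsA", 0.7)])
    assert find_proxy("target", cands, ld_low, sel_cfg) is None


def test_proxy_tie_broken_by_p_then_id(sel_cfg):
    cands = [make_record("rsB", pvalue=1e-12), make_record("rsA", pvalue=1e-9)]
    ld = _ld_from_pairs([("t", "rsA", 0.9), ("t", "rsB", 0.9)])
    assert find_proxy("t", cands, ld, sel_cfg).snp_id == "rsB"


def test_proxy_matches_brute_force(sel_cfg, rng):
    cands = [make_record(f"rs{i:03d}", pvalue=float(rng.uniform(1e-12, 1e-8)))
             for i in range(20)]
    ld = LDReference()
    r2s = {}
    for c in cands:
        r2 = float(rng.uniform(0.5, 1.0))
        ld.add("t", c.snp_id, r2)
        r2s[c.snp_id] = r2
    got = find_proxy("t", cands, ld, sel_cfg)
    qualifying = [c for c in cands if r2s[c.snp_id] > sel_cfg.proxy_r2_min]
    expected = min(qualifying, key=lambda c: (-r2s[c.snp_id], c.pvalue, c.snp_id))
    assert got.snp_id == expected.snp_id


# --- trait-based exclusion ----------------------------------------------

def test_exclude_by_trait_rules():
    ivs = [make_record("rs1"), make_record("rs2"), make_record("rs3")]
    trait = [make_record("rs1", pvalue=1e-6), make_record("rs2", pvalue=1e-3)]
    kept, removed = exclude_by_trait(ivs, trait, 1e-5)
    assert [r.snp_id for r in removed] == ["rs1"]
    assert [r.snp_id for r in kept] == ["rs2", "rs3"]   # absent rs3 kept
    assert len(kept) + len(removed) == len(ivs)


def test_sequential_confounder_filters_match_brute_force(rng):
    ivs = [make_record(f"rs{i:03d}") for i in range(200)]
    conf1 = [make_record(f"rs{i:03d}", pvalue=float(rng.uniform(1e-8, 1e-2)))
             for i in rng.choice(200, 80, replace=False)]
    conf2 = [make_record(f"rs{i:03d}", pvalue=float(rng.uniform(1e-8, 1e-2)))
             for i in rng.choice(200, 80, replace=False)]
    kept = ivs
    for conf in (conf1, conf2):
        kept, _ = exclude_by_trait(kept, conf, 1e-5)
    bad = {r.snp_id for conf in (conf1, conf2) for r in conf if r.pvalue < 1e-5}
    assert {r.snp_id for r in kept} == {r.snp_id for r in ivs} - bad


# --- harmonization -------------------------------------------------------

def test_swapped_alleles_negate_outcome_beta(sel_cfg):
    exp = make_record("rs1", ea="A", oa="G", beta=0.05, eaf=0.3)
    out = make_record("rs1", ea="G", oa="A", beta=0.02, eaf=0.7)
    iv = harmonize_pair(exp, out, sel_cfg)
    assert iv.beta_out == -0.02
    assert iv.eaf_out == pytest.approx(0.3)
    assert "flipped" in iv.flags


def test_strand_complement_resolved(sel_cfg):
    exp = make_record("rs1", ea="A", oa="G", beta=0.05)
    out = make_record("rs1", ea="T", oa="C", beta=0.02)   # same variant, other strand
    iv = harmonize_pair(exp, out, sel_cfg)
    assert iv.beta_out == 0.02 and "flipped" not in iv.flags
    out2 = make_record("rs1", ea="C", oa="T", beta=0.02, eaf=0.7)
    iv2 = harmonize_pair(exp, out2, sel_cfg)
    assert iv2.beta_out == -0.02 and "flipped" in iv2.flags


def test_ambiguous_palindrome_dropped_at_maf_threshold(sel_cfg):
    exp = make_record("rs1", ea="A", oa="T", eaf=0.45)
    out = make_record("rs1", ea="A", oa="T", eaf=0.45)
    res = harmonize_pair(exp, out, sel_cfg)
    assert isinstance(res, DroppedIV) and res.reason == "ambiguous palindrome"


def test_alignable_palindrome_flipped_by_frequency(sel_cfg):
    exp = make_record("rs1", ea="A", oa="T", eaf=0.2, beta=0.05)
    # outcome reports the same labels but the frequency says other strand/allele
    out = make_record("rs1", ea="A", oa="T", eaf=0.8, beta=0.02)
    iv = harmonize_pair(exp, out, sel_cfg)
    assert iv.beta_out == -0.02
    assert {"flipped", "palindromic"} <= iv.flags


def test_non_concordant_alleles_dropped(sel_cfg):
    exp = make_record("rs1", ea="A", oa="G")
    out = make_record("rs1", ea="A", oa="C")
    res = harmonize_pair(exp, out, sel_cfg)
    assert isinstance(res, DroppedIV) and res.reason == "non-concordant"


def test_harmonization_idempotent_on_aligned_pair(sel_cfg):
    exp = make_record("rs1", ea="A", oa="G", beta=0.05, eaf=0.3)
    out = make_record("rs1", ea="A", oa="G", beta=0.02, eaf=0.3)
    iv = harmonize_pair(exp, out, sel_cfg)
    assert iv.beta_out == out.beta and iv.eaf_out == out.eaf and iv.flags == frozenset()


@given(beta=st.floats(-0.5, 0.5), eaf=st.floats(0.01, 0.99))
@settings(max_examples=50, deadline=None)
def test_double_flip_is_involution(beta, eaf):
    """Applying the allele-swap transform twice restores beta and EAF."""
    b1, f1 = -beta, 1.0 - eaf
    b2, f2 = -b1, 1.0 - f1
    assert b2 == beta and f2 == pytest.approx(eaf)


# --- full funnel ---------------------------------------------------------

def test_funnel_conserves_counts(sel_cfg):
    exposure, outcome, ld, _ = simulate.generate(simulate.SyntheticConfig(
        n_snp=200, gamma_sd=0.015, seed=9))
    ivs, rpt = harmonize_tables(exposure, outcome, ld, sel_cfg)
    c = rpt.stage_counts
    assert c["input"] == 200
    # each stage is a subset of the previous one
    stages = ["input", "significant", "clumped", "in_outcome",
              "outcome_pleiotropy_filtered", "confounder_filtered", "harmonized"]
    vals = [c[s] for s in stages]
    assert vals == sorted(vals, reverse=True)
    # harmonization stage conserves: harmonized + drops at that stage = input to it
    harm_drops = sum(1 for d in rpt.dropped
                     if d.reason in ("ambiguous palindrome", "non-concordant"))
    assert c["harmonized"] + harm_drops == c["confounder_filtered"]


def test_proxy_substitution_requires_exposure_record(sel_cfg):
    # index SNP rs1 absent from outcome; rs2 is in LD, present in both tables
    exposure = [make_record("rs1", pos=1000, pvalue=1e-10, beta=0.05),
                make_record("rs2", pos=2000, pvalue=1e-9, beta=0.04)]
    outcome = [make_record("rs2", pos=2000, beta=0.01, pvalue=0.5)]
    ld = _ld_from_pairs([("rs1", "rs2", 0.95)])
    cfg = SelectionConfig(clump_r2=0.999)  # keep both through clumping
    ivs, rpt = harmonize_tables(exposure, outcome, ld, cfg)
    by_id = {iv.snp_id: iv for iv in ivs}
    # rs2 appears once as itself; rs1 is replaced by proxy rs2 only if rs2
    # not already an index SNP — here rs2 IS an index SNP, so no proxy
    assert rpt.proxies == {}
    exposure2 = [make_record("rs1", pos=1000, pvalue=1e-10, beta=0.05),
                 make_record("rs2", pos=2000, pvalue=1e-3, beta=0.04)]
    ivs2, rpt2 = harmonize_tables(exposure2, outcome, ld, cfg)
    assert rpt2.proxies == {"rs1": "rs2"}
    assert ivs2[0].beta_exp == 0.04      # the proxy's own exposure effect
    assert "proxy" in ivs2[0].flags
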