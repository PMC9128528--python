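"""Instrument selection and allele harmonization.

Implements the standard funnel for building a two-sample MR instrument set
from exposure and outcome summary statistics:

1. genome-wide significance filter on the exposure associations;
2. greedy LD clumping (lowest p first) under an r-squared + distance rule;
3. proxy substitution for index SNPs absent from the outcome study;
4. exclusion of SNPs with suggestive association to the outcome or to
   known confounders (exclusion-restriction guard);
5. allele harmonization onto a shared effect allele, with palindromic
   variants aligned by allele frequency or dropped as ambiguous.

Every stage conserves counts: kept + removed/dropped = input, and
:func:`harmonize_tables` returns the full cascade for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .exceptions import ConfigError
from .sumstats import COMPLEMENT, HarmonizedIV, LDReference, SumstatRecord

__all__ = [
    "SelectionConfig",
    "DroppedIV",
    "FunnelReport",
    "select_significant",
    "clump",
    "find_proxy",
    "exclude_by_trait",
    "harmonize_pair",
    "harmonize_tables",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing the instrument-selection funnel.

    Defaults follow common two-sample MR practice with GWAS summary data:
    genome-wide significance 5e-8 for instruments, clumping at r2 < 0.001
    within a 10 kb window keeping the lowest p per locus, proxies at
    r2 > 0.8, suggestive-significance (1e-5) exclusion against the outcome
    and against confounder traits, and a 0.3 MAF ceiling for aligning
    palindromic variants by frequency.
    """

    p_exposure: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10.0
    p_outcome_exclude: float = 1e-5
    p_confounder_exclude: float = 1e-5
    proxy_r2_min: float = 0.8
    palindrome_maf_max: float = 0.3

    def __post_init__(self):
        for name in ("p_exposure", "clump_r2", "p_outcome_exclude",
                     "p_confounder_exclude", "proxy_r2_min", "palindrome_maf_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} = {v} must lie in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ConfigError(f"clump_window_kb = {self.clump_window_kb} must be positive")


@dataclass(frozen=True)
class DroppedIV:
    """A SNP dropped during harmonization, with a machine-readable reason."""

    snp_id: str
    reason: str


@dataclass
class FunnelReport:
    """Per-stage instrument counts plus itemized drops, for one trait."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    dropped: list[DroppedIV] = field(default_factory=list)
    proxies: dict[str, str] = field(default_factory=dict)   # original -> proxy snp_id

    def record(self, stage: str, count: int) -> None:
        self.stage_counts[stage] = count


def select_significant(records: Sequence[SumstatRecord], cfg: SelectionConfig) -> list[SumstatRecord]:
    """Keep records with exposure p-value below the significance cutoff (order preserved)."""
    return [r for r in records if r.pvalue < cfg.p_exposure]


def clump(records: Sequence[SumstatRecord], ld: LDReference, cfg: SelectionConfig) -> list[SumstatRecord]:
    """Greedy LD clumping: retain index SNPs by ascending p-value.

    Repeatedly takes the unprocessed record with the lowest p-value (ties
    broken by snp_id), retains it, and discards every unprocessed record on
    the same chromosome within ``clump_window_kb`` (inclusive) whose r2 with
    the retained SNP is >= ``clump_r2``. The returned set is mutually
    independent under the (r2, window) rule; output is in input order.
    """
    window_bp = cfg.clump_window_kb * 1000.0
    order = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    retained: list[SumstatRecord] = []
    discarded: set[str] = set()
    for i, rec in enumerate(order):
        if rec.snp_id in discarded:
            continue
        retained.append(rec)
        for other in order[i + 1:]:
            if other.snp_id in discarded or other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            if ld.r2(rec.snp_id, other.snp_id) >= cfg.clump_r2:
                discarded.add(other.snp_id)
    kept_ids = {r.snp_id for r in retained}
    return [r for r in records if r.snp_id in kept_ids]


def find_proxy(
    target: str,
    available: Sequence[SumstatRecord],
    ld: LDReference,
    cfg: SelectionConfig,
) -> SumstatRecord | None:
    """Best LD proxy for ``target`` among ``available`` records.

    Returns the record with maximal r2 to the target among those with
    r2 > ``proxy_r2_min``; ties broken by lower p-value then snp_id. None if
    no candidate qualifies.
    """
    best: SumstatRecord | None = None
    best_key: tuple[float, float, str] | None = None
    for rec in available:
        r2 = ld.r2(target, rec.snp_id)
        if r2 <= cfg.proxy_r2_min:
            continue
        key = (-r2, rec.pvalue, rec.snp_id)
        if best_key is None or key < best_key:
            best, best_key = rec, key
    return best


def exclude_by_trait(
    ivs: Sequence[SumstatRecord],
    trait_stats: Sequence[SumstatRecord] | Mapping[str, SumstatRecord],
    p_cut: float,
) -> tuple[list[SumstatRecord], list[SumstatRecord]]:
    """Partition instruments by association with another trait.

    A SNP is removed iff it appears in ``trait_stats`` with p-value below
    ``p_cut``; SNPs absent from the trait table are kept. Returns
    (kept, removed); the two lists partition the input.
    """
    if not isinstance(trait_stats, Mapping):
        trait_stats = {r.snp_id: r for r in trait_stats}
    kept: list[SumstatRecord] = []
    removed: list[SumstatRecord] = []
    for iv in ivs:
        hit = trait_stats.get(iv.snp_id)
        (removed if hit is not None and hit.pvalue < p_cut else kept).append(iv)
    return kept, removed


def _palindromic_pair(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def harmonize_pair(
    exp: SumstatRecord,
    out: SumstatRecord,
    cfg: SelectionConfig,
    extra_flags: Iterable[str] = (),
) -> HarmonizedIV | DroppedIV:
    """Align one exposure/outcome record pair onto the exposure's effect allele.

    Cases, in order:

    * identical alleles → passed through;
    * swapped alleles → outcome beta negated, outcome EAF complemented,
      flagged ``flipped``;
    * opposite-strand match → outcome alleles complemented first, then as above;
    * palindromic pair (A/T or C/G) → strand cannot be resolved from allele
      labels; aligned by allele frequency only when the MAF is below
      ``palindrome_maf_max`` in both studies, else dropped as an ambiguous
      palindrome;
    * anything else → dropped as non-concordant.
    """
    assert exp.snp_id == out.snp_id or "proxy" in set(extra_flags)
    flags = set(extra_flags)
    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele
    beta_out, eaf_out = out.beta, out.eaf

    def build() -> HarmonizedIV:
        return HarmonizedIV(
            snp_id=exp.snp_id,
            effect_allele=ea_e,
            other_allele=oa_e,
            eaf_exp=exp.eaf,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out.se,
            eaf_out=eaf_out,
            p_exp=exp.pvalue,
            p_out=out.pvalue,
            n_exp=exp.n,
            n_out=out.n,
            flags=frozenset(flags),
        )

    if _palindromic_pair(ea_e, oa_e):
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return DroppedIV(exp.snp_id, "non-concordant")
        flags.add("palindromic")
        if exp.maf >= cfg.palindrome_maf_max or out.maf >= cfg.palindrome_maf_max:
            return DroppedIV(exp.snp_id, "ambiguous palindrome")
        # nominal alignment by allele label, then frequency check: for a
        # palindrome a strand flip looks exactly like an allele swap, so the
        # label alignment can be wrong by one flip — EAF sidedness decides.
        if ea_o == oa_e:
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        if (exp.eaf < 0.5) != (eaf_out < 0.5):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            flags.add("flipped")
        return build()

    if (ea_o, oa_o) == (ea_e, oa_e):
        return build()
    if (ea_o, oa_o) == (oa_e, ea_e):
        beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        flags.add("flipped")
        return build()
    # opposite strand (non-palindromic, so unambiguous)
    comp = (COMPLEMENT[ea_o], COMPLEMENT[oa_o])
    if comp == (ea_e, oa_e):
        return build()
    if comp == (oa_e, ea_e):
        beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        flags.add("flipped")
        return build()
    return DroppedIV(exp.snp_id, "non-concordant")


def harmonize_tables(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    ld: LDReference,
    cfg: SelectionConfig,
    confounders: Sequence[Sequence[SumstatRecord]] = (),
    use_proxies: bool = True,
    report: FunnelReport | None = None,
) -> tuple[list[HarmonizedIV], FunnelReport]:
    """Run the full instrument-selection funnel for one exposure trait.

    Stages: significance filter → LD clumping → outcome lookup with optional
    proxy substitution → outcome-pleiotropy exclusion → confounder exclusion
    → allele harmonization. The report carries the per-stage counts and each
    dropped SNP's reason.

    A proxy is substituted only when the index SNP is absent from the outcome
    table AND the proxy has its own exposure record (the proxy's exposure
    association is never borrowed from the index SNP); the outcome-side
    record used is the proxy's.
    """
    rpt = report if report is not None else FunnelReport()
    rpt.record("input", len(exposure))

    sig = select_significant(exposure, cfg)
    rpt.record("significant", len(sig))

    clumped = clump(sig, ld, cfg)
    rpt.record("clumped", len(clumped))

    out_by_id = {r.snp_id: r for r in outcome}
    exp_by_id = {r.snp_id: r for r in exposure}
    clumped_ids = {r.snp_id for r in clumped}

    pairs: list[tuple[SumstatRecord, SumstatRecord, frozenset[str]]] = []
    for rec in clumped:
        if rec.snp_id in out_by_id:
            pairs.append((rec, out_by_id[rec.snp_id], frozenset()))
            continue
        if not use_proxies:
            rpt.dropped.append(DroppedIV(rec.snp_id, "absent from outcome"))
            continue
        candidates = [
            exp_by_id[s] for s in out_by_id
            if s in exp_by_id and s not in clumped_ids
        ]
        proxy = find_proxy(rec.snp_id, candidates, ld, cfg)
        if proxy is None:
            rpt.dropped.append(DroppedIV(rec.snp_id, "absent from outcome, no proxy"))
            continue
        rpt.proxies[rec.snp_id] = proxy.snp_id
        pairs.append((proxy, out_by_id[proxy.snp_id], frozenset({"proxy"})))
    rpt.record("in_outcome", len(pairs))

    kept_recs, removed = exclude_by_trait(
        [p[0] for p in pairs], [p[1] for p in pairs], cfg.p_outcome_exclude
    )
    rpt.dropped.extend(DroppedIV(r.snp_id, "outcome pleiotropy") for r in removed)
    kept_ids = {r.snp_id for r in kept_recs}
    pairs = [p for p in pairs if p[0].snp_id in kept_ids]
    rpt.record("outcome_pleiotropy_filtered", len(pairs))

    for i, conf in enumerate(confounders):
        kept_recs, removed = exclude_by_trait(
            [p[0] for p in pairs], conf, cfg.p_confounder_exclude
        )
        rpt.dropped.extend(DroppedIV(r.snp_id, f"confounder_{i}") for r in removed)
        kept_ids = {r.snp_id for r in kept_recs}
        pairs = [p for p in pairs if p[0].snp_id in kept_ids]
    rpt.record("confounder_filtered", len(pairs))

    ivs: list[HarmonizedIV] = []
    for exp_rec, out_rec, flags in pairs:
        res = harmonize_pair(exp_rec, out_rec, cfg, extra_flags=flags)
        if isinstance(res, DroppedIV):
            rpt.dropped.append(res)
        else:
            ivs.append(res)
    rpt.record("harmonized", len(ivs))
    return ivs, rpt
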