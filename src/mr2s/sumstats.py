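"""Reading, validating and writing GWAS summary statistics and related tables.

Three tabular formats are handled, all TSV with a header row:

* summary statistics — canonical columns ``snp, chr, pos, ea, oa, eaf, beta,
  se, p, n`` (one row per variant; ``beta`` is per SD of a continuous trait or
  a log odds ratio for a binary trait, on the effect allele ``ea``);
* pairwise LD — columns ``snp_a, snp_b, r2``;
* harmonized instrument tables — columns ``snp, ea, oa, eaf, beta_exp,
  se_exp, p_exp, beta_out, se_out, p_out, flags`` (the shape of the
  per-instrument tables typically deposited as study supplements).

Foreign column headers are supported through a ``dialect`` mapping from the
canonical names to the file's headers. Validation is total: every input row is
either returned as a record or reported in the rejection list with an explicit
reason, so row counts always reconcile.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import SumstatFormatError, SumstatValidationError

__all__ = [
    "SumstatRecord",
    "HarmonizedIV",
    "LDReference",
    "RejectedRow",
    "CANONICAL_COLUMNS",
    "VALID_ALLELES",
    "COMPLEMENT",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "read_harmonized",
    "write_harmonized",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the summary-statistics format
CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")

HARMONIZED_COLUMNS = (
    "snp", "ea", "oa", "eaf", "beta_exp", "se_exp", "p_exp",
    "beta_out", "se_out", "p_out", "flags",
)


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association summary for one trait.

    ``beta`` is oriented on ``effect_allele``; ``eaf`` is the effect-allele
    frequency. Positions are 1-based.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validation_errors(self) -> list[str]:
        """Reasons this record violates the format invariants (empty if valid)."""
        errs: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"effect allele {self.effect_allele!r} is not a single nucleotide")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"other allele {self.other_allele!r} is not a single nucleotide")
        if not errs and self.effect_allele == self.other_allele:
            errs.append("effect and other allele identical")
        if not (0.0 < self.eaf < 1.0):
            errs.append("eaf out of range")
        if not (self.se > 0.0) or math.isnan(self.se):
            errs.append("se not positive")
        if not (0.0 < self.pvalue <= 1.0):
            errs.append("pvalue out of range")
        if self.pos < 1:
            errs.append("position not positive")
        if self.n < 1:
            errs.append("sample size not positive")
        return errs

    @property
    def maf(self) -> float:
        """Minor-allele frequency."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedIV:
    """An exposure-outcome instrument pair expressed on one shared effect allele.

    Both ``beta_exp`` and ``beta_out`` refer to ``effect_allele``. ``flags``
    records what harmonization did: ``flipped`` (outcome effect re-oriented),
    ``palindromic`` (alignment relied on allele frequency), ``proxy`` (outcome
    association taken from an LD proxy).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf_exp: float
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    flags: frozenset[str] = frozenset()
    eaf_out: float | None = None
    p_exp: float | None = None
    p_out: float | None = None
    n_exp: int | None = None
    n_out: int | None = None

    def __post_init__(self):
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass
class RejectedRow:
    """A rejected input row together with the reasons for its rejection."""

    line: int           # 1-based line number in the source file (header = 1)
    snp_id: str
    reasons: list[str]


class LDReference:
    """Sparse pairwise LD (r-squared) lookup with optional positions.

    Symmetric by construction; self pairs are 1; absent pairs are 0 (treated
    as unlinked, which is conservative for clumping on sparse references).
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], float] | None = None,
        positions: Mapping[str, tuple[str, int]] | None = None,
    ):
        self._r2: dict[tuple[str, str], float] = {}
        self.positions: dict[str, tuple[str, int]] = dict(positions or {})
        for (a, b), r2 in (entries or {}).items():
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise SumstatValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self._r2[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        return self._r2.get(key, 0.0)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), r2 in sorted(self._r2.items()):
            yield a, b, r2

    def __len__(self) -> int:
        return len(self._r2)


def _resolve_columns(header: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, int]:
    dialect = dict(dialect or {})
    index: dict[str, int] = {}
    for canon in CANONICAL_COLUMNS:
        name = dialect.get(canon, canon)
        if name not in header:
            raise SumstatFormatError(f"required column {name!r} (field {canon!r}) missing from header")
        index[canon] = header.index(name)
    return index


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[SumstatRecord], list[RejectedRow]]:
    """Read a summary-statistics TSV.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        Mapping from canonical field names (``snp``, ``chr``, ...) to the
        file's column headers, for files with foreign headers.

    Returns
    -------
    (records, rejected):
        Validated records in file order, and the rows that violated the
        format invariants, each with its reasons. Alleles are upper-cased
        before validation.

    Raises
    ------
    SumstatFormatError
        if a required column is missing.
    SumstatValidationError
        if the same ``snp`` identifier appears on more than one accepted row.
    """
    path = Path(path)
    records: list[SumstatRecord] = []
    rejected: list[RejectedRow] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SumstatFormatError(f"{path}: empty file, no header")
        cols = _resolve_columns(header, dialect)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            snp_id = row[cols["snp"]].strip() if len(row) > cols["snp"] else ""
            try:
                rec = SumstatRecord(
                    snp_id=snp_id,
                    chrom=row[cols["chr"]].strip(),
                    pos=int(row[cols["pos"]]),
                    effect_allele=row[cols["ea"]].strip().upper(),
                    other_allele=row[cols["oa"]].strip().upper(),
                    eaf=float(row[cols["eaf"]]),
                    beta=float(row[cols["beta"]]),
                    se=float(row[cols["se"]]),
                    pvalue=float(row[cols["p"]]),
                    n=int(float(row[cols["n"]])),
                )
            except (ValueError, IndexError) as exc:
                rejected.append(RejectedRow(lineno, snp_id, [f"unparseable row: {exc}"]))
                continue
            errs = rec.validation_errors()
            if errs:
                rejected.append(RejectedRow(lineno, snp_id, errs))
            else:
                records.append(rec)
    seen: dict[str, int] = {}
    dups: list[str] = []
    for rec in records:
        seen[rec.snp_id] = seen.get(rec.snp_id, 0) + 1
    dups = sorted(s for s, c in seen.items() if c > 1)
    if dups:
        raise SumstatValidationError(f"duplicate snp identifiers: {', '.join(dups)}")
    return records, rejected


def write_sumstats(records: Iterable[SumstatRecord], path: str | Path) -> None:
    """Write records as a canonical summary-statistics TSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow([
                r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
                repr(r.eaf), repr(r.beta), repr(r.se), repr(r.pvalue), r.n,
            ])


def read_ld(path: str | Path) -> LDReference:
    """Read a three-column (snp_a, snp_b, r2) TSV into an :class:`LDReference`.

    The symmetric closure is applied and self pairs are forced to 1. An empty
    file yields an empty reference on which every query returns 0.
    """
    path = Path(path)
    ref = LDReference()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and row[0].strip().lower() in {"snp_a", "snpa"}:
                continue
            if len(row) < 3:
                raise SumstatFormatError(f"{path}:{lineno}: expected 3 columns snp_a, snp_b, r2")
            try:
                r2 = float(row[2])
            except ValueError as exc:
                raise SumstatFormatError(f"{path}:{lineno}: bad r2 value: {exc}")
            ref.add(row[0].strip(), row[1].strip(), r2)
    return ref


def write_ld(ref: LDReference, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_a", "snp_b", "r2"])
        for a, b, r2 in ref.pairs():
            writer.writerow([a, b, repr(r2)])


def write_harmonized(ivs: Iterable[HarmonizedIV], path: str | Path) -> None:
    """Write harmonized instruments in the supplementary-table TSV layout."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HARMONIZED_COLUMNS)
        for iv in ivs:
            writer.writerow([
                iv.snp_id, iv.effect_allele, iv.other_allele, repr(iv.eaf_exp),
                repr(iv.beta_exp), repr(iv.se_exp),
                "" if iv.p_exp is None else repr(iv.p_exp),
                repr(iv.beta_out), repr(iv.se_out),
                "" if iv.p_out is None else repr(iv.p_out),
                ";".join(sorted(iv.flags)),
            ])


def read_harmonized(path: str | Path) -> list[HarmonizedIV]:
    """Read a harmonized-instrument TSV (see :func:`write_harmonized`)."""
    path = Path(path)
    out: list[HarmonizedIV] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in HARMONIZED_COLUMNS if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise SumstatFormatError(f"harmonized table missing columns: {', '.join(missing)}")
        for row in reader:
            flags = frozenset(f for f in row["flags"].split(";") if f)
            out.append(HarmonizedIV(
                snp_id=row["snp"],
                effect_allele=row["ea"].upper(),
                other_allele=row["oa"].upper(),
                eaf_exp=float(row["eaf"]),
                beta_exp=float(row["beta_exp"]),
                se_exp=float(row["se_exp"]),
                beta_out=float(row["beta_out"]),
                se_out=float(row["se_out"]),
                p_exp=float(row["p_exp"]) if row.get("p_exp") else None,
                p_out=float(row["p_out"]) if row.get("p_out") else None,
                flags=flags,
            ))
    return out
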