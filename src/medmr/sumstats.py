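"""Reading, validation and allele harmonization of GWAS summary statistics.

Summary statistics arrive as delimited text with one row per SNP. Before
two-sample MR the exposure and outcome effects must refer to the same
effect allele; alleles reported on opposite strands are reconciled by
complementing, palindromic (A/T, C/G) variants — whose strand cannot be
resolved from the alleles alone — are dropped, and SNPs absent from the
outcome are dropped without proxy substitution.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

REQUIRED_ROLES = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ColumnMapError(ValueError):
    """A required column role is missing from the column map or the header."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association summary for one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    binary traits); ``eaf`` its frequency; ``n`` the GWAS sample size.
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

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.se > 0:
            problems.append(f"se must be > 0, got {self.se}")
        if not (0 < self.eaf < 1):
            problems.append(f"eaf must be in (0,1), got {self.eaf}")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not (0 < self.pvalue <= 1):
            problems.append(f"pvalue must be in (0,1], got {self.pvalue}")
        if self.n <= 0:
            problems.append(f"n must be positive, got {self.n}")
        if self.pos <= 0:
            problems.append(f"pos must be positive, got {self.pos}")
        return problems

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        a, b = self.effect_allele.upper(), self.other_allele.upper()
        return _COMPLEMENT.get(a) == b


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP, same effect allele.

    Carries the exposure-side alleles, position and EAF so downstream
    clumping, instrument-strength and Steiger computations need no second
    lookup, and so harmonization can be re-applied to its own output.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    eaf_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    pval_out: float
    n_out: int

    @property
    def ratio(self) -> float:
        """Per-SNP Wald ratio beta_out / beta_exp."""
        return self.beta_out / self.beta_exp


@dataclass(frozen=True)
class ExclusionEntry:
    snp_id: str
    stage: str
    detail: str = ""


EXCLUSION_STAGES = (
    "missing_in_outcome", "palindromic", "allele_mismatch",
    "maf", "p_exposure", "outcome_p", "ld_clump", "weak_instrument",
)


@dataclass
class ExclusionLog:
    """Per-SNP record of why variants left the pipeline, one stage each."""

    entries: list[ExclusionEntry] = field(default_factory=list)

    def add(self, snp_id: str, stage: str, detail: str = "") -> None:
        if stage not in EXCLUSION_STAGES:
            raise ValueError(f"unknown exclusion stage {stage!r}")
        if any(e.snp_id == snp_id and e.stage == stage for e in self.entries):
            raise ValueError(f"{snp_id} already excluded at stage {stage}")
        self.entries.append(ExclusionEntry(snp_id, stage, detail))

    def extend(self, other: "ExclusionLog") -> None:
        for e in other.entries:
            self.add(e.snp_id, e.stage, e.detail)

    def stage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.stage] = counts.get(e.stage, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.snp_id, e.stage, e.detail) for e in self.entries],
            columns=["snp_id", "stage", "detail"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RowIssue:
    """A data row that failed validation, reported rather than dropped silently."""

    line_number: int
    snp_id: str
    problems: tuple[str, ...]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[SummaryRecord], list[RowIssue]]:
    """Read delimited summary statistics into validated records.

    Parameters
    ----------
    path : delimited text file with a header row; ``.gz`` accepted.
    column_map : mapping from role (``snp_id``, ``beta``, ...) to the column
        name in the file. Roles whose name already matches may be omitted.
    sep : field delimiter; sniffed from the header (tab then comma) if None.

    Returns the list of valid records plus a list of :class:`RowIssue` for
    rows failing type or range validation.
    """
    column_map = dict(column_map or {})
    with _open_text(path) as fh:
        header_line = fh.readline()
    if sep is None:
        sep = "\t" if "\t" in header_line else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    for role in REQUIRED_ROLES:
        column_map.setdefault(role, role)
    missing = [r for r in REQUIRED_ROLES if column_map[r] not in df.columns]
    if missing:
        raise ColumnMapError(
            "missing required column(s) for role(s): "
            + ", ".join(f"{r} -> {column_map[r]!r}" for r in missing)
        )

    records: list[SummaryRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_number = i + 2  # header is line 1
        # itertuples mangles column names; index positionally instead
        vals = {role: row[df.columns.get_loc(column_map[role])] for role in REQUIRED_ROLES}
        snp_id = str(vals["snp_id"])
        try:
            rec = SummaryRecord(
                snp_id=snp_id,
                chrom=str(vals["chrom"]),
                pos=int(float(vals["pos"])),
                effect_allele=str(vals["effect_allele"]).upper(),
                other_allele=str(vals["other_allele"]).upper(),
                eaf=float(vals["eaf"]),
                beta=float(vals["beta"]),
                se=float(vals["se"]),
                pvalue=float(vals["pvalue"]),
                n=int(float(vals["n"])),
            )
        except (TypeError, ValueError) as exc:
            issues.append(RowIssue(line_number, snp_id, (f"unparseable value: {exc}",)))
            continue
        problems = rec.validate()
        if problems:
            issues.append(RowIssue(line_number, snp_id, tuple(problems)))
        else:
            records.append(rec)
    return records, issues


def write_sumstats(records: Iterable[SummaryRecord], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(path, sep=sep, index=False)


def _complemented(a: str) -> str | None:
    return _COMPLEMENT.get(a.upper())


def _key_by_id(records: Iterable[SummaryRecord], label: str) -> dict[str, SummaryRecord]:
    out: dict[str, SummaryRecord] = {}
    for r in records:
        if r.snp_id in out:
            raise ValueError(f"duplicated snp_id {r.snp_id!r} in {label} records")
        out[r.snp_id] = r
    return out


def harmonize(
    exposure: Iterable[SummaryRecord],
    outcome: Iterable[SummaryRecord],
    drop_palindromic: bool = True,
) -> tuple[list[HarmonizedPair], ExclusionLog]:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Outcome alleles reported in swapped order get their beta sign flipped;
    alleles on the opposite strand are complemented before comparison.
    Palindromic SNPs are removed when ``drop_palindromic`` (strand is
    unresolvable from alleles alone); SNPs missing from the outcome are
    excluded — no proxy lookup. Input SNP count equals pairs + exclusions.
    """
    exp_by_id = _key_by_id(exposure, "exposure")
    out_by_id = _key_by_id(outcome, "outcome")

    pairs: list[HarmonizedPair] = []
    log = ExclusionLog()
    for snp_id, e in exp_by_id.items():
        o = out_by_id.get(snp_id)
        if o is None:
            log.add(snp_id, "missing_in_outcome")
            continue
        if drop_palindromic and e.is_palindromic:
            log.add(snp_id, "palindromic", f"{e.effect_allele}/{e.other_allele}")
            continue

        ea, oa = e.effect_allele, e.other_allele
        o_ea, o_oa = o.effect_allele, o.other_allele
        flip: bool | None = None
        if (o_ea, o_oa) == (ea, oa):
            flip = False
        elif (o_ea, o_oa) == (oa, ea):
            flip = True
        else:
            c_ea, c_oa = _complemented(o_ea), _complemented(o_oa)
            if c_ea is not None and c_oa is not None:
                if (c_ea, c_oa) == (ea, oa):
                    flip = False
                elif (c_ea, c_oa) == (oa, ea):
                    flip = True
        if flip is None:
            log.add(
                snp_id, "allele_mismatch",
                f"exposure {ea}/{oa} vs outcome {o_ea}/{o_oa}",
            )
            continue

        pairs.append(HarmonizedPair(
            snp_id=snp_id,
            chrom=e.chrom,
            pos=e.pos,
            effect_allele=ea,
            other_allele=oa,
            beta_exp=e.beta, se_exp=e.se, pval_exp=e.pvalue,
            eaf_exp=e.eaf, n_exp=e.n,
            beta_out=-o.beta if flip else o.beta,
            se_out=o.se, pval_out=o.pvalue, n_out=o.n,
        ))
    return pairs, log


def pairs_to_records(pairs: Iterable[HarmonizedPair]) -> tuple[list[SummaryRecord], list[SummaryRecord]]:
    """Split harmonized pairs back into exposure and outcome record lists.

    Useful for re-harmonization (idempotence) and for feeding a pair set
    into record-based operations. Outcome EAF is not tracked in the pair;
    the exposure EAF is reused (EAFs are shared across aligned cohorts).
    """
    exp, out = [], []
    for p in pairs:
        exp.append(SummaryRecord(p.snp_id, p.chrom, p.pos, p.effect_allele, p.other_allele,
                                 p.eaf_exp, p.beta_exp, p.se_exp, p.pval_exp, p.n_exp))
        out.append(SummaryRecord(p.snp_id, p.chrom, p.pos, p.effect_allele, p.other_allele,
                                 p.eaf_exp, p.beta_out, p.se_out, p.pval_out, p.n_out))
    return exp, out
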