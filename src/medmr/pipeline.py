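"""Pipeline orchestration: per-trait MR, mediation table, multiple testing.

Significance follows the dual rule: an association is flagged when its raw
p-value is below ``alpha_raw`` (0.05) AND its Benjamini–Hochberg adjusted
p-value is below ``alpha_adjusted`` (0.10). BH families are the rows
adjusted together in one call — here, one (exposure-set × outcome) analysis
batch; the family definition is recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from medmr.estimators import MREstimate, ivw, mode_estimate, mr_egger, wald_ratio, weighted_median
from medmr.instruments import InstrumentCriteria, LDMatrix, select_instruments
from medmr.mediation import two_step_mediation
from medmr.sensitivity import sensitivity_report
from medmr.sumstats import ExclusionLog, HarmonizedPair, SummaryRecord, harmonize, read_sumstats

ALPHA_RAW = 0.05
ALPHA_ADJUSTED = 0.10


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_i = min over j >= i (rank order) of p_(j)·m/j, capped at 1.
    Inputs must be in (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class EstimatorSettings:
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0


def _estimates_for(pairs: Sequence[HarmonizedPair], settings: EstimatorSettings,
                   primary_only: bool = False) -> list[MREstimate]:
    """Wald ratio for a single instrument; the five-method battery otherwise.

    With exactly two instruments only IVW is computable among the
    multi-SNP methods (Egger/median/mode need >= 3). ``primary_only``
    stops after the headline estimate (Wald/IVW), the one mediation uses.
    """
    n = len(pairs)
    if n == 1:
        return [wald_ratio(pairs[0])]
    ests = [ivw(pairs, effects_model=settings.effects_model)]
    if n >= 3 and not primary_only:
        ests.append(mr_egger(pairs))
        ests.append(weighted_median(pairs, n_boot=settings.n_boot, seed=settings.seed))
        ests.append(mode_estimate(pairs, weighted=True, bandwidth_factor=settings.bandwidth_factor,
                                  n_boot=settings.n_boot, seed=settings.seed))
        ests.append(mode_estimate(pairs, weighted=False, bandwidth_factor=settings.bandwidth_factor,
                                  n_boot=settings.n_boot, seed=settings.seed))
    return ests


def estimates_frame(trait: str, estimates: Iterable[MREstimate]) -> pd.DataFrame:
    rows = [{
        "trait": trait,
        "method": e.method,
        "beta": e.beta,
        "se": e.se,
        "or": e.or_,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "pvalue": e.pvalue,
        "n_snp": e.n_snp,
    } for e in estimates]
    return pd.DataFrame(rows)


def add_significance(table: pd.DataFrame, alpha_raw: float = ALPHA_RAW,
                     alpha_adjusted: float = ALPHA_ADJUSTED,
                     family: Sequence[str] = ("method",)) -> pd.DataFrame:
    """Attach BH-adjusted p-values (within ``family`` groups) and the dual
    significance flag: raw p < alpha_raw AND adjusted p < alpha_adjusted."""
    table = table.copy()
    table["p_adjusted"] = np.nan
    fam_cols = [c for c in family if c in table.columns]
    groups = table.groupby(fam_cols).groups.values() if fam_cols else [table.index]
    for idx in groups:
        table.loc[idx, "p_adjusted"] = bh_adjust(table.loc[idx, "pvalue"].tolist())
    table["significant"] = (table["pvalue"] < alpha_raw) & (table["p_adjusted"] < alpha_adjusted)
    return table


def run_mr(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    settings: EstimatorSettings | None = None,
    trait: str = "exposure",
    drop_palindromic: bool = True,
    primary_only: bool = False,
) -> tuple[pd.DataFrame, dict, ExclusionLog]:
    """Harmonize, select instruments, estimate, and attach sensitivity suite.

    Returns the per-method estimates table, the sensitivity report dict,
    and the full exclusion log (harmonization + selection stages).
    Raises :class:`medmr.instruments.NoInstrumentsError` when selection
    empties the candidate set.
    """
    criteria = criteria or InstrumentCriteria()
    settings = settings or EstimatorSettings()
    pairs, log = harmonize(exposure, outcome, drop_palindromic=drop_palindromic)
    instruments, sel_log = select_instruments(pairs, criteria, ld=ld)
    log.extend(sel_log)
    estimates = _estimates_for(instruments, settings, primary_only=primary_only)
    table = estimates_frame(trait, estimates)
    report = (sensitivity_report(instruments)
              if len(instruments) >= 1 and not primary_only else {})
    report["n_instruments"] = len(instruments)
    report["exclusion_counts"] = log.stage_counts()
    return table, report, log


def primary_effect(table: pd.DataFrame) -> tuple[float, float, float]:
    """(beta, se, p) of the headline estimate: IVW when present, else Wald."""
    for method in ("ivw", "wald"):
        sub = table[table["method"] == method]
        if len(sub):
            row = sub.iloc[0]
            return float(row["beta"]), float(row["se"]), float(row["pvalue"])
    raise ValueError("no IVW or Wald estimate in table")


MEDIATION_COLUMNS = [
    "exposure", "mediator", "outcome", "total_effect", "direct_effect",
    "mediation_effect", "mediation_proportion_pct", "consistent", "reported",
]


def mediation_row(
    name_exposure: str, name_mediator: str, name_outcome: str,
    beta1: float, beta2: float, beta3: float,
    se1: float | None = None, se2: float | None = None,
) -> dict:
    res = two_step_mediation(beta1, beta2, beta3, se1=se1, se2=se2)
    return {
        "exposure": name_exposure,
        "mediator": name_mediator,
        "outcome": name_outcome,
        "total_effect": res.beta3,
        "direct_effect": res.direct_effect,
        "mediation_effect": res.mediation_effect,
        "mediation_proportion_pct": (None if res.proportion is None
                                     else res.proportion * 100.0),
        "consistent": res.consistent,
        "reported": res.consistent,
        "se_mediation": res.se_mediation,
    }


def run_mediation(
    exposure: Sequence[SummaryRecord],
    mediator: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    settings: EstimatorSettings | None = None,
    names: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
) -> dict:
    """Two-step mediation on three record sets.

    beta1 from exposure→mediator MR, beta2 from mediator→outcome MR (the
    mediator's own instruments), beta3 from exposure→outcome MR; then the
    product-of-coefficients decomposition. Returns one mediation table row.

    Two-step validity requires the mediator's instruments not to act
    through the exposure, so SNPs that qualify as exposure instruments
    (exposure p below the selection threshold) are removed from the
    mediator→outcome leg before selection.
    """
    criteria = criteria or InstrumentCriteria()
    p_exp = {r.snp_id: r.pvalue for r in exposure}
    mediator_own = [r for r in mediator
                    if p_exp.get(r.snp_id, 1.0) >= criteria.p_exposure_max]
    t1, _, _ = run_mr(exposure, mediator, criteria, ld, settings,
                      trait=names[0], primary_only=True)
    t2, _, _ = run_mr(mediator_own, outcome, criteria, ld, settings,
                      trait=names[1], primary_only=True)
    t3, _, _ = run_mr(exposure, outcome, criteria, ld, settings,
                      trait=names[0], primary_only=True)
    b1, s1, _ = primary_effect(t1)
    b2, s2, _ = primary_effect(t2)
    b3, _, _ = primary_effect(t3)
    return mediation_row(*names, beta1=b1, beta2=b2, beta3=b3, se1=s1, se2=s2)


# ---------------------------------------------------------------------------
# File-driven runs (YAML config)


@dataclass
class TraitSpec:
    path: str
    column_map: dict = dc_field(default_factory=dict)


@dataclass
class RunConfig:
    """Parsed YAML run configuration. See docs/methods.md for the schema."""

    seed: int
    traits: dict[str, TraitSpec]
    pathways: list[dict]
    criteria: InstrumentCriteria = dc_field(default_factory=InstrumentCriteria)
    estimator: EstimatorSettings = dc_field(default_factory=EstimatorSettings)
    ld_path: str | None = None
    alpha_raw: float = ALPHA_RAW
    alpha_adjusted: float = ALPHA_ADJUSTED

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        traits = {name: TraitSpec(**spec) for name, spec in raw.get("traits", {}).items()}
        crit = InstrumentCriteria(**raw.get("criteria", {}))
        est = EstimatorSettings(**{"seed": raw["seed"], **raw.get("estimator", {})})
        for pw in raw.get("pathways", []):
            for role in ("exposure", "mediator", "outcome"):
                if pw.get(role) not in traits:
                    raise ValueError(f"pathway references unknown trait {pw.get(role)!r}")
        return cls(
            seed=int(raw["seed"]),
            traits=traits,
            pathways=list(raw.get("pathways", [])),
            criteria=crit,
            estimator=est,
            ld_path=raw.get("ld"),
            alpha_raw=float(raw.get("alpha_raw", ALPHA_RAW)),
            alpha_adjusted=float(raw.get("alpha_adjusted", ALPHA_ADJUSTED)),
        )

    def load_trait(self, name: str) -> list[SummaryRecord]:
        spec = self.traits[name]
        records, issues = read_sumstats(spec.path, spec.column_map)
        if issues:
            import logging
            logging.getLogger(__name__).warning(
                "%d invalid rows in %s (first: line %d)", len(issues), spec.path,
                issues[0].line_number)
        return records

    def load_ld(self) -> LDMatrix:
        if self.ld_path is None:
            return LDMatrix.identity()
        return LDMatrix.from_file(self.ld_path)


def run_mediation_pipeline(config: RunConfig) -> pd.DataFrame:
    """All configured pathways → mediation table (one row each).

    Rows whose mediated and total effects disagree in sign are kept in the
    frame with ``reported = False`` (present in the log, absent from the
    reported table). Pathways whose MR legs fail are skipped with a log
    entry in the ``error`` column.
    """
    ld = config.load_ld()
    rows = []
    for pw in config.pathways:
        names = (pw["exposure"], pw["mediator"], pw["outcome"])
        try:
            row = run_mediation(
                config.load_trait(names[0]), config.load_trait(names[1]),
                config.load_trait(names[2]),
                criteria=config.criteria, ld=ld, settings=config.estimator,
                names=names,
            )
        except Exception as exc:  # pathway skipped, logged
            row = {"exposure": names[0], "mediator": names[1], "outcome": names[2],
                   "error": str(exc), "reported": False}
        rows.append(row)
    return pd.DataFrame(rows)


def reported_mediation_table(full: pd.DataFrame) -> pd.DataFrame:
    """The Table-3-style output: only sign-consistent, error-free rows."""
    mask = full.get("reported", pd.Series(False, index=full.index)).fillna(False)
    cols = [c for c in MEDIATION_COLUMNS if c in full.columns and c != "consistent"]
    return full.loc[mask.astype(bool), cols].reset_index(drop=True)
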