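"""Instrument selection for two-sample MR.

A SNP qualifies as an instrumental variable when it is strongly associated
with the exposure (genome-wide suggestive p < 5e-6 by default), common
(MAF >= 0.01), independent of other instruments (greedy LD clumping at
r^2 < 0.01 within a 10,000 kb window), not associated with the outcome
(configurable direction, see `outcome_p_policy`), and strong (F > 10).

Instrument strength uses the standard variance-explained formula

    R^2 = 2 EAF (1-EAF) beta^2 / (2 EAF (1-EAF) beta^2 + 2 EAF (1-EAF) N SE^2)

which simplifies to beta^2 / (beta^2 + N SE^2), and

    F = R^2 (N - 2) / (1 - R^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from medmr.sumstats import ExclusionLog, HarmonizedPair, SummaryRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstrumentCriteria:
    """Thresholds for the instrument-selection filters, in application order.

    ``outcome_p_policy``:
      * ``exclude_below`` (default) — drop SNPs *associated* with the outcome
        (outcome p < threshold), the confounding-minimising direction;
      * ``exclude_above`` — the literal printed rule (outcome p > threshold
        dropped);
      * ``off`` — no outcome-p filter.
    """

    p_exposure_max: float = 5e-6
    clump_r2: float = 0.01
    clump_window_kb: int = 10_000
    maf_min: float = 0.01
    outcome_p_policy: str = "exclude_below"
    outcome_p_threshold: float = 0.05
    f_min: float = 10.0

    def __post_init__(self):
        if self.outcome_p_policy not in ("exclude_below", "exclude_above", "off"):
            raise ValueError(f"unknown outcome_p_policy {self.outcome_p_policy!r}")
        for name in ("p_exposure_max", "clump_r2", "clump_window_kb",
                     "maf_min", "outcome_p_threshold", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.clump_r2 < 1):
            raise ValueError("clump_r2 must be in (0,1)")


@dataclass(frozen=True)
class InstrumentStrength:
    snp_id: str
    r2: float
    f_stat: float


class NoInstrumentsError(RuntimeError):
    """All candidate SNPs were filtered out; carries per-stage counts."""

    def __init__(self, stage_counts: dict[str, int]):
        self.stage_counts = dict(stage_counts)
        super().__init__(f"no instruments survive selection; exclusions: {self.stage_counts}")


def variance_explained(eaf: float, beta: float, se: float, n: float) -> float:
    """Fraction of exposure variance explained by one SNP.

    The 2·EAF·(1−EAF) factor appears in both numerator and denominator and
    cancels; it is kept in the expression for fidelity to the usual printed
    form. Requires n > 1.
    """
    if n <= 1:
        raise ValueError(f"sample size must exceed 1, got {n}")
    if not (0 < eaf < 1):
        raise ValueError(f"eaf must be in (0,1), got {eaf}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    k = 2.0 * eaf * (1.0 - eaf)
    return (k * beta * beta) / (k * beta * beta + k * n * se * se)


def f_statistic(r2: float, n: float) -> float:
    """Single-instrument F statistic, F = R²(N−2)/(1−R²)."""
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0,1), got {r2}")
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    return r2 * (n - 2.0) / (1.0 - r2)


def instrument_strength(rec_or_pair) -> InstrumentStrength:
    """R² and F for a SummaryRecord or the exposure side of a HarmonizedPair."""
    if isinstance(rec_or_pair, HarmonizedPair):
        r2 = variance_explained(rec_or_pair.eaf_exp, rec_or_pair.beta_exp,
                                rec_or_pair.se_exp, rec_or_pair.n_exp)
        return InstrumentStrength(rec_or_pair.snp_id, r2, f_statistic(r2, rec_or_pair.n_exp))
    r2 = variance_explained(rec_or_pair.eaf, rec_or_pair.beta, rec_or_pair.se, rec_or_pair.n)
    return InstrumentStrength(rec_or_pair.snp_id, r2, f_statistic(r2, rec_or_pair.n))


class LDMatrix:
    """Pairwise LD (r²) lookup; missing pairs default to 0.

    Built from a square matrix file (SNP IDs as header row and first
    column) or a three-column ``snp_a  snp_b  r2`` list; symmetric
    completion is applied either way.
    """

    def __init__(self, r2: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._missing_logged: set[tuple[str, str]] = set()
        for (a, b), v in (r2 or {}).items():
            self.set(a, b, v)

    def set(self, a: str, b: str, value: float) -> None:
        if not (0 <= value <= 1):
            raise ValueError(f"r2 must be in [0,1], got {value} for ({a},{b})")
        self._r2[(a, b)] = value
        self._r2[(b, a)] = value

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        v = self._r2.get((a, b))
        if v is None:
            key = (min(a, b), max(a, b))
            if key not in self._missing_logged:
                self._missing_logged.add(key)
                logger.debug("LD pair (%s, %s) missing; treated as r2=0", a, b)
            return 0.0
        return v

    @property
    def n_missing_lookups(self) -> int:
        return len(self._missing_logged)

    @classmethod
    def identity(cls) -> "LDMatrix":
        return cls()

    @classmethod
    def from_square(cls, df: pd.DataFrame) -> "LDMatrix":
        ld = cls()
        ids = list(df.columns)
        arr = df.to_numpy(dtype=float)
        if list(df.index) != ids:
            raise ValueError("square LD matrix must have identical row and column SNP IDs")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("square LD matrix must be symmetric")
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                ld.set(a, ids[j], float(arr[i, j]))
        return ld

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        head = pd.read_csv(path, sep=sep, nrows=1)
        if list(head.columns[:3]) == ["snp_a", "snp_b", "r2"] or len(head.columns) == 3:
            pairs = pd.read_csv(path, sep=sep)
            pairs.columns = ["snp_a", "snp_b", "r2"]
            ld = cls()
            for r in pairs.itertuples(index=False):
                ld.set(str(r.snp_a), str(r.snp_b), float(r.r2))
            return ld
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_square(df)

    @classmethod
    def from_array(cls, snp_ids: Sequence[str], arr: np.ndarray) -> "LDMatrix":
        return cls.from_square(pd.DataFrame(arr, index=list(snp_ids), columns=list(snp_ids)))


def _pos_key(item) -> tuple[str, int, float, str]:
    """(chrom, pos, exposure p, snp_id) regardless of record/pair type."""
    if isinstance(item, HarmonizedPair):
        return item.chrom, item.pos, item.pval_exp, item.snp_id
    return item.chrom, item.pos, item.pvalue, item.snp_id


def clump(
    records: Sequence[SummaryRecord] | Sequence[HarmonizedPair],
    ld: LDMatrix,
    r2_thresh: float = 0.01,
    window_kb: int = 10_000,
) -> tuple[list, ExclusionLog]:
    """Greedy LD clumping: one index SNP per correlated region.

    Candidates are visited by ascending exposure p (ties broken
    lexicographically by snp_id); each index SNP removes same-chromosome
    neighbours within ``window_kb`` kilobases whose r² with it is at or
    above ``r2_thresh``. Output order and content do not depend on the
    input row order.
    """
    order = sorted(records, key=lambda r: (_pos_key(r)[2], _pos_key(r)[3]))
    retained: list = []
    log = ExclusionLog()
    removed: set[str] = set()
    window_bp = window_kb * 1000
    for rec in order:
        chrom, pos, _, snp = _pos_key(rec)
        if snp in removed:
            continue
        retained.append(rec)
        for other in order:
            o_chrom, o_pos, _, o_snp = _pos_key(other)
            if o_snp == snp or o_snp in removed:
                continue
            if o_chrom != chrom or abs(o_pos - pos) > window_bp:
                continue
            if ld.get(snp, o_snp) >= r2_thresh:
                removed.add(o_snp)
                log.add(o_snp, "ld_clump", f"r2 with index {snp} >= {r2_thresh}")
    return retained, log


def select_instruments(
    pairs: Sequence[HarmonizedPair],
    criteria: InstrumentCriteria,
    ld: LDMatrix | None = None,
    strengths: dict[str, InstrumentStrength] | None = None,
) -> tuple[list[HarmonizedPair], ExclusionLog]:
    """Apply the instrument filters in order: exposure-p, MAF, LD clump,
    outcome-p policy, F-statistic.

    ``strengths`` may pre-supply per-SNP R²/F (keyed by snp_id); otherwise
    they are computed from the exposure side of each pair. Every excluded
    SNP carries exactly one stage label; retained + excluded = input.
    Raises :class:`NoInstrumentsError` if nothing survives.
    """
    ld = ld or LDMatrix.identity()
    log = ExclusionLog()

    stage1 = []
    for p in pairs:
        if p.pval_exp < criteria.p_exposure_max:
            stage1.append(p)
        else:
            log.add(p.snp_id, "p_exposure", f"p={p.pval_exp:.3g} >= {criteria.p_exposure_max:g}")

    stage2 = []
    for p in stage1:
        maf = min(p.eaf_exp, 1.0 - p.eaf_exp)
        if maf >= criteria.maf_min:
            stage2.append(p)
        else:
            log.add(p.snp_id, "maf", f"maf={maf:.4g} < {criteria.maf_min:g}")

    stage3, clump_log = clump(stage2, ld, criteria.clump_r2, criteria.clump_window_kb)
    log.extend(clump_log)

    stage4 = []
    for p in stage3:
        if criteria.outcome_p_policy == "off":
            keep = True
        elif criteria.outcome_p_policy == "exclude_below":
            keep = p.pval_out >= criteria.outcome_p_threshold
        else:  # exclude_above: paper-literal direction
            keep = p.pval_out <= criteria.outcome_p_threshold
        if keep:
            stage4.append(p)
        else:
            log.add(p.snp_id, "outcome_p",
                    f"p_out={p.pval_out:.3g} fails {criteria.outcome_p_policy} "
                    f"{criteria.outcome_p_threshold:g}")

    retained = []
    for p in stage4:
        s = (strengths or {}).get(p.snp_id) or instrument_strength(p)
        if s.f_stat > criteria.f_min:
            retained.append(p)
        else:
            log.add(p.snp_id, "weak_instrument", f"F={s.f_stat:.3g} <= {criteria.f_min:g}")

    if not retained:
        raise NoInstrumentsError(log.stage_counts())
    return retained, log
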