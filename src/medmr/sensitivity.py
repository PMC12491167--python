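"""Heterogeneity, pleiotropy, directionality and power diagnostics.

* Cochran's Q — excess dispersion of per-SNP ratios around the IVW (or
  Egger) fit; p < 0.05 flags heterogeneity.
* Leave-one-out — re-estimation dropping each instrument in turn, to spot
  single-SNP-driven results.
* Egger intercept — average directional pleiotropy (re-reported here from
  the Egger fit so the sensitivity report is one object).
* Steiger — compares exposure vs outcome variance explained by the
  instrument set; the causal direction is supported when the instruments
  explain more of the exposure.
* Power — noncentral-normal approximation for a binary outcome; taxa with
  power < 0.5 at the observed effect are conventionally set aside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from medmr.estimators import (
    InsufficientInstrumentsError,
    MREstimate,
    ivw,
    mr_egger,
)
from medmr.instruments import variance_explained
from medmr.sumstats import HarmonizedPair


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pvalue: float
    reference: str


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pvalue: float


@dataclass(frozen=True)
class LeaveOneOutRow:
    excluded_snp: str
    estimate: MREstimate


def cochran_q(pairs: Sequence[HarmonizedPair], reference: str = "ivw") -> HeterogeneityResult:
    """Q = sum over instruments of w_j (ratio_j − beta_hat)² with IVW weights.

    ``reference='ivw'`` uses the fixed-effect IVW estimate (df = n−1);
    ``'egger'`` uses residuals about the Egger fit (df = n−2).
    """
    n = len(pairs)
    if reference == "ivw":
        if n < 2:
            raise InsufficientInstrumentsError("Cochran's Q (IVW) needs >= 2 instruments")
        est = ivw(pairs, effects_model="fixed")
        q = est.extra["Q"]
        df = n - 1
    elif reference == "egger":
        if n < 3:
            raise InsufficientInstrumentsError("Cochran's Q (Egger) needs >= 3 instruments")
        est = mr_egger(pairs)
        q = est.extra["Q"]
        df = n - 2
    else:
        raise ValueError(f"unknown reference {reference!r}")
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(float(q), df, min(max(p, np.finfo(float).tiny), 1.0), reference)


def leave_one_out(
    pairs: Sequence[HarmonizedPair],
    estimator: Callable[[Sequence[HarmonizedPair]], MREstimate] = ivw,
) -> list[LeaveOneOutRow]:
    """Re-estimate on every (n−1)-subset; one row per excluded SNP."""
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    rows = []
    for i, p in enumerate(pairs):
        subset = list(pairs[:i]) + list(pairs[i + 1:])
        rows.append(LeaveOneOutRow(p.snp_id, estimator(subset)))
    return rows


def steiger(pairs: Sequence[HarmonizedPair]) -> SteigerResult:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-trait R² sums the single-SNP variance explained over instruments;
    the p-value compares the Fisher-transformed correlations sqrt(R²) at
    the two sample sizes. Ties resolve to ``correct_direction = False``
    with p = 1 (never asserted as reverse causation).
    """
    if not pairs:
        raise ValueError("steiger needs at least one instrument")
    for p in pairs:
        if p.n_exp <= 3 or p.n_out <= 3:
            raise ValueError("sample sizes must exceed 3 for the Steiger z-test")
    r2_exp = float(sum(variance_explained(p.eaf_exp, p.beta_exp, p.se_exp, p.n_exp)
                       for p in pairs))
    r2_out = float(sum(variance_explained(p.eaf_exp, p.beta_out, p.se_out, p.n_out)
                       for p in pairs))
    r2_exp, r2_out = min(r2_exp, 1 - 1e-12), min(r2_out, 1 - 1e-12)
    n_exp = min(p.n_exp for p in pairs)
    n_out = min(p.n_out for p in pairs)
    z_exp = math.atanh(math.sqrt(r2_exp))
    z_out = math.atanh(math.sqrt(r2_out))
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SteigerResult(r2_exp, r2_out, bool(r2_exp > r2_out), max(p, np.finfo(float).tiny))


def mr_power(n_outcome: int, case_fraction: float, r2_exposure: float,
             or_alternative: float, alpha: float = 0.05) -> float:
    """Approximate power of an MR test of a binary outcome.

    Noncentral-normal approximation: with noncentrality
    lambda = sqrt(n·R²·cf·(1−cf))·|ln OR|, power is the two-sided normal
    rejection probability. At OR = 1 this returns alpha exactly.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not (0 < case_fraction < 1):
        raise ValueError(f"case_fraction must be in (0,1), got {case_fraction}")
    if not (0 <= r2_exposure < 1):
        raise ValueError(f"r2_exposure must be in [0,1), got {r2_exposure}")
    if or_alternative <= 0:
        raise ValueError(f"or_alternative must be positive, got {or_alternative}")
    if n_outcome <= 0:
        raise ValueError("n_outcome must be positive")
    z_crit = stats.norm.isf(alpha / 2.0)
    lam = math.sqrt(n_outcome * r2_exposure * case_fraction * (1 - case_fraction)) \
        * abs(math.log(or_alternative))
    power = stats.norm.cdf(lam - z_crit) + stats.norm.cdf(-lam - z_crit)
    return float(min(max(power, 0.0), 1.0))


def sensitivity_report(
    pairs: Sequence[HarmonizedPair],
    n_outcome: int | None = None,
    case_fraction: float | None = None,
    or_alternative: float | None = None,
    alpha: float = 0.05,
) -> dict:
    """One-object sensitivity summary: Q, Egger intercept, Steiger, power.

    Power is reported only when the binary-outcome design values are given;
    the formula is a declared convention (see module docstring), not a
    published procedure.
    """
    report: dict = {}
    n = len(pairs)
    if n >= 2:
        q = cochran_q(pairs, "ivw")
        report.update(Q=q.q_stat, Q_df=q.df, Q_p=q.pvalue)
    if n >= 3:
        egger = mr_egger(pairs)
        report.update(egger_intercept=egger.extra["intercept"],
                      egger_intercept_se=egger.extra["intercept_se"],
                      egger_intercept_p=egger.extra["intercept_p"])
    st = steiger(pairs)
    report.update(steiger_direction=st.correct_direction, steiger_p=st.pvalue,
                  r2_exposure=st.r2_exposure, r2_outcome=st.r2_outcome)
    if None not in (n_outcome, case_fraction, or_alternative):
        report["power"] = mr_power(n_outcome, case_fraction, st.r2_exposure,
                                   or_alternative, alpha)
        report["power_formula"] = "noncentral-normal approximation (declared convention)"
    return report
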