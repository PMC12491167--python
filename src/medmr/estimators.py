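"""Causal-effect estimators for two-sample MR on harmonized instruments.

Each estimator combines per-SNP Wald ratios (outcome effect over exposure
effect) under different assumptions about pleiotropy:

* IVW — regression of outcome on exposure betas through the origin with
  1/se_out² weights; efficient but biased under directional pleiotropy.
* MR-Egger — same regression with a free intercept; the intercept estimates
  the average directional pleiotropic effect, the slope stays consistent
  under the InSIDE assumption.
* Weighted median — consistent when at least half of the total weight comes
  from valid instruments.
* Mode-based (simple/weighted) — the mode of the smoothed ratio density;
  consistent when the largest cluster of instruments is valid.

Ratio variances use the first-order delta approximation se_out²/beta_exp²
throughout (second-order available for the Wald ratio by flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from medmr.sumstats import HarmonizedPair

Z95 = 1.96


class InsufficientInstrumentsError(ValueError):
    """An estimator was given fewer instruments than it supports."""


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal-effect estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


def _two_sided_normal_p(z: float) -> float:
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return max(p, float(np.finfo(float).tiny))  # keep p in (0, 1]


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, by, sx, sy


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp.

    SE by the first-order delta method, se_out/|beta_exp|; with
    ``second_order`` the exposure-side noise term
    (beta_out²·se_exp²/beta_exp⁴) is added.
    """
    if pair.beta_exp == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    beta = pair.beta_out / pair.beta_exp
    var = pair.se_out ** 2 / pair.beta_exp ** 2
    if second_order:
        var += (pair.beta_out ** 2 * pair.se_exp ** 2) / pair.beta_exp ** 4
    se = math.sqrt(var)
    return MREstimate("wald", beta, se, _two_sided_normal_p(beta / se), 1)


def ivw(pairs: Sequence[HarmonizedPair], effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out²; algebraically the 1/var-weighted mean of per-SNP
    ratios with weights beta_exp²/se_out². Under the default multiplicative
    random-effects model the SE is inflated by max(1, sqrt(Q/(n−1))), never
    deflated below the fixed-effects SE.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    if len(pairs) < 1:
        raise InsufficientInstrumentsError("IVW needs at least 1 instrument")
    bx, by, _, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("beta_exp = 0 in instrument set")
    w = 1.0 / sy ** 2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    se = float(1.0 / math.sqrt(np.sum(w * bx * bx)))
    n = len(pairs)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if effects_model == "multiplicative_random" and n > 1:
        se *= max(1.0, math.sqrt(q / (n - 1)))
    return MREstimate("ivw", beta, se, _two_sided_normal_p(beta / se), n,
                      extra={"Q": q, "effects_model": effects_model})


def mr_egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Instruments are oriented so beta_exp >= 0 before fitting (the intercept
    is only meaningful in a fixed allele orientation). Slope and intercept
    p-values come from the t distribution on n−2 df; SEs follow the usual
    convention of never dropping below the fixed-effects SE
    (division by min(1, residual SD)).
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, by, _, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("beta_exp = 0 in instrument set")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    fit = sm.WLS(by, X, weights=w).fit()
    n = len(pairs)
    dof = n - 2
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    # statsmodels SEs carry the estimated residual scale; the multiplicative
    # random-effects convention never lets SEs fall below fixed-effects
    scale = float(fit.scale)
    inflate = 1.0 / math.sqrt(scale) if 0.0 < scale < 1.0 else 1.0
    tiny = np.finfo(float).tiny
    int_se = max(float(fit.bse[0]) * inflate, tiny)
    slope_se = max(float(fit.bse[1]) * inflate, tiny)
    slope_p = max(float(min(1.0, 2.0 * stats.t.sf(abs(slope / slope_se), dof))), tiny)
    int_p = max(float(min(1.0, 2.0 * stats.t.sf(abs(intercept / int_se), dof))), tiny)
    q = float(np.sum(w * (by - intercept - slope * bx) ** 2))
    return MREstimate("egger", slope, slope_se, slope_p, n,
                      extra={"intercept": intercept, "intercept_se": int_se,
                             "intercept_p": int_p, "Q": q})


def _ratio_weights(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    bx, by, _, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("beta_exp = 0 in instrument set")
    ratios = by / bx
    weights = bx ** 2 / sy ** 2  # 1 / first-order var of the ratio
    return ratios, weights


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cw = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = int(np.searchsorted(cw, 0.5, side="right")) - 1
    if below < 0:
        return float(r[0])
    if cw[below] == 0.5 or below == len(r) - 1:
        return float(r[below])
    frac = (0.5 - cw[below]) / (cw[below + 1] - cw[below])
    return float(r[below] + frac * (r[below + 1] - r[below]))


def _parametric_bootstrap_se(pairs, point_fn, n_boot, seed) -> float:
    """SE of a ratio-based statistic by resampling per-SNP effects from
    their sampling distributions."""
    bx, by, sx, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    n = len(bx)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        stats_[b] = point_fn(bys / bxs, bxs ** 2 / sy ** 2)
    return float(np.std(stats_, ddof=1))


def weighted_median(pairs: Sequence[HarmonizedPair], n_boot: int = 1000,
                    seed: int | None = 0) -> MREstimate:
    """Weighted median of per-SNP ratios (inverse-variance weights), linear
    interpolation at cumulative weight 0.5; SE by parametric bootstrap."""
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    if seed is None:
        raise ValueError("bootstrap seed is mandatory")
    ratios, weights = _ratio_weights(pairs)
    beta = _weighted_median(ratios, weights)
    se = _parametric_bootstrap_se(pairs, lambda r, w: _weighted_median(r, w), n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    return MREstimate("weighted_median", beta, se, _two_sided_normal_p(beta / se), len(pairs))


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Mode of the weighted, normal-kernel-smoothed ratio density.

    Bandwidth: modified Silverman rule 0.9·min(sd, mad)·n^(−1/5), scaled by
    ``bandwidth_factor``. Grid argmax; ties resolve to the lowest point.
    """
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = 0.9 * min(sd, mad) * len(ratios) ** (-1 / 5)
    h = bandwidth_factor * s
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: fall back to the weighted median of ratios
        return _weighted_median(ratios, weights)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(pairs: Sequence[HarmonizedPair], weighted: bool = True,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int | None = 0) -> MREstimate:
    """Mode-based estimate: the peak of the smoothed per-SNP ratio density.

    ``weighted`` applies inverse-variance weights to the kernel sum; the
    simple variant weights all ratios equally. SE by parametric bootstrap.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("mode estimator needs at least 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    if seed is None:
        raise ValueError("bootstrap seed is mandatory")
    ratios, ivw_w = _ratio_weights(pairs)
    point = lambda r, w: _kde_mode(r, w if weighted else np.ones_like(w), bandwidth_factor)
    beta = point(ratios, ivw_w)
    se = _parametric_bootstrap_se(pairs, point, n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, _two_sided_normal_p(beta / se), len(pairs))
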