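"""Synthetic GWAS summary statistics with a known causal structure.

The generator emulates three aligned summary-statistic sets — exposure
(e.g. a microbial taxon's abundance), mediator (e.g. IBD liability) and
outcome (e.g. CRC liability) — connected by the causal diagram

    exposure --b1--> mediator --b2--> outcome
        |____________ b_direct __________^

so the true total effect is beta3 = b_direct + b1*b2 and the true
proportion mediated is (b1*b2)/beta3.

Per SNP j (standardized genotypes):

* a fraction of SNPs instrument the exposure: gamma_j ~ N(0, gamma_sd²);
  their mediator effect is b1·gamma_j and their outcome effect
  (b_direct + b1·b2)·gamma_j;
* the remaining SNPs instrument the mediator directly: delta_j ~
  N(0, gamma_sd²), outcome effect b2·delta_j — without these the
  mediator→outcome leg of two-step MR would have no valid instruments;
* an optional ``pleiotropy_fraction`` of SNPs receives an extra direct
  outcome effect pi_j ~ N(0, pleiotropy_sd²), violating the exclusion
  restriction.

Observed effects are the true effects plus Normal noise with the standard
summary-statistic SE for a standardized trait, se = 1/sqrt(2·N·EAF·(1−EAF));
p-values are two-sided normal. EAFs are shared across the three cohorts.
Betas are interpreted as log-odds when a trait is binary; the sampling
model is unchanged (continuous-liability emulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from medmr.sumstats import SummaryRecord

_N_CHROM = 22
_POS_STEP = 100_000  # bp between adjacent simulated SNPs


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification; ``seed`` is mandatory.

    Defaults are the recovery design used throughout the test-suite:
    200 independent SNPs, cohorts of 100,000, b1 = 0.3, b2 = −0.2,
    b_direct = −0.5 and no pleiotropy, giving beta3 = −0.56 and a true
    proportion mediated of 3/28 ≈ 0.107. ``gamma_sd = 0.2`` keeps
    instruments strong enough (median F in the thousands) that regression
    dilution is negligible and nominal test calibration holds; see the
    methods note for the arithmetic behind that choice.
    """

    seed: int
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    gamma_sd: float = 0.2
    b1: float = 0.3
    b2: float = -0.2
    b_direct: float = -0.5
    pleiotropy_fraction: float = 0.0
    pleiotropy_sd: float = 0.05
    mediator_snp_fraction: float = 0.5
    ld_block_size: int = 1
    ld_within_block_r2: float = 0.0
    noiseless: bool = False  # n -> infinity limit: observed betas = truth

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        for frac in (self.pleiotropy_fraction, self.mediator_snp_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0,1]")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n <= 2:
                raise ValueError("sample sizes must exceed 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0 <= self.ld_within_block_r2 <= 1):
            raise ValueError("ld_within_block_r2 must be in [0,1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-SNP true effects and the implied mediation decomposition."""

    gamma: np.ndarray          # true SNP -> exposure effects
    delta: np.ndarray          # true direct SNP -> mediator effects
    pi: np.ndarray             # true direct SNP -> outcome (pleiotropic) effects
    beta_mediator: np.ndarray  # total SNP -> mediator effects
    beta_outcome: np.ndarray   # total SNP -> outcome effects
    b1: float
    b2: float
    b_direct: float

    @property
    def beta3(self) -> float:
        return self.b_direct + self.b1 * self.b2

    @property
    def proportion_mediated(self) -> float:
        return (self.b1 * self.b2) / self.beta3


_SNPS_PER_CHROM = 1000


def _snp_map(n_snps: int) -> tuple[list[str], list[str], list[int]]:
    """Deterministic SNP panel: contiguous chunks of SNPs per chromosome,
    100 kb apart, so LD-block neighbours share a chromosome."""
    ids = [f"rs{j + 1:07d}" for j in range(n_snps)]
    chroms, positions = [], []
    for j in range(n_snps):
        chroms.append(str(j // _SNPS_PER_CHROM % _N_CHROM + 1))
        positions.append((j % _SNPS_PER_CHROM + 1) * _POS_STEP)
    return ids, chroms, positions


def _observe(rng, truth: np.ndarray, se: np.ndarray, noiseless: bool) -> tuple[np.ndarray, np.ndarray]:
    from scipy import stats
    beta = truth.copy() if noiseless else rng.normal(truth, se)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, p


def _records(ids, chroms, positions, eaf, beta, se, pval, n) -> list[SummaryRecord]:
    return [
        SummaryRecord(ids[j], chroms[j], positions[j], "A", "G",
                      float(eaf[j]), float(beta[j]), float(se[j]),
                      float(pval[j]), int(n))
        for j in range(len(ids))
    ]


def simulate_sumstats(config: SimulationConfig) -> tuple[
        list[SummaryRecord], list[SummaryRecord], list[SummaryRecord], SyntheticTruth]:
    """Generate aligned exposure, mediator and outcome summary statistics.

    Deterministic for a fixed config (one master seed; per-trait noise
    streams drawn from independent child generators). Returns the three
    record lists plus the :class:`SyntheticTruth` sidecar.
    """
    master = np.random.default_rng(config.seed)
    rng_struct, rng_exp, rng_med, rng_out = master.spawn(4)

    n = config.n_snps
    ids, chroms, positions = _snp_map(n)
    eaf = rng_struct.uniform(*config.maf_range, size=n)

    n_med_snps = int(round(config.mediator_snp_fraction * n))
    is_mediator_snp = np.zeros(n, dtype=bool)
    if n_med_snps:
        is_mediator_snp[rng_struct.choice(n, size=n_med_snps, replace=False)] = True

    gamma = np.where(~is_mediator_snp, rng_struct.normal(0.0, config.gamma_sd, n), 0.0)
    delta = np.where(is_mediator_snp, rng_struct.normal(0.0, config.gamma_sd, n), 0.0)

    pi = np.zeros(n)
    n_pleio = int(round(config.pleiotropy_fraction * n))
    if n_pleio:
        idx = rng_struct.choice(n, size=n_pleio, replace=False)
        pi[idx] = rng_struct.normal(0.0, config.pleiotropy_sd, n_pleio)

    beta_med_true = config.b1 * gamma + delta
    beta_out_true = config.b_direct * gamma + config.b2 * beta_med_true + pi

    var_g = 2.0 * eaf * (1.0 - eaf)
    se_exp = 1.0 / np.sqrt(var_g * config.n_exposure)
    se_med = 1.0 / np.sqrt(var_g * config.n_mediator)
    se_out = 1.0 / np.sqrt(var_g * config.n_outcome)

    b_exp, p_exp = _observe(rng_exp, gamma, se_exp, config.noiseless)
    b_med, p_med = _observe(rng_med, beta_med_true, se_med, config.noiseless)
    b_out, p_out = _observe(rng_out, beta_out_true, se_out, config.noiseless)

    exposure = _records(ids, chroms, positions, eaf, b_exp, se_exp, p_exp, config.n_exposure)
    mediator = _records(ids, chroms, positions, eaf, b_med, se_med, p_med, config.n_mediator)
    outcome = _records(ids, chroms, positions, eaf, b_out, se_out, p_out, config.n_outcome)

    truth = SyntheticTruth(gamma, delta, pi, beta_med_true, beta_out_true,
                           config.b1, config.b2, config.b_direct)
    return exposure, mediator, outcome, truth


def simulate_ld(config: SimulationConfig) -> pd.DataFrame:
    """Block-diagonal LD (r²) matrix matching the simulated SNP panel.

    ``ld_within_block_r2`` within consecutive blocks of ``ld_block_size``
    SNPs, zero between blocks, unit diagonal; symmetric by construction.
    Blocks never span the chromosome boundaries of the simulated map.
    """
    n = config.n_snps
    ids, chroms, _ = _snp_map(n)
    arr = np.eye(n)
    for start in range(0, n, config.ld_block_size):
        stop = min(start + config.ld_block_size, n)
        for i in range(start, stop):
            for j in range(i + 1, stop):
                if chroms[i] == chroms[j]:
                    arr[i, j] = arr[j, i] = config.ld_within_block_r2
    return pd.DataFrame(arr, index=ids, columns=ids)


def truth_frame(truth: SyntheticTruth, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Truth sidecar as a table (one row per SNP plus the implied effects
    in the attrs)."""
    df = pd.DataFrame({
        "snp_id": list(snp_ids),
        "gamma": truth.gamma,
        "delta": truth.delta,
        "pi": truth.pi,
        "beta_mediator_true": truth.beta_mediator,
        "beta_outcome_true": truth.beta_outcome,
    })
    df.attrs.update(b1=truth.b1, b2=truth.b2, b_direct=truth.b_direct,
                    beta3=truth.beta3, proportion_mediated=truth.proportion_mediated)
    return df


def simulate_eqtl_region(
    seed: int,
    n_snps: int = 30,
    gene_id: str = "GENE1",
    b_smr: float = 0.0,
    beta_eqtl_top: float = 0.5,
    se_eqtl: float = 0.02,
    se_gwas: float = 0.01,
    ld_r2: float = 0.3,
    linkage: bool = False,
) -> tuple[str, list, pd.DataFrame]:
    """Small cis-region generator for SMR/HEIDI testing.

    Under the single-causal-variant model (``linkage=False``) every SNP's
    GWAS effect equals ``b_smr`` times its eQTL effect, so HEIDI sees a
    homogeneous region. With ``linkage=True`` half of the SNPs tag an
    independent GWAS signal (b_smr doubled), the heterogeneous alternative.
    Returns ``(gene_id, [CisSNP...], square LD r² DataFrame)``.
    """
    from scipy import stats

    from medmr.smr import CisSNP

    rng = np.random.default_rng(seed)
    ids = [f"cis{j + 1:03d}" for j in range(n_snps)]
    # eQTL effects taper away from the top SNP but stay well-powered
    eqtl_true = beta_eqtl_top * rng.uniform(0.5, 1.0, n_snps)
    eqtl_true[0] = beta_eqtl_top
    slopes = np.full(n_snps, b_smr)
    if linkage:
        slopes[n_snps // 2:] = 2.0 * b_smr if b_smr != 0 else 1.0
    gwas_true = slopes * eqtl_true

    # sampling noise correlated across SNPs as LD implies (r = sqrt(r2))
    r = np.sqrt(ld_r2)
    corr = np.full((n_snps, n_snps), r)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    beta_eqtl = eqtl_true + se_eqtl * (chol @ rng.standard_normal(n_snps))
    beta_gwas = gwas_true + se_gwas * (chol @ rng.standard_normal(n_snps))
    p_eqtl = np.clip(2.0 * stats.norm.sf(np.abs(beta_eqtl / se_eqtl)),
                     np.finfo(float).tiny, 1.0)
    snps = [CisSNP(ids[j], float(beta_eqtl[j]), se_eqtl, float(p_eqtl[j]),
                   float(beta_gwas[j]), se_gwas) for j in range(n_snps)]
    arr = np.full((n_snps, n_snps), ld_r2)
    np.fill_diagonal(arr, 1.0)
    ld = pd.DataFrame(arr, index=ids, columns=ids)
    return gene_id, snps, ld
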