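"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR estimates the effect of gene expression on an outcome from a single
top cis-eQTL: b_SMR = beta_GWAS / beta_eQTL, tested with

    T_SMR = z_GWAS² · z_eQTL² / (z_GWAS² + z_eQTL²)  ~  chi²(1),

and se_SMR = |b_SMR| / sqrt(T_SMR). A small SMR p-value is consistent with
either a shared causal variant (pleiotropy/causality) or distinct variants
in LD (linkage). HEIDI separates the two: if a single variant drives both
traits, every cis SNP in LD with the top SNP must imply the same b_SMR, so
the differences d_j = b_SMR(j) − b_SMR(top) are jointly zero up to sampling
noise. HEIDI tests the quadratic form of standardized d against its null —
a weighted sum of chi²(1) variables whose weights are eigenvalues of the
correlation matrix of d — with the tail evaluated by Imhof's method.

Decision rule for a robust, potentially causal gene: p_SMR < 0.10 AND
p_HEIDI > 0.05 (heterogeneity NOT detected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from medmr.instruments import LDMatrix


@dataclass(frozen=True)
class CisSNP:
    """eQTL and (harmonized) GWAS effects for one cis SNP of one gene."""

    snp_id: str
    beta_eqtl: float
    se_eqtl: float
    pval_eqtl: float
    beta_gwas: float
    se_gwas: float

    @property
    def z_eqtl(self) -> float:
        return self.beta_eqtl / self.se_eqtl

    @property
    def z_gwas(self) -> float:
        return self.beta_gwas / self.se_gwas

    @property
    def b_smr(self) -> float:
        return self.beta_gwas / self.beta_eqtl


@dataclass
class SMRResult:
    gene_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0
    passes: bool = False
    reason: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.b_smr)


def smr_test(z_eqtl: float, z_gwas: float, beta_eqtl: float, beta_gwas: float
             ) -> tuple[float, float, float]:
    """SMR effect, SE and p-value from the top cis-eQTL.

    Returns ``(b_smr, se_smr, p_smr)``. The statistic is capped by the
    weaker of the two z-scores (harmonic structure), so an instrument that
    is weak on either side cannot yield a strong SMR signal.
    """
    if z_eqtl == 0:
        raise ValueError("z_eqtl must be nonzero")
    if beta_eqtl == 0:
        raise ValueError("beta_eqtl must be nonzero")
    b = beta_gwas / beta_eqtl
    z2e, z2g = z_eqtl * z_eqtl, z_gwas * z_gwas
    t_smr = z2g * z2e / (z2g + z2e)
    p = float(stats.chi2.sf(t_smr, 1)) if t_smr > 0 else 1.0
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    se = abs(b) / math.sqrt(t_smr) if t_smr > 0 else math.inf
    return float(b), float(se), p


def _imhof_sf(x: float, lam: np.ndarray) -> float:
    """P(Q > x) for Q = sum lam_i * chi2_1 by Imhof's (1961) inversion.

    Accurate for the small dimensions HEIDI uses (<= ~20 eigenvalues);
    falls back to the Satterthwaite two-moment chi-square match if the
    quadrature fails to converge.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return math.sin(theta) / (u * rho)

    try:
        # the integrand decays like u^(-1-m/2); full_output silences the
        # subdivision warning on the oscillatory tail
        out = integrate.quad(integrand, 0.0, np.inf, limit=500, full_output=1)
        val, err = out[0], out[1]
        p = 0.5 + val / math.pi
        if not np.isfinite(p) or err > 1e-4:
            raise RuntimeError
    except Exception:
        s1, s2 = float(np.sum(lam)), float(np.sum(lam ** 2))
        scale, dof = s2 / s1, s1 * s1 / s2
        p = float(stats.chi2.sf(x / scale, dof))
    return float(min(max(p, 0.0), 1.0))


def heidi_test(
    cis_snps: Sequence[CisSNP],
    ld: LDMatrix,
    top_snp: str | None = None,
    min_snps: int = 3,
    max_snps: int = 20,
    eqtl_p_max: float = 1.57e-3,
    ld_r2_range: tuple[float, float] = (0.05, 0.9),
) -> tuple[float | None, int]:
    """Heterogeneity-in-dependent-instruments test around the top cis-eQTL.

    Candidate SNPs must pass the eQTL significance window (``eqtl_p_max``)
    and sit in intermediate LD with the top SNP (``ld_r2_range``); at most
    ``max_snps`` strongest-eQTL candidates are used. With fewer than
    ``min_snps`` eligible SNPs the test is undefined: returns
    ``(None, n_eligible)``.

    The statistic sums squared standardized differences d_j between each
    candidate's b_SMR and the top SNP's; its covariance combines LD-induced
    correlation of the GWAS and eQTL effects with the shared top-SNP term
    (first-order delta method). LD is supplied as r²; the signed correlation
    is taken as +sqrt(r²), a documented approximation.
    """
    by_id = {s.snp_id: s for s in cis_snps}
    if len(by_id) != len(cis_snps):
        raise ValueError("duplicated snp_id in cis_snps")
    if top_snp is None:
        top_snp = min(cis_snps, key=lambda s: (s.pval_eqtl, s.snp_id)).snp_id
    top = by_id[top_snp]

    candidates = [
        s for s in cis_snps
        if s.snp_id != top_snp
        and s.pval_eqtl < eqtl_p_max
        and ld_r2_range[0] <= ld.get(top_snp, s.snp_id) <= ld_r2_range[1]
    ]
    candidates.sort(key=lambda s: (s.pval_eqtl, s.snp_id))
    candidates = candidates[:max_snps]
    m = len(candidates)
    if m < min_snps:
        return None, m

    def r(a: CisSNP, b: CisSNP) -> float:
        return math.sqrt(ld.get(a.snp_id, b.snp_id))

    def cov_b(a: CisSNP, b: CisSNP) -> float:
        """First-order covariance of b_smr(a), b_smr(b)."""
        rr = 1.0 if a.snp_id == b.snp_id else r(a, b)
        gwas_term = rr * a.se_gwas * b.se_gwas
        eqtl_term = rr * a.b_smr * b.b_smr * a.se_eqtl * b.se_eqtl
        return (gwas_term + eqtl_term) / (a.beta_eqtl * b.beta_eqtl)

    d = np.array([s.b_smr - top.b_smr for s in candidates])
    V = np.empty((m, m))
    var_top = cov_b(top, top)
    for i, si in enumerate(candidates):
        for j in range(i, m):
            sj = candidates[j]
            V[i, j] = V[j, i] = (
                cov_b(si, sj) - cov_b(si, top) - cov_b(sj, top) + var_top
            )
    sd = np.sqrt(np.diag(V))
    if np.any(sd <= 0):
        raise ValueError("non-positive variance of b_smr difference; check inputs")
    z = d / sd
    R = V / np.outer(sd, sd)
    t_heidi = float(np.sum(z * z))
    lam = np.linalg.eigvalsh(R)
    p = _imhof_sf(t_heidi, lam)
    return min(max(p, float(np.finfo(float).tiny)), 1.0), m


def smr_gene(
    gene_id: str,
    cis_snps: Sequence[CisSNP],
    ld: LDMatrix,
    **heidi_kwargs,
) -> SMRResult:
    """Full per-gene SMR + HEIDI: top-eQTL selection, SMR test, HEIDI test."""
    if not cis_snps:
        raise ValueError("no cis SNPs supplied")
    top = min(cis_snps, key=lambda s: (s.pval_eqtl, s.snp_id))
    b, se, p = smr_test(top.z_eqtl, top.z_gwas, top.beta_eqtl, top.beta_gwas)
    p_heidi, n_used = heidi_test(cis_snps, ld, top_snp=top.snp_id, **heidi_kwargs)
    res = SMRResult(gene_id, top.snp_id, b, se, p, p_heidi, n_used)
    return apply_decision_rule([res])[0]


def apply_decision_rule(results: Sequence[SMRResult],
                        p_smr_max: float = 0.10,
                        p_heidi_min: float = 0.05) -> list[SMRResult]:
    """Flag genes with robust, potentially causal associations:
    p_SMR < 0.10 and p_HEIDI > 0.05. An undefined HEIDI p fails with reason."""
    out = []
    for r in results:
        if r.p_heidi is None:
            passes, reason = False, "HEIDI undefined (too few eligible cis SNPs)"
        elif r.p_smr < p_smr_max and r.p_heidi > p_heidi_min:
            passes, reason = True, ""
        else:
            passes = False
            reason = ("p_smr >= threshold" if r.p_smr >= p_smr_max else "p_heidi <= threshold")
        out.append(SMRResult(r.gene_id, r.top_snp, r.b_smr, r.se_smr, r.p_smr,
                             r.p_heidi, r.n_heidi_snps, passes, reason, dict(r.extra)))
    return out
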