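"""Two-step MR mediation decomposition via the product of coefficients.

With β1 the exposure→mediator effect, β2 the mediator→outcome effect and
β3 the total exposure→outcome effect (all on the log-odds scale for binary
traits), the mediated (indirect) effect is β1·β2, the direct effect is
β3 − β1·β2, and the proportion mediated is (β1·β2)/β3. A decomposition is
reported only when the mediated effect and the total effect share a sign;
inconsistent rows are flagged, never silently altered.

When an upstream estimate arrives as an odds ratio, take β1 = ln(OR) before
calling in here — the arithmetic lives entirely on the coefficient scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MediationResult:
    beta1: float
    beta2: float
    beta3: float
    mediation_effect: float
    direct_effect: float
    proportion: float | None  # None when beta3 == 0 (undefined)
    consistent: bool
    se_mediation: float | None = None

    @property
    def proportion_pct(self) -> str:
        """Proportion mediated formatted as a percentage with 3 decimals."""
        if self.proportion is None:
            return "undefined"
        return f"{self.proportion * 100:.3f}%"


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def two_step_mediation(beta1: float, beta2: float, beta3: float,
                       se1: float | None = None, se2: float | None = None) -> MediationResult:
    """Decompose a total effect into mediated and direct components.

    Exact arithmetic: mediation = beta1*beta2; direct = beta3 − mediation;
    proportion = mediation/beta3 (None when beta3 is zero — no exception).
    ``consistent`` is True when the mediated effect has the same sign as
    the total effect; results failing this rule are flagged for suppression
    from reported tables but the numbers are untouched. Optional SEs yield
    a first-order delta SE for the product.
    """
    mediation = beta1 * beta2
    direct = beta3 - mediation
    proportion = None if beta3 == 0 else mediation / beta3
    consistent = _sign(mediation) == _sign(beta3) and beta3 != 0
    se_med = None
    if se1 is not None and se2 is not None:
        se_med = mediation_se_delta(beta1, se1, beta2, se2)
    return MediationResult(beta1, beta2, beta3, mediation, direct, proportion,
                           consistent, se_med)


def mediation_se_delta(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """First-order delta-method SE of the product beta1·beta2:
    sqrt(beta2²·se1² + beta1²·se2²)."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    return math.sqrt(beta2 * beta2 * se1 * se1 + beta1 * beta1 * se2 * se2)
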