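"""Drug-target MR with correlated instruments in a gene region.

Variants within a drug's target gene (HMGCR for statins, NPC1L1 for
ezetimibe, PCSK9 for PCSK9 inhibitors) proxy pharmacological modulation
of the exposure, but lie close together and are in linkage
disequilibrium, so the independent-instrument IVW understates the
information overlap.  The generalized IVW here performs weighted least
squares of Γ on γ without intercept under the correlated error
covariance Ω_jk = se(Γ_j)·se(Γ_k)·ρ_jk, where ρ is the signed LD
correlation aligned to the harmonized effect alleles.  Pairs with
r² ≥ 0.3 are warned about but retained — the correlation is modeled, not
pruned.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .harmonize import AnalysisError, HarmonizedSet
from .io import AssocRecord, LDMatrix
from .univariate import MREstimate

DEFAULT_R2_CEILING = 0.3
RIDGE_START = 1e-6
RIDGE_MAX = 1e-3


class SingularLDError(np.linalg.LinAlgError):
    """Ω not invertible even after ridge escalation; prune the region."""


def restrict_to_region(
    records: Sequence[AssocRecord], region_variants: Sequence[str]
) -> tuple[list[AssocRecord], list[str]]:
    """Subset records to a gene region's variant list, order preserved.

    Returns (subset, missing_ids); an empty subset is an analysis error.
    """
    wanted = set(region_variants)
    subset = [r for r in records if r.variant_id in wanted]
    present = {r.variant_id for r in subset}
    missing = [v for v in region_variants if v not in present]
    if not subset:
        raise AnalysisError("no region variants present in the summary table")
    return subset, missing


def check_correlation_ceiling(
    ld: LDMatrix, r2_max: float = DEFAULT_R2_CEILING
) -> list[str]:
    """One warning message per variant pair with r² ≥ ``r2_max``."""
    warnings_out = []
    J = len(ld.variant_ids)
    for i in range(J):
        for j in range(i + 1, J):
            r2 = ld.r[i, j] ** 2
            if r2 >= r2_max:
                warnings_out.append(
                    f"{ld.variant_ids[i]}–{ld.variant_ids[j]}: r²={r2:.3f} ≥ {r2_max}"
                )
    return warnings_out


def _inv_factor(omega: np.ndarray) -> tuple[tuple, float]:
    """Cholesky factor of Ω, ridging the diagonal only when needed.

    A well-conditioned Ω is factored untouched (so the identity-LD case
    reduces to the ordinary IVW exactly); otherwise a ridge of 1e-6 of
    the diagonal is added, escalating tenfold up to 1e-3.
    """
    d2 = np.diag(omega).copy()
    for ridge in (0.0, RIDGE_START, RIDGE_START * 10, RIDGE_START * 100, RIDGE_MAX):
        try:
            return linalg.cho_factor(omega + np.diag(d2) * ridge), ridge
        except np.linalg.LinAlgError:
            continue
    raise SingularLDError(
        "LD covariance not positive definite after ridge adjustment; "
        "prune highly correlated variants"
    )


def correlated_ivw(h: HarmonizedSet, ld: LDMatrix) -> MREstimate:
    """Generalized (LD-aware) random-effects IVW for correlated instruments.

    β̂ = (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ with Ω_jk = se(Γ_j)·se(Γ_k)·ρ_jk; the SE
    √((γᵀΩ⁻¹γ)⁻¹) is scaled by max(1, √(Q/(J−1))) where
    Q = (Γ−β̂γ)ᵀΩ⁻¹(Γ−β̂γ) is the GLS heterogeneity statistic (χ², J−1
    df).  With ρ = I this reduces exactly to the univariate IVW.  A small
    ridge (1e-6, escalating tenfold to at most 1e-3) is added to the
    correlation diagonal when Ω is not positive definite; the ridge used
    is recorded in ``extras``.
    """
    rho = ld.subset(h.variant_ids).r
    omega = np.outer(h.se_Gamma, h.se_Gamma) * rho
    factor, ridge = _inv_factor(omega)
    J = h.n_snps
    oi_g = linalg.cho_solve(factor, h.gamma)
    oi_G = linalg.cho_solve(factor, h.Gamma)
    gtg = float(h.gamma @ oi_g)
    beta = float(h.gamma @ oi_G) / gtg
    se_fixed = math.sqrt(1.0 / gtg)
    resid = h.Gamma - beta * h.gamma
    Q = float(resid @ linalg.cho_solve(factor, resid))
    q_p = float(stats.chi2.sf(Q, J - 1)) if J > 1 else float("nan")
    scale = max(1.0, math.sqrt(Q / (J - 1))) if J > 1 else 1.0
    return MREstimate(
        "Correlated IVW",
        beta,
        se_fixed * scale,
        J,
        exposure=h.exposure_id,
        outcome=h.outcome_id,
        extras={"Q": Q, "Q_pval": q_p, "Q_df": J - 1, "ridge": ridge},
    )


class RegionalMR:
    """Gene-region MR model: harmonized regional instruments plus their LD matrix.

    ``RegionalMR(harmonized, ld).fit()`` returns the LD-aware IVW
    estimate; :meth:`correlation_warnings` reports pairs above the r²
    ceiling (retained, not pruned).
    """

    def __init__(self, data: HarmonizedSet, ld: LDMatrix):
        self.data = data
        self.ld = ld

    def fit(self) -> MREstimate:
        return correlated_ivw(self.data, self.ld)

    def correlation_warnings(self, r2_max: float = DEFAULT_R2_CEILING) -> list[str]:
        return check_correlation_ceiling(self.ld.subset(self.data.variant_ids), r2_max)
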