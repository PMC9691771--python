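"""Multivariable IVW MR: direct effects of several exposures jointly.

When instruments associate with more than one exposure (e.g. the lipid
fractions and BMI), the univariate estimate conflates direct and mediated
paths.  Multivariable MR regresses the SNP-outcome effects on the full
J×K matrix of SNP-exposure effects (no intercept, weights 1/se(Γ_j)²),
so each coefficient β_k is the effect of exposure k conditional on the
others.  The instrument set is the union of each exposure's instruments,
every variant harmonized to a common effect-allele frame against the
outcome; the per-exposure "number of SNPs" reported is the count of that
exposure's own genome-wide-significant instruments surviving
harmonization, matching how multi-exposure results tables are usually
annotated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .harmonize import AnalysisError, DEFAULT_MAF_LIMIT, harmonize_pair
from .io import AssocRecord
from .univariate import MREstimate


class CollinearityError(np.linalg.LinAlgError):
    """Exposure-effect matrix is rank deficient."""


@dataclass
class MVMRInput:
    """J instruments × K exposures design for multivariable IVW."""

    variant_ids: list[str]
    G: np.ndarray  # J×K exposure betas γ_jk
    se_G: np.ndarray  # J×K
    Gamma: np.ndarray  # J outcome betas
    se_Gamma: np.ndarray
    exposure_ids: list[str]
    n_snps_per_exposure: dict[str, int] = field(default_factory=dict)
    audit: list[tuple[str, str, str]] = field(default_factory=list)
    outcome_id: str = ""

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.se_G = np.atleast_2d(np.asarray(self.se_G, dtype=float))
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_Gamma = np.asarray(self.se_Gamma, dtype=float)
        J, K = self.G.shape
        if len(self.variant_ids) != J or self.Gamma.size != J:
            raise ValueError("inconsistent instrument dimension")
        if len(self.exposure_ids) != K:
            raise ValueError("inconsistent exposure dimension")
        if np.any(np.all(self.G == 0, axis=0)):
            raise ValueError("an exposure column is identically zero")

    @property
    def J(self) -> int:
        return self.G.shape[0]

    @property
    def K(self) -> int:
        return self.G.shape[1]


def build_mvmr_input(
    instrument_sets: Mapping[str, Sequence[AssocRecord]],
    exposure_tables: Mapping[str, Sequence[AssocRecord]],
    outcome_table: Sequence[AssocRecord],
    maf_limit: float = DEFAULT_MAF_LIMIT,
) -> MVMRInput:
    """Assemble the multivariable design from per-exposure instrument lists.

    The instrument set is the union (de-duplicated on variant ID) of the
    per-exposure instruments.  Every instrument must be present in all K
    exposure tables and the outcome table; variants missing anywhere, or
    failing harmonization against the outcome, are dropped with an audit
    entry.  Each exposure's association is re-expressed on the frame of
    the variant's outcome-harmonized effect allele.
    """
    exposure_ids = list(instrument_sets.keys())
    lookup = {
        eid: {r.variant_id: r for r in exposure_tables[eid]} for eid in exposure_ids
    }
    out_by_id = {r.variant_id: r for r in outcome_table}

    union: list[tuple[str, str]] = []  # (variant_id, source exposure)
    seen: set[str] = set()
    for eid in exposure_ids:
        for rec in instrument_sets[eid]:
            if rec.variant_id not in seen:
                seen.add(rec.variant_id)
                union.append((rec.variant_id, eid))

    audit: list[tuple[str, str, str]] = []
    rows: list[tuple[str, str, list[AssocRecord], AssocRecord]] = []
    for vid, source in union:
        missing = [eid for eid in exposure_ids if vid not in lookup[eid]]
        if vid not in out_by_id:
            audit.append((vid, "dropped", "not in outcome"))
            continue
        if missing:
            audit.append((vid, "dropped", f"not in exposure table(s): {','.join(missing)}"))
            continue
        # harmonize the outcome against the source exposure's coding
        anchor = lookup[source][vid]
        action, reason, out_adj = harmonize_pair(anchor, out_by_id[vid], maf_limit)
        if action == "dropped":
            audit.append((vid, "dropped", reason))
            continue
        # re-express every exposure on the anchor's effect allele
        exp_row = []
        ok = True
        for eid in exposure_ids:
            rec = lookup[eid][vid]
            a, _, adj = harmonize_pair(anchor, rec, maf_limit)
            if a == "dropped":
                audit.append((vid, "dropped", f"allele mismatch across exposures ({eid})"))
                ok = False
                break
            exp_row.append(adj)
        if not ok:
            continue
        audit.append((vid, action, reason))
        rows.append((vid, source, exp_row, out_adj))

    K = len(exposure_ids)
    if len(rows) <= K:
        raise AnalysisError(
            f"multivariable MR needs more instruments ({len(rows)}) than exposures ({K})"
        )
    n_per = {eid: 0 for eid in exposure_ids}
    for _, source, _, _ in rows:
        n_per[source] += 1
    return MVMRInput(
        variant_ids=[vid for vid, _, _, _ in rows],
        G=np.array([[r.beta for r in exp_row] for _, _, exp_row, _ in rows]),
        se_G=np.array([[r.se for r in exp_row] for _, _, exp_row, _ in rows]),
        Gamma=np.array([out.beta for _, _, _, out in rows]),
        se_Gamma=np.array([out.se for _, _, _, out in rows]),
        exposure_ids=exposure_ids,
        n_snps_per_exposure=n_per,
        audit=audit,
        outcome_id=outcome_table[0].trait_id if outcome_table else "",
    )


def mvmr_ivw(m: MVMRInput) -> list[MREstimate]:
    """Multivariable IVW: weighted least squares Γ_j = Σ_k β_k γ_jk, no intercept.

    Weights 1/se(Γ_j)²; SEs use the multiplicative random-effects scale
    max(1, √(RSS_w/(J−K))).  One estimate per exposure; with K=1 this is
    algebraically the univariate IVW.
    """
    J, K = m.J, m.K
    w = 1.0 / m.se_Gamma**2
    XtW = m.G.T * w
    xtwx = XtW @ m.G
    rank = np.linalg.matrix_rank(xtwx)
    if rank < K:
        # point at the collinear columns via the null space
        _, _, vt = np.linalg.svd(m.G * np.sqrt(w)[:, None])
        null_vec = np.abs(vt[-1])
        offenders = [m.exposure_ids[k] for k in np.flatnonzero(null_vec > 1e-8)]
        raise CollinearityError(
            f"collinear exposure effects: {', '.join(offenders)}"
        )
    xtwx_inv = np.linalg.inv(xtwx)
    coef = xtwx_inv @ (XtW @ m.Gamma)
    resid = m.Gamma - m.G @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (J - K))) if J > K else 1.0
    ses = np.sqrt(np.diag(xtwx_inv)) * scale
    estimates = []
    for k, eid in enumerate(m.exposure_ids):
        beta, se = float(coef[k]), float(ses[k])
        estimates.append(
            MREstimate(
                "Multivariable IVW",
                beta,
                se,
                m.n_snps_per_exposure.get(eid, J),
                exposure=eid,
                outcome=m.outcome_id,
                extras={"J_total": J, "K": K, "rss_w": rss_w},
            )
        )
    return estimates


class MultivariableMR:
    """Model front end for multivariable IVW.

    Construct from an :class:`MVMRInput` (or via
    :meth:`from_tables`, which assembles and harmonizes the design);
    ``fit()`` returns one :class:`~causalmr.univariate.MREstimate` per
    exposure.
    """

    def __init__(self, data: MVMRInput):
        self.data = data

    @classmethod
    def from_tables(
        cls,
        instrument_sets: Mapping[str, Sequence[AssocRecord]],
        exposure_tables: Mapping[str, Sequence[AssocRecord]],
        outcome_table: Sequence[AssocRecord],
        maf_limit: float = DEFAULT_MAF_LIMIT,
    ) -> "MultivariableMR":
        return cls(build_mvmr_input(instrument_sets, exposure_tables, outcome_table, maf_limit))

    def fit(self) -> list[MREstimate]:
        return mvmr_ivw(self.data)
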