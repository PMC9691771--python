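"""Instrument selection and exposure/outcome allele harmonization.

Instruments are genome-wide-significant variants (P < 5e-8 by default)
pruned to near-independence (pairwise r² < 0.001) by greedy clumping on
ascending p-value.  Harmonization re-expresses every outcome association
on the exposure's effect allele, resolving strand flips by complementing
alleles and palindromic (A/T, C/G) variants by allele-frequency
concordance; palindromic variants with intermediate frequency (MAF ≥ 0.3
on either side, or missing frequency) are unresolvable and dropped.
Every input variant receives exactly one audit entry (kept / flipped /
dropped with a reason).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AssocRecord, LDMatrix

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.001
DEFAULT_MAF_LIMIT = 0.3


class AnalysisError(RuntimeError):
    """Unrecoverable analysis-level failure (e.g. no overlapping variants)."""


@dataclass
class HarmonizedSet:
    """Aligned per-variant exposure/outcome effect pairs with an audit trail.

    gamma/se_gamma are the SNP-exposure effects γ_j and their SEs;
    Gamma/se_Gamma the SNP-outcome effects Γ_j, all expressed on the same
    effect allele per variant.
    """

    variant_ids: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    eaf_exposure: np.ndarray  # NaN where missing
    audit: list[tuple[str, str, str]] = field(default_factory=list)
    n_exposure: float | None = None
    n_outcome: float | None = None
    exposure_id: str = ""
    outcome_id: str = ""

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_gamma = np.asarray(self.se_gamma, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_Gamma = np.asarray(self.se_Gamma, dtype=float)
        self.eaf_exposure = np.asarray(self.eaf_exposure, dtype=float)
        lengths = {
            len(self.variant_ids),
            self.gamma.size,
            self.se_gamma.size,
            self.Gamma.size,
            self.se_Gamma.size,
            self.eaf_exposure.size,
        }
        if len(lengths) != 1:
            raise ValueError("harmonized vectors have inconsistent lengths")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HarmonizedSet(
            variant_ids=[self.variant_ids[i] for i in keep],
            gamma=self.gamma[keep],
            se_gamma=self.se_gamma[keep],
            Gamma=self.Gamma[keep],
            se_Gamma=self.se_Gamma[keep],
            eaf_exposure=self.eaf_exposure[keep],
            audit=list(self.audit),
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
        )

    def drop_variants(self, variant_ids: Sequence[str]) -> "HarmonizedSet":
        drop = set(variant_ids)
        keep = [i for i, v in enumerate(self.variant_ids) if v not in drop]
        return self.subset(keep)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.audit, columns=["variant_id", "action", "reason"])


def select_instruments(
    records: Sequence[AssocRecord],
    ld: LDMatrix | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[AssocRecord]:
    """Greedy LD clumping of genome-wide-significant variants.

    Sort by ascending p; retain a variant iff its r² with every
    already-retained variant is below ``r2_threshold``.  Without an LD
    matrix the records are assumed pre-pruned and only the p filter
    applies.
    """
    significant = [r for r in records if r.pval < p_threshold]
    if ld is None:
        return significant
    index = {v: i for i, v in enumerate(ld.variant_ids)}
    missing = [r.variant_id for r in significant if r.variant_id not in index]
    if missing:
        raise KeyError(f"variants missing from LD matrix: {missing}")
    retained: list[AssocRecord] = []
    for rec in sorted(significant, key=lambda r: r.pval):
        i = index[rec.variant_id]
        if all(ld.r[i, index[k.variant_id]] ** 2 < r2_threshold for k in retained):
            retained.append(rec)
    return retained


def is_palindromic(a1: str, a2: str) -> bool:
    """A variant whose alleles are strand-complementary (A/T or C/G)."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _complemented(rec: AssocRecord) -> AssocRecord:
    import dataclasses

    return dataclasses.replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )


def _maf(eaf: float | None) -> float | None:
    if eaf is None:
        return None
    return min(eaf, 1.0 - eaf)


def harmonize_pair(
    exp: AssocRecord,
    out: AssocRecord,
    maf_limit: float = DEFAULT_MAF_LIMIT,
) -> tuple[str, str, AssocRecord | None]:
    """Align one outcome record to the exposure's effect allele.

    Returns ``(action, reason, adjusted_outcome)`` where action is one of
    ``kept``, ``flipped``, ``dropped``.  Non-palindromic variants are
    matched directly, after an effect/other swap (sign flip), or after a
    strand complement.  Palindromic variants are ambiguous between a swap
    and a strand flip, so allele labels are aligned nominally and then the
    strand is verified by frequency concordance; with MAF ≥ ``maf_limit``
    (strictly: a MAF of exactly the limit drops) or a missing frequency on
    either side the strand cannot be verified and the variant is dropped.
    """
    if exp.variant_id != out.variant_id:
        raise ValueError("harmonize_pair requires matching variant IDs")
    e1, e2 = exp.effect_allele, exp.other_allele
    palindromic = is_palindromic(e1, e2)

    def nominal_align(o: AssocRecord) -> tuple[str, AssocRecord] | None:
        if (o.effect_allele, o.other_allele) == (e1, e2):
            return "kept", o
        if (o.effect_allele, o.other_allele) == (e2, e1):
            return "flipped", o.flipped()
        return None

    if not palindromic:
        aligned = nominal_align(out)
        if aligned is None and is_palindromic(out.effect_allele, out.other_allele):
            return "dropped", "allele mismatch", None
        if aligned is None:
            aligned = nominal_align(_complemented(out))
        if aligned is None:
            return "dropped", "allele mismatch", None
        action, adj = aligned
        return action, "strand/swap alignment" if action == "flipped" else "", adj

    # palindromic: nominal label alignment first, then frequency check
    aligned = nominal_align(out)
    if aligned is None:
        return "dropped", "allele mismatch", None
    action, adj = aligned
    maf_e, maf_o = _maf(exp.eaf), _maf(adj.eaf)
    if maf_e is None or maf_o is None:
        return "dropped", "palindromic, missing allele frequency", None
    if maf_e >= maf_limit or maf_o >= maf_limit:
        return "dropped", "palindromic, intermediate frequency", None
    if (exp.eaf - 0.5) * (adj.eaf - 0.5) < 0:
        # frequencies disagree about the minor allele: strand flip hidden
        # behind the palindrome; undo by flipping the outcome effect again
        adj = adj.flipped()
        import dataclasses

        adj = dataclasses.replace(adj, effect_allele=e1, other_allele=e2)
        action = "flipped"
    return action, "palindromic, frequency aligned" if action == "flipped" else "", adj


def harmonize_sets(
    exposure: Sequence[AssocRecord],
    outcome: Sequence[AssocRecord],
    maf_limit: float = DEFAULT_MAF_LIMIT,
) -> HarmonizedSet:
    """Intersect exposure and outcome records on variant ID and align alleles.

    Exposure variants absent from the outcome table are audited as
    dropped ("not in outcome").  An empty intersection is an analysis
    error.  Duplicate IDs keep the first occurrence.
    """
    out_by_id: dict[str, AssocRecord] = {}
    for rec in outcome:
        out_by_id.setdefault(rec.variant_id, rec)
    seen: set[str] = set()
    audit: list[tuple[str, str, str]] = []
    kept_rows: list[tuple[AssocRecord, AssocRecord]] = []
    n_intersection = 0
    for rec in exposure:
        if rec.variant_id in seen:
            continue
        seen.add(rec.variant_id)
        out_rec = out_by_id.get(rec.variant_id)
        if out_rec is None:
            audit.append((rec.variant_id, "dropped", "not in outcome"))
            continue
        n_intersection += 1
        action, reason, adj = harmonize_pair(rec, out_rec, maf_limit=maf_limit)
        audit.append((rec.variant_id, action, reason))
        if action != "dropped":
            kept_rows.append((rec, adj))
    if n_intersection == 0:
        raise AnalysisError("no overlapping variants between exposure and outcome")
    if not kept_rows:
        raise AnalysisError("all overlapping variants dropped during harmonization")
    exp_recs, out_recs = zip(*kept_rows)
    return HarmonizedSet(
        variant_ids=[r.variant_id for r in exp_recs],
        gamma=np.array([r.beta for r in exp_recs]),
        se_gamma=np.array([r.se for r in exp_recs]),
        Gamma=np.array([r.beta for r in out_recs]),
        se_Gamma=np.array([r.se for r in out_recs]),
        eaf_exposure=np.array(
            [np.nan if r.eaf is None else r.eaf for r in exp_recs]
        ),
        audit=audit,
        n_exposure=float(np.median([r.n for r in exp_recs])) if exp_recs else None,
        n_outcome=float(np.median([r.n for r in out_recs])) if out_recs else None,
        exposure_id=exp_recs[0].trait_id,
        outcome_id=out_recs[0].trait_id,
    )
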