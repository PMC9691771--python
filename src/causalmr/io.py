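"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

The tabular dialect is tab-separated with a mandatory header; missing
values are encoded as ``NA`` or the empty string.  Alleles are restricted
to single nucleotides (A/C/G/T): the instruments used throughout are SNPs,
and indels are rejected with an audited reason rather than silently
dropped.  LD matrices store *signed* correlations r (not r²) aligned to
the listed effect alleles, because the generalized IVW covariance for
correlated instruments requires the sign.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the summary-table dialect
SUMMARY_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


class FormatError(ValueError):
    """Malformed input file (missing columns, non-square matrix, ...)."""


@dataclass(frozen=True)
class AssocRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: SD units for a
    continuous trait, log odds ratio for a binary one.  ``eaf`` is the
    effect-allele frequency and may be missing (``None``); ``n`` is the
    GWAS sample size and ``n_cases`` the number of cases when the trait is
    binary.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float
    trait_id: str = ""
    n_cases: float | None = None

    def validate(self) -> list[str]:
        """Return hard invariant violations (empty list if the record is valid)."""
        problems = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            problems.append("non-SNP variant")
        elif self.effect_allele == self.other_allele:
            problems.append("identical alleles")
        if not (self.se > 0) or not math.isfinite(self.se):
            problems.append("nonpositive SE")
        if not math.isfinite(self.beta):
            problems.append("non-finite beta")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            problems.append("eaf outside (0,1)")
        if not (0.0 < self.pval <= 1.0):
            problems.append("pval outside (0,1]")
        if not (self.n > 0):
            problems.append("nonpositive sample size")
        return problems

    def pval_consistent(self, tol_orders: float = 1.0) -> bool:
        """Check |beta/se| against the reported p within ``tol_orders`` orders of magnitude."""
        if self.se <= 0:
            return False
        z = abs(self.beta / self.se)
        p_implied = 2.0 * stats.norm.sf(z)
        if p_implied <= 1e-290 or self.pval <= 1e-290:
            # at or beyond float resolution for the normal tail; cannot compare
            return True
        return abs(math.log10(p_implied) - math.log10(self.pval)) <= tol_orders

    def flipped(self) -> "AssocRecord":
        """The same association expressed with the allele roles swapped."""
        return dataclasses.replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class LDMatrix:
    """Signed variant-by-variant correlation matrix aligned to effect alleles."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise FormatError("LD matrix must be square")
        if len(self.variant_ids) != self.r.shape[0]:
            raise FormatError("LD matrix dimension does not match variant list")

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise KeyError(f"variants absent from LD matrix: {missing}")
        idx = [index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        i = self.variant_ids.index(a)
        j = self.variant_ids.index(b)
        return float(self.r[i, j] ** 2)


@dataclass
class ReadResult:
    """Outcome of reading a summary table: accepted records plus a rejection audit."""

    records: list[AssocRecord]
    rejections: pd.DataFrame  # columns: row, variant_id, reason
    warnings: list[str] = field(default_factory=list)


def _parse_float(token: str) -> float | None:
    token = token.strip()
    if token == "" or token.upper() == "NA":
        return None
    return float(token)


def read_gwas_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
) -> ReadResult:
    """Read a tab-separated GWAS summary table into validated records.

    ``column_map`` maps the dialect's field names (``variant_id``,
    ``effect_allele``, ...) to the file's header names; identity by
    default.  Rows violating record invariants are collected in the
    rejection report with a reason, never silently dropped.  A p-value
    inconsistent with |beta/se| by more than one order of magnitude raises
    a warning (the record is still accepted).
    """
    path = Path(path)
    cmap = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"]
    for name in needed + ["eaf"]:
        source = cmap.get(name, name)
        if source not in df.columns:
            if name == "eaf":
                df["eaf"] = "NA"
                cmap["eaf"] = "eaf"
            else:
                raise FormatError(f"missing mandatory column {source!r} in {path.name}")

    records: list[AssocRecord] = []
    rejected: list[tuple[int, str, str]] = []
    warn_messages: list[str] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        getter = lambda name: getattr(row, cmap.get(name, name))
        vid = str(getter("variant_id")).strip()
        try:
            numeric = {name: _parse_float(getter(name)) for name in ("eaf", "beta", "se", "pval", "n")}
        except ValueError as exc:
            rejected.append((row_idx, vid, f"unparseable numeric: {exc}"))
            continue
        missing = [name for name in ("beta", "se", "pval", "n") if numeric[name] is None]
        if missing:
            rejected.append((row_idx, vid, f"missing value for {','.join(missing)}"))
            continue
        rec = AssocRecord(
            variant_id=vid,
            effect_allele=str(getter("effect_allele")).strip().upper(),
            other_allele=str(getter("other_allele")).strip().upper(),
            eaf=numeric["eaf"],
            beta=numeric["beta"],
            se=numeric["se"],
            pval=numeric["pval"],
            n=numeric["n"],
            trait_id=trait_id,
        )
        problems = rec.validate()
        if problems:
            rejected.append((row_idx, vid, "; ".join(problems)))
            continue
        if not rec.pval_consistent():
            msg = f"{vid}: reported p {rec.pval:g} inconsistent with |beta/se|"
            warn_messages.append(msg)
            warnings.warn(msg, stacklevel=2)
        records.append(rec)
    rejections = pd.DataFrame(rejected, columns=["row", "variant_id", "reason"])
    return ReadResult(records=records, rejections=rejections, warnings=warn_messages)


def records_to_frame(records: Iterable[AssocRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def write_gwas_table(records: Iterable[AssocRecord], path: str | Path) -> None:
    """Write records in the package dialect (tab-separated, NA for missing)."""
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD matrix TSV with a header row and a leading ID column.

    Symmetry is enforced by averaging (A+Aᵀ)/2 with a warning when the two
    triangles disagree; the diagonal is reset to exactly 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix is not square: {df.shape}")
    ids = [str(v) for v in df.index]
    if [str(c) for c in df.columns] != ids:
        raise FormatError("LD matrix row and column IDs disagree")
    r = df.to_numpy(dtype=float)
    if not np.allclose(r, r.T, atol=1e-12):
        warnings.warn("asymmetric LD matrix; symmetrizing by averaging", stacklevel=2)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    off = r[~np.eye(len(ids), dtype=bool)]
    if off.size and np.max(np.abs(off)) > 1.0:
        warnings.warn("off-diagonal |r| > 1 in LD matrix", stacklevel=2)
    return LDMatrix(ids, r)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep="\t")


def _format_ci(or_low: float, or_high: float) -> str:
    return f"({or_low:.2f}–{or_high:.2f})"


def write_report(results: Sequence["MREstimate"], path: str | Path) -> pd.DataFrame:
    """Write causal-effect estimates as a report table.

    Layout mirrors the conventional MR results table: Exposure, Outcome,
    Method, Number of SNPs, OR (95% CI) with the OR to two decimals and
    the CI as "(lo–hi)", and the p-value.  Returns the frame that was
    written.  An empty result list yields a header-only file.
    """
    rows = []
    for e in results:
        or_, lo, hi = e.to_odds_ratio()
        rows.append(
            {
                "exposure": e.exposure,
                "outcome": e.outcome,
                "method": e.method,
                "n_snps": e.format_n_snps(),
                "or_ci": f"{or_:.2f} {_format_ci(lo, hi)}",
                "pval": f"{e.pval:.3g}",
            }
        )
    df = pd.DataFrame(
        rows, columns=["exposure", "outcome", "method", "n_snps", "or_ci", "pval"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
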