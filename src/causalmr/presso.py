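"""MR-PRESSO: residual-sum-of-squares outlier detection for two-sample MR.

Horizontal pleiotropy concentrated in a few instruments shows up as
outlying residuals around the IVW fit.  The global test compares the
observed weighted residual sum of squares (each SNP's residual taken
around its leave-one-out IVW prediction) with a parametric null obtained
by redrawing the summary statistics from their sampling distributions;
the outlier test localizes the signal to individual SNPs with a
Bonferroni correction; the distortion test asks whether removing the
flagged SNPs moves the causal estimate more than removing a random
subset of the same size would.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import HarmonizedSet
from .univariate import InsufficientInstrumentsError, MREstimate, ivw

DEFAULT_N_SIM = 10_000
DEFAULT_ALPHA = 0.05


class AllOutliersError(RuntimeError):
    """Every instrument was flagged; no corrected estimate is possible."""


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    per_snp_p: dict[str, float]
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate
    distortion_p: float | None
    n_sim: int
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def per_snp_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": v,
                "pval": p,
                "bonferroni_pval": min(1.0, p * len(self.per_snp_p)),
                "outlier": v in set(self.outliers),
            }
            for v, p in self.per_snp_p.items()
        ]
        return pd.DataFrame(rows, columns=["variant_id", "pval", "bonferroni_pval", "outlier"])

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "per_snp_p": self.per_snp_p,
            "outliers": list(self.outliers),
            "raw_beta": self.raw_estimate.beta,
            "raw_se": self.raw_estimate.se,
            "corrected_beta": self.corrected_estimate.beta,
            "corrected_se": self.corrected_estimate.se,
            "distortion_p": self.distortion_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            f"MR-PRESSO (n_sim={self.n_sim}): RSS_obs={self.rss_obs:.3f}, "
            f"global p={self.global_p:.4g}",
            f"  outliers: {', '.join(self.outliers) if self.outliers else 'none'}",
            "  " + self.corrected_estimate.summary().replace("\n", "\n  "),
        ]
        if self.distortion_p is not None:
            lines.append(f"  distortion test p={self.distortion_p:.3f}")
        return "\n".join(lines)


def _loo_beta(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over the left-out index.

    Works on 2-D input with rows as independent replicates.
    """
    sw = np.sum(w, axis=-1, keepdims=True)
    swb = np.sum(w * b, axis=-1, keepdims=True)
    return (swb - w * b) / (sw - w)


def _rss_components(
    gamma: np.ndarray, Gamma: np.ndarray, se_Gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP weighted squared residuals around leave-one-out predictions.

    Returns (rss_j, beta_loo).  Accepts 2-D input (replicates × J).
    """
    b = Gamma / gamma
    w = (gamma / se_Gamma) ** 2  # = 1/ratio_se²
    beta_loo = _loo_beta(b, w)
    rss_j = (Gamma - beta_loo * gamma) ** 2 / se_Gamma**2
    return rss_j, beta_loo


def _simulate_rss(
    h: HarmonizedSet, beta_loo: np.ndarray, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Null per-SNP RSS contributions: (n_sim × J) matrix.

    Each draw resamples γ* ~ N(γ̂, se_γ²) and Γ* ~ N(β̂₋ⱼ γ̂_j, se_Γ²) and
    recomputes the leave-one-out residual sum of squares.
    """
    J = h.n_snps
    g_star = rng.normal(h.gamma, h.se_gamma, size=(n_sim, J))
    G_star = rng.normal(beta_loo * h.gamma, h.se_Gamma, size=(n_sim, J))
    g_star = np.where(g_star == 0, np.finfo(float).tiny, g_star)
    rss_star, _ = _rss_components(g_star, G_star, np.broadcast_to(h.se_Gamma, (n_sim, J)))
    return rss_star


def presso_global(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Global heterogeneity test; returns (rss_obs, global_p).

    global_p = (1 + #{RSS* ≥ RSS_obs}) / (1 + n_sim), so it is bounded
    below by 1/(n_sim+1) and never exactly zero.
    """
    if h.n_snps < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least four instruments")
    rng = np.random.default_rng(seed)
    rss_j, beta_loo = _rss_components(h.gamma, h.Gamma, h.se_Gamma)
    rss_obs = float(np.sum(rss_j))
    rss_star = _simulate_rss(h, beta_loo, n_sim, rng)
    global_p = (1 + int(np.sum(rss_star.sum(axis=1) >= rss_obs))) / (1 + n_sim)
    return rss_obs, float(global_p)


def presso_outlier(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | np.random.Generator = 0,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, float], list[str]]:
    """Per-SNP outlier test: each SNP's observed RSS contribution against its
    simulated null distribution; flagged iff the Bonferroni-adjusted p < alpha."""
    if h.n_snps < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least four instruments")
    rng = np.random.default_rng(seed)
    J = h.n_snps
    if J / (1 + n_sim) >= alpha:
        warnings.warn(
            f"n_sim={n_sim} cannot resolve Bonferroni-adjusted p below "
            f"alpha={alpha} for J={J}; no outlier can be flagged",
            stacklevel=2,
        )
    rss_j, beta_loo = _rss_components(h.gamma, h.Gamma, h.se_Gamma)
    rss_star = _simulate_rss(h, beta_loo, n_sim, rng)
    counts = np.sum(rss_star >= rss_j[None, :], axis=0)
    pvals = (1 + counts) / (1 + n_sim)
    per_snp_p = {v: float(p) for v, p in zip(h.variant_ids, pvals)}
    outliers = [v for v, p in per_snp_p.items() if p * J < alpha]
    return per_snp_p, outliers


def presso_distortion(
    h: HarmonizedSet,
    outliers: list[str],
    n_sim: int = DEFAULT_N_SIM,
    seed: int | np.random.Generator = 0,
) -> tuple[MREstimate, float | None]:
    """Outlier-corrected IVW and the distortion test.

    The corrected estimate is the IVW on the non-outlier instruments.
    The distortion statistic is the percentage change
    100·(β_corrected − β_raw)/|β_corrected|; its two-sided p-value comes
    from re-removing random pseudo-outlier subsets of the same size.
    With no outliers the corrected estimate equals the raw one and the
    distortion p is undefined (None).
    """
    raw = ivw(h)
    if not outliers:
        return raw, None
    outlier_set = set(outliers)
    if len(outlier_set) >= h.n_snps:
        raise AllOutliersError("every instrument flagged as an outlier")
    corrected_h = h.drop_variants(outliers)
    corrected = ivw(corrected_h)
    corrected.n_outliers = len(outlier_set)
    d_obs = 100.0 * (corrected.beta - raw.beta) / abs(corrected.beta)

    rng = np.random.default_rng(seed)
    J = h.n_snps
    k = len(outlier_set)
    b = h.Gamma / h.gamma
    w = (h.gamma / h.se_Gamma) ** 2
    sw, swb = float(np.sum(w)), float(np.sum(w * b))
    d_null = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(J, size=k, replace=False)
        beta_sub = (swb - float(np.sum(w[drop] * b[drop]))) / (
            sw - float(np.sum(w[drop]))
        )
        d_null[i] = 100.0 * (beta_sub - raw.beta) / abs(beta_sub)
    distortion_p = (1 + int(np.sum(np.abs(d_null) >= abs(d_obs)))) / (1 + n_sim)
    corrected.extras["distortion_pct"] = d_obs
    return corrected, float(distortion_p)


class MRPRESSO:
    """Model-object front end running the global, outlier and distortion tests.

    ``MRPRESSO(harmonized).fit(n_sim=10000, seed=...)`` returns a
    :class:`PressoResult`; defaults follow the convention of 10,000 null
    distributions at significance threshold 0.05.
    """

    def __init__(self, data: HarmonizedSet):
        self.data = data

    def fit(
        self,
        n_sim: int = DEFAULT_N_SIM,
        seed: int = 0,
        alpha: float = DEFAULT_ALPHA,
    ) -> PressoResult:
        rng = np.random.default_rng(seed)
        rss_obs, global_p = presso_global(self.data, n_sim, rng)
        per_snp_p, outliers = presso_outlier(self.data, n_sim, rng, alpha)
        raw = ivw(self.data)
        corrected, distortion_p = presso_distortion(self.data, outliers, n_sim, rng)
        corrected.method = "MR-PRESSO outlier-corrected"
        if corrected.n_outliers is None:
            corrected.n_outliers = 0
        return PressoResult(
            rss_obs=rss_obs,
            global_p=global_p,
            per_snp_p=per_snp_p,
            outliers=outliers,
            raw_estimate=raw,
            corrected_estimate=corrected,
            distortion_p=distortion_p,
            n_sim=n_sim,
            seed=seed,
        )
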