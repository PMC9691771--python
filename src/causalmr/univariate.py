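"""Univariate two-sample MR estimators and diagnostics.

All estimators operate on a :class:`~causalmr.harmonize.HarmonizedSet` of
J aligned SNP-exposure effects γ_j (SE σ_xj) and SNP-outcome effects Γ_j
(SE σ_yj).  The per-SNP causal estimate is the Wald ratio β_j = Γ_j/γ_j
with first-order delta-method SE σ_yj/|γ_j|.  The primary estimator is
the multiplicative random-effects IVW: the inverse-variance-weighted mean
of the ratios, with the SE inflated by √(Q/(J−1)) when Cochran's Q
exceeds its degrees of freedom (never deflated below the fixed-effect
SE).  MR-Egger adds an intercept to absorb directional pleiotropy; the
weighted median and weighted mode are robust to invalid instruments
(respectively: up to half the weight, and any minority cluster).  The
Steiger test checks that the instruments explain more variance in the
exposure than in the outcome, i.e. that causation runs the presumed way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

Z95 = 1.959963984540054  # Φ⁻¹(0.975)


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(ZeroDivisionError):
    """Wald ratio undefined because the SNP-exposure effect is zero."""


@dataclass
class MREstimate:
    """A causal-effect estimate: log-OR of outcome per 1-SD exposure.

    ``extras`` carries method-specific diagnostics such as the Egger
    intercept and its p-value, or Cochran's Q.
    """

    method: str
    beta: float
    se: float
    n_snps: int
    pval: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    exposure: str = ""
    outcome: str = ""
    n_outliers: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se
        if math.isnan(self.pval):
            self.pval = _normal_p(self.beta, self.se)

    def to_odds_ratio(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) per 1-SD increase in the exposure."""
        return math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high)

    def format_n_snps(self) -> str:
        if self.n_outliers is None:
            return str(self.n_snps)
        label = "outlier SNP" if self.n_outliers == 1 else "outlier SNPs"
        return f"{self.n_snps} ({self.n_outliers} {label})"

    def summary(self) -> str:
        or_, lo, hi = self.to_odds_ratio()
        lines = [
            f"{self.method}: beta={self.beta:.4f} (SE {self.se:.4f}), "
            f"OR={or_:.2f} (95% CI {lo:.2f}–{hi:.2f}), p={self.pval:.3g}, "
            f"n_snps={self.format_n_snps()}",
        ]
        for key, value in self.extras.items():
            lines.append(f"  {key}: {value:.4g}" if isinstance(value, float) else f"  {key}: {value}")
        return "\n".join(lines)


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: str  # "exposure_to_outcome" or "outcome_to_exposure"
    pval: float


def _normal_p(beta: float, se: float) -> float:
    if se <= 0:
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def to_odds_ratio(e: MREstimate) -> tuple[float, float, float]:
    """Exponentiate an estimate and its CI onto the odds-ratio scale."""
    return e.to_odds_ratio()


def wald_ratio(
    gamma: float, se_gamma: float, Gamma: float, se_Gamma: float
) -> tuple[float, float]:
    """Per-SNP causal estimate Γ/γ with first-order delta-method SE se(Γ)/|γ|.

    The first-order SE ignores the uncertainty in γ, the usual convention
    for genome-wide-significant (strong) instruments.
    """
    if gamma == 0:
        raise UndefinedRatioError("SNP-exposure effect is zero")
    return Gamma / gamma, se_Gamma / abs(gamma)


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(h.gamma == 0):
        raise UndefinedRatioError("SNP-exposure effect is zero for some instrument")
    return h.Gamma / h.gamma, h.se_Gamma / np.abs(h.gamma)


def ivw(h: HarmonizedSet) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    β̂ = Σ w_j β_j / Σ w_j with w_j = 1/se(β_j)²; the fixed-effect SE
    (Σ w_j)^(-1/2) is scaled by max(1, √(Q/(J−1))).  With a single
    instrument this reduces to the Wald ratio.
    """
    J = h.n_snps
    if J < 1:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    b, s = _ratios(h)
    if J == 1:
        beta, se = float(b[0]), float(s[0])
        return MREstimate("Wald ratio", beta, se, 1,
                          exposure=h.exposure_id, outcome=h.outcome_id)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (b - beta) ** 2))
    q_p = float(stats.chi2.sf(Q, J - 1))
    scale = max(1.0, math.sqrt(Q / (J - 1)))
    se = se_fixed * scale
    return MREstimate(
        "Inverse variance weighted",
        beta,
        se,
        J,
        exposure=h.exposure_id,
        outcome=h.outcome_id,
        extras={"Q": Q, "Q_pval": q_p, "Q_df": J - 1, "se_fixed": se_fixed},
    )


def cochran_q(h: HarmonizedSet, beta: float) -> tuple[float, float]:
    """Heterogeneity of the per-SNP ratios around ``beta`` (χ², J−1 df)."""
    J = h.n_snps
    if J < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least two instruments")
    b, s = _ratios(h)
    w = 1.0 / s**2
    Q = float(np.sum(w * (b - beta) ** 2))
    return Q, float(stats.chi2.sf(Q, J - 1))


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression Γ_j = α + β γ_j allowing directional pleiotropy.

    Instrument orientation is fixed by flipping (γ_j, Γ_j) sign pairs so
    all γ_j ≥ 0 (required for the InSIDE-consistent interpretation of the
    intercept).  Weights are 1/se(Γ_j)²; SEs use the multiplicative
    random-effects scale max(1, √(RSS_w/(J−2))).  The intercept α
    estimates the average directional pleiotropic effect; its p-value
    tests for directional pleiotropy.  Inference uses the t distribution
    with J−2 df, the convention for this small-J regression.
    """
    J = h.n_snps
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least three instruments")
    flip = np.where(h.gamma < 0, -1.0, 1.0)
    g = h.gamma * flip
    G = h.Gamma * flip
    w = 1.0 / h.se_Gamma**2
    X = np.column_stack([np.ones(J), g])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ G)
    resid = G - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (J - 2)))
    ses = np.sqrt(np.diag(xtwx_inv)) * scale
    alpha, beta = float(coef[0]), float(coef[1])
    se_alpha, se_beta = float(ses[0]), float(ses[1])
    p_beta = float(2.0 * stats.t.sf(abs(beta) / se_beta, J - 2))
    p_alpha = float(2.0 * stats.t.sf(abs(alpha) / se_alpha, J - 2))
    return MREstimate(
        "MR Egger",
        beta,
        se_beta,
        J,
        pval=p_beta,
        exposure=h.exposure_id,
        outcome=h.outcome_id,
        extras={
            "egger_intercept": alpha,
            "egger_intercept_se": se_alpha,
            "egger_intercept_pval": p_alpha,
        },
    )


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b_sorted = b[order]
    w_sorted = w[order] / np.sum(w)
    cum_mid = np.cumsum(w_sorted) - w_sorted / 2.0
    return float(np.interp(0.5, cum_mid, b_sorted))


def _bootstrap_se(
    h: HarmonizedSet,
    point: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Parametric bootstrap: resample γ̂, Γ̂ from their sampling distributions."""
    J = h.n_snps
    g_star = rng.normal(h.gamma, h.se_gamma, size=(n_boot, J))
    G_star = rng.normal(h.Gamma, h.se_Gamma, size=(n_boot, J))
    g_star = np.where(g_star == 0, np.finfo(float).tiny, g_star)
    b_star = G_star / g_star
    w_star = (np.abs(g_star) / h.se_Gamma) ** 2
    draws = np.array([point(b_star[i], w_star[i]) for i in range(n_boot)])
    return float(np.std(draws, ddof=1))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> MREstimate:
    """Weighted median of the per-SNP ratios.

    Consistent when instruments carrying at least half the total weight
    are valid.  The point estimate interpolates the order statistics of
    the ratios at cumulative weight 1/2 (weights 1/se(β_j)², cumulative
    midpoints (S_{j−1}+w'_j/2)); the SE comes from a parametric bootstrap.
    """
    J = h.n_snps
    if J < 3:
        raise InsufficientInstrumentsError("weighted median needs at least three instruments")
    rng = np.random.default_rng(seed)
    b, s = _ratios(h)
    w = 1.0 / s**2
    beta = _weighted_median_point(b, w)
    se = _bootstrap_se(h, _weighted_median_point, n_boot, rng)
    return MREstimate(
        "Weighted median", beta, se, J,
        exposure=h.exposure_id, outcome=h.outcome_id,
        extras={"n_boot": n_boot},
    )


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    J = b.size
    sd = float(np.std(b, ddof=1)) if J > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return phi * 0.9 * spread * J ** (-1.0 / 5.0)


def _weighted_mode_point(
    b: np.ndarray, w: np.ndarray, phi: float, n_grid: int = 512
) -> float:
    hband = _mode_bandwidth(b, phi)
    if hband <= 0:
        return float(b[0])  # all ratios identical
    grid = np.linspace(b.min() - 3 * hband, b.max() + 3 * hband, n_grid)
    wn = w / np.sum(w)
    dens = np.sum(
        wn[None, :] * np.exp(-0.5 * ((grid[:, None] - b[None, :]) / hband) ** 2),
        axis=1,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: HarmonizedSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MREstimate:
    """Weighted mode: the ratio value where the largest cluster of SNPs agrees.

    A weighted normal-kernel density over the per-SNP ratios (bandwidth
    phi × 0.9·min(sd, IQR/1.349)·J^(−1/5), evaluated on a 512-point grid
    spanning the ratios ± 3 bandwidths) is maximized.  Consistent when
    the largest group of instruments sharing a ratio value is valid, even
    if valid instruments are a minority.
    """
    J = h.n_snps
    if J < 3:
        raise InsufficientInstrumentsError("weighted mode needs at least three instruments")
    rng = np.random.default_rng(seed)
    b, s = _ratios(h)
    w = 1.0 / s**2
    beta = _weighted_mode_point(b, w, phi)
    se = _bootstrap_se(h, lambda bb, ww: _weighted_mode_point(bb, ww, phi), n_boot, rng)
    return MREstimate(
        "Weighted mode", beta, se, J,
        exposure=h.exposure_id, outcome=h.outcome_id,
        extras={"phi": phi, "n_boot": n_boot},
    )


def steiger(
    h: HarmonizedSet,
    n_exposure: float | None = None,
    n_outcome: float | None = None,
) -> SteigerResult:
    """Directionality test: do the instruments explain more exposure or outcome variance?

    Per-SNP R² uses the t-statistic approximation R² = t²/(t²+n−2) summed
    over instruments for each trait (binary outcomes use the same
    approximation, on the liability of the log-odds scale — an accepted
    approximation, noted as such).  Causation is inferred to run from
    exposure to outcome iff ΣR²_exposure > ΣR²_outcome; the p-value
    compares the Fisher-transformed correlations √ΣR² between the two
    (independent) samples.
    """
    n_x = n_exposure if n_exposure is not None else h.n_exposure
    n_y = n_outcome if n_outcome is not None else h.n_outcome
    if n_x is None or n_y is None:
        raise ValueError("Steiger test requires exposure and outcome sample sizes")
    t_x = h.gamma / h.se_gamma
    t_y = h.Gamma / h.se_Gamma
    r2_x = float(np.sum(t_x**2 / (t_x**2 + n_x - 2)))
    r2_y = float(np.sum(t_y**2 / (t_y**2 + n_y - 2)))
    r2_x = min(r2_x, 1.0)
    r2_y = min(r2_y, 1.0)
    r_x = math.sqrt(r2_x)
    r_y = math.sqrt(r2_y)
    # two-sample z on Fisher-transformed correlations (cohorts independent)
    z = (math.atanh(min(r_x, 1 - 1e-15)) - math.atanh(min(r_y, 1 - 1e-15))) / math.sqrt(
        1.0 / (n_x - 3) + 1.0 / (n_y - 3)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    direction = "exposure_to_outcome" if r2_x > r2_y else "outcome_to_exposure"
    return SteigerResult(r2_x, r2_y, direction, pval)


def per_snp_table(h: HarmonizedSet) -> "pd.DataFrame":
    """Plot-ready per-SNP data: the content of scatter, forest and funnel views.

    Columns: the harmonized effect pairs, the Wald ratio per SNP with its
    SE (forest rows), and the inverse ratio-SE (funnel y-axis).
    """
    import pandas as pd

    b, s = _ratios(h)
    return pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "gamma": h.gamma,
            "se_gamma": h.se_gamma,
            "Gamma": h.Gamma,
            "se_Gamma": h.se_Gamma,
            "ratio": b,
            "ratio_se": s,
            "precision": 1.0 / s,
        }
    )


class UnivariateMR:
    """Univariate two-sample MR model over one harmonized instrument set.

    Statsmodels-style front end: construct from a
    :class:`~causalmr.harmonize.HarmonizedSet` (or raw effect arrays via
    :meth:`from_arrays`), then ``fit(method=...)`` returns an
    :class:`MREstimate`; ``fit_all`` runs the full estimator suite.
    """

    METHODS = ("ivw", "egger", "wmedian", "wmode")

    def __init__(self, data: HarmonizedSet):
        self.data = data

    @classmethod
    def from_arrays(
        cls,
        gamma,
        se_gamma,
        Gamma,
        se_Gamma,
        variant_ids=None,
        **kwargs,
    ) -> "UnivariateMR":
        gamma = np.asarray(gamma, dtype=float)
        if variant_ids is None:
            variant_ids = [f"snp{i + 1}" for i in range(gamma.size)]
        h = HarmonizedSet(
            variant_ids=list(variant_ids),
            gamma=gamma,
            se_gamma=np.asarray(se_gamma, dtype=float),
            Gamma=np.asarray(Gamma, dtype=float),
            se_Gamma=np.asarray(se_Gamma, dtype=float),
            eaf_exposure=np.full(gamma.size, np.nan),
            **kwargs,
        )
        return cls(h)

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        if method == "ivw":
            return ivw(self.data)
        if method == "egger":
            return egger(self.data)
        if method == "wmedian":
            return weighted_median(self.data, **kwargs)
        if method == "wmode":
            return weighted_mode(self.data, **kwargs)
        raise ValueError(f"unknown method {method!r}; choose from {self.METHODS}")

    def fit_all(self, n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
        rng = np.random.default_rng(seed)
        return [
            self.fit("ivw"),
            self.fit("egger"),
            self.fit("wmedian", n_boot=n_boot, seed=rng),
            self.fit("wmode", n_boot=n_boot, seed=rng),
        ]

    def heterogeneity(self) -> tuple[float, float]:
        return cochran_q(self.data, ivw(self.data).beta)

    def per_snp_table(self):
        return per_snp_table(self.data)

    def steiger(self, n_exposure=None, n_outcome=None) -> SteigerResult:
        return steiger(self.data, n_exposure, n_outcome)
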