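"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data regime of a lipid→osteoarthritis MR
study: one continuous exposure measured in SD units in a large GWAS
(default n = 188,578, the scale of a lipid consortium meta-analysis) and
a binary outcome from a case-control GWAS (default 77,052 cases /
378,169 controls).  Per-SNP true effects γ_j on the exposure are drawn
with magnitude ~N(0.08, 0.02) SD per allele (floored at 0.03 so every
instrument is genome-wide significant at these sample sizes) and random
sign; the SNP-outcome effect is Γ_j = θ·γ_j + α_j with θ the causal
log-OR per SD and α_j an optional pleiotropic contribution (balanced or
directional, on a configurable fraction of instruments, optionally
correlated with γ to break the InSIDE assumption).  Summary SEs derive
from the sample sizes via se ≈ 1/√(2·n·eaf·(1−eaf)) for the standardized
exposure and the case/control-weighted analogue
1/√(2·n·φ(1−φ)·eaf·(1−eaf)) for the binary outcome.  Outcome tables are
emitted with randomized allele order and strand so harmonization is
exercised; palindromic variants are planted at a configurable fraction,
a sub-fraction of them with intermediate allele frequency (unresolvable,
expected to be dropped).  Optional AR(1) LD blocks propagate joint
effects to marginal ones and correlate the summary noise, matching what
the LD-aware estimator assumes.  All randomness flows from one seeded
generator; no global state.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io import AssocRecord, LDMatrix, write_gwas_table, write_ld_matrix

LN_OR_091 = math.log(0.91)

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Ground-truth configuration for one synthetic two-sample dataset.

    Defaults reproduce the primary study regime: J=79 independent
    instruments, θ = ln(0.91) log-OR per 1-SD exposure, no pleiotropy,
    consortium-scale sample sizes.
    """

    J: int = 79
    theta: float | Sequence[float] = LN_OR_091
    gamma_mean: float = 0.08      # mean |γ| in SD per allele
    gamma_sd: float = 0.02
    gamma_min: float = 0.03       # floor keeps every instrument genome-wide significant
    n_exposure: float = 188_578.0
    n_outcome: float = 455_221.0
    n_cases: float = 77_052.0
    se_exposure: float | None = None   # overrides sample-size-derived SEs
    se_outcome: float | None = None
    pleiotropy_mode: str = "none"      # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0   # fraction of instruments carrying α_j
    inside_violation: float = 0.0      # corr(γ_j, α_j); 0 keeps InSIDE
    outlier_count: int = 0
    outlier_displacement: float = 10.0  # in outcome SEs
    palindromic_fraction: float = 0.0
    intermediate_fraction: float = 0.0  # of palindromic SNPs, MAF ≥ 0.3
    eaf_low: float = 0.10
    eaf_high: float = 0.90
    ld_mode: str = "none"               # none | ar1
    ld_rho: float = 0.0
    ld_block_size: int = 0
    K: int = 1
    exposure_corr: Sequence[Sequence[float]] | None = None
    exposure_ids: Sequence[str] | None = None
    outcome_id: str = "outcome"
    seed: int = 0

    def thetas(self) -> np.ndarray:
        t = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if t.size == 1 and self.K > 1:
            t = np.repeat(t, self.K)
        if t.size != self.K:
            raise ValueError("theta vector length must equal K")
        return t

    def validate(self) -> None:
        if self.J <= 0 or self.K <= 0:
            raise ValueError("J and K must be positive")
        if self.outlier_count < 0:
            raise ValueError("outlier_count must be nonnegative")
        if not (0 <= self.palindromic_fraction <= 1 and 0 <= self.intermediate_fraction <= 1):
            raise ValueError("fractions must lie in [0,1]")
        if not (-1 <= self.inside_violation <= 1):
            raise ValueError("inside_violation is a correlation")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.ld_mode not in ("none", "ar1"):
            raise ValueError(f"unknown LD mode {self.ld_mode!r}")
        if self.ld_mode == "ar1" and not (-1 < self.ld_rho < 1 and self.ld_block_size >= 1):
            raise ValueError("ar1 LD needs |rho|<1 and block_size ≥ 1")


@dataclass
class TruthRecord:
    """Ground truth aligned with the emitted tables by variant_id."""

    theta: list[float]
    variant_ids: list[str]
    gamma_true: dict[str, list[float]]  # variant → per-exposure true γ
    alpha: dict[str, float]             # pleiotropic outcome contribution
    outlier_ids: list[str]
    intermediate_palindromic_ids: list[str]
    exposure_ids: list[str]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthRecord":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


@dataclass
class SimData:
    """One simulated two-sample dataset (tables, optional LD, truth)."""

    exposures: dict[str, list[AssocRecord]]
    outcome: list[AssocRecord]
    ld: LDMatrix | None
    truth: TruthRecord

    @property
    def exposure(self) -> list[AssocRecord]:
        return next(iter(self.exposures.values()))

    def __iter__(self):
        tables = self.exposure if len(self.exposures) == 1 else self.exposures
        return iter((tables, self.outcome, self.ld, self.truth))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def _draw_eaf(cfg: SimConfig, rng: np.random.Generator, palindromic: np.ndarray,
              intermediate: np.ndarray) -> np.ndarray:
    """Allele frequencies; palindromic SNPs get MAF strictly inside or outside 0.3."""
    eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, size=cfg.J)
    for j in range(cfg.J):
        if not palindromic[j]:
            continue
        if intermediate[j]:
            eaf[j] = rng.uniform(0.35, 0.65)
        else:
            maf = rng.uniform(0.08, 0.25)
            eaf[j] = maf if rng.random() < 0.5 else 1.0 - maf
    return eaf


def _ar1_blocks(J: int, rho: float, block_size: int) -> np.ndarray:
    R = np.eye(J)
    for start in range(0, J, block_size):
        stop = min(start + block_size, J)
        idx = np.arange(start, stop)
        R[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return R


def _correlated_noise(rng: np.random.Generator, R_chol: np.ndarray | None,
                      se: np.ndarray) -> np.ndarray:
    z = rng.standard_normal(se.size)
    if R_chol is not None:
        z = R_chol @ z
    return z * se


def simulate_two_sample(cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> SimData:
    """Generate exposure and outcome summary tables under a known causal model.

    See the module docstring for the generative model.  Returns a
    :class:`SimData`; iterating it yields the classic
    ``(exposure table(s), outcome table, LD matrix or None, truth)``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    J, K = cfg.J, cfg.K
    thetas = cfg.thetas()
    exposure_ids = list(cfg.exposure_ids or [f"exposure{k + 1}" for k in range(K)])
    if len(exposure_ids) != K:
        raise ValueError("exposure_ids length must equal K")
    variant_ids = [f"rs{1000 + j}" for j in range(J)]

    # allele assignment
    n_pal = int(round(cfg.palindromic_fraction * J))
    pal_idx = rng.choice(J, size=n_pal, replace=False)
    palindromic = np.zeros(J, dtype=bool)
    palindromic[pal_idx] = True
    n_int = int(round(cfg.intermediate_fraction * n_pal))
    intermediate = np.zeros(J, dtype=bool)
    if n_int:
        intermediate[rng.choice(pal_idx, size=n_int, replace=False)] = True
    alleles = []
    for j in range(J):
        pairs = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        alleles.append(pairs[rng.integers(len(pairs))])
    eaf = _draw_eaf(cfg, rng, palindromic, intermediate)

    # true per-exposure effects; each SNP is an instrument "for" one exposure
    assigned = np.repeat(np.arange(K), int(np.ceil(J / K)))[:J]
    magnitude = np.maximum(cfg.gamma_min,
                           rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=J))
    sign = rng.choice([-1.0, 1.0], size=J)
    gamma_primary = sign * magnitude
    C = np.eye(K) if cfg.exposure_corr is None else np.asarray(cfg.exposure_corr, float)
    gamma_true = np.zeros((J, K))
    for j in range(J):
        k0 = assigned[j]
        for k in range(K):
            if k == k0:
                gamma_true[j, k] = gamma_primary[j]
            else:
                shared = C[k0, k] * gamma_primary[j]
                gamma_true[j, k] = shared + rng.normal(0.0, 0.2 * cfg.gamma_sd)

    # LD propagation: marginal effects are R-mixtures of joint effects
    R = None
    R_chol = None
    if cfg.ld_mode == "ar1":
        R = _ar1_blocks(J, cfg.ld_rho, cfg.ld_block_size)
        R_chol = np.linalg.cholesky(R)
        gamma_true = R @ gamma_true

    # pleiotropy, planted relative to the exposure-increasing orientation so
    # that a directional mean biases every affected ratio the same way
    alpha = np.zeros(J)
    if cfg.pleiotropy_mode != "none" and cfg.pleiotropy_fraction > 0:
        n_pleio = int(round(cfg.pleiotropy_fraction * J))
        pleio_idx = rng.choice(J, size=n_pleio, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        z_ind = rng.standard_normal(n_pleio)
        if cfg.inside_violation != 0.0:
            strength = np.abs(gamma_true[pleio_idx, 0])
            z_g = (strength - strength.mean()) / (strength.std() or 1.0)
            rho = cfg.inside_violation
            z = rho * z_g + math.sqrt(1 - rho**2) * z_ind
        else:
            z = z_ind
        oriented = mean + cfg.pleiotropy_sd * z
        alpha[pleio_idx] = np.sign(gamma_true[pleio_idx, 0]) * oriented

    # standard errors
    if cfg.se_exposure is not None:
        se_x = np.full((J, K), float(cfg.se_exposure))
    else:
        se_x = np.tile(1.0 / np.sqrt(2.0 * cfg.n_exposure * eaf * (1 - eaf)),
                       (K, 1)).T
    if cfg.se_outcome is not None:
        se_y = np.full(J, float(cfg.se_outcome))
    else:
        phi = cfg.n_cases / cfg.n_outcome
        se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * phi * (1 - phi) * eaf * (1 - eaf))

    # observed summary statistics
    gamma_hat = np.column_stack(
        [gamma_true[:, k] + _correlated_noise(rng, R_chol, se_x[:, k]) for k in range(K)]
    )
    Gamma_mean = gamma_true @ thetas + alpha
    outlier_ids: list[str] = []
    if cfg.outlier_count:
        out_idx = rng.choice(J, size=min(cfg.outlier_count, J), replace=False)
        shift = cfg.outlier_displacement * se_y[out_idx]
        Gamma_mean = Gamma_mean.copy()
        Gamma_mean[out_idx] += shift * rng.choice([-1.0, 1.0], size=out_idx.size)
        outlier_ids = [variant_ids[i] for i in sorted(out_idx)]
    Gamma_hat = Gamma_mean + _correlated_noise(rng, R_chol, se_y)

    def record(vid, ea, oa, eaf_v, beta, se, n, trait, n_cases=None):
        return AssocRecord(
            variant_id=vid, effect_allele=ea, other_allele=oa, eaf=float(eaf_v),
            beta=float(beta), se=float(se),
            pval=float(_two_sided_p(np.array([beta]), np.array([se]))[0]),
            n=float(n), trait_id=trait, n_cases=n_cases,
        )

    exposures: dict[str, list[AssocRecord]] = {eid: [] for eid in exposure_ids}
    for k, eid in enumerate(exposure_ids):
        for j in range(J):
            ea, oa = alleles[j]
            exposures[eid].append(
                record(variant_ids[j], ea, oa, eaf[j], gamma_hat[j, k],
                       se_x[j, k], cfg.n_exposure, eid)
            )

    # outcome table: randomized allele order and strand
    outcome: list[AssocRecord] = []
    for j in range(J):
        ea, oa = alleles[j]
        beta, eaf_v = Gamma_hat[j], eaf[j]
        if rng.random() < 0.5:  # swap allele roles
            ea, oa = oa, ea
            beta, eaf_v = -beta, 1.0 - eaf_v
        if rng.random() < 0.5:  # report the other strand
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        outcome.append(
            record(variant_ids[j], ea, oa, eaf_v, beta, se_y[j],
                   cfg.n_outcome, cfg.outcome_id, cfg.n_cases)
        )

    ld = LDMatrix(list(variant_ids), R) if R is not None else None
    truth = TruthRecord(
        theta=[float(t) for t in thetas],
        variant_ids=list(variant_ids),
        gamma_true={variant_ids[j]: [float(g) for g in gamma_true[j]] for j in range(J)},
        alpha={variant_ids[j]: float(alpha[j]) for j in range(J)},
        outlier_ids=outlier_ids,
        intermediate_palindromic_ids=[variant_ids[j] for j in range(J) if intermediate[j]],
        exposure_ids=exposure_ids,
    )
    return SimData(exposures=exposures, outcome=outcome, ld=ld, truth=truth)


#: named fixture regimes: (directory name, config overrides)
FIXTURE_REGIMES: dict[str, dict] = {
    "null": dict(J=80, theta=0.0),
    "effect": dict(J=79, theta=LN_OR_091),
    # robustness regime: 40% of instruments carry directional pleiotropy a
    # quarter the size of the exposure effect; instruments are strong
    # (per-ratio SE ≈ 0.02) so the median's half-weight guarantee applies
    "invalid40": dict(
        J=60, theta=LN_OR_091, pleiotropy_mode="directional",
        pleiotropy_mean=0.02, pleiotropy_sd=0.005, pleiotropy_fraction=0.4,
        se_exposure=0.003, se_outcome=0.0016,
    ),
    "outlier": dict(J=50, theta=LN_OR_091, outlier_count=1, outlier_displacement=10.0),
    "palindrome": dict(
        J=60, theta=LN_OR_091, palindromic_fraction=0.5, intermediate_fraction=0.4,
    ),
    "mvmr": dict(
        J=80, K=4, theta=[LN_OR_091, 0.0, 0.0, math.log(2.14)],
        exposure_ids=["LDL", "HDL", "TG", "BMI"],
        exposure_corr=[
            [1.0, -0.1, 0.3, 0.0],
            [-0.1, 1.0, -0.4, 0.0],
            [0.3, -0.4, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ],
    ),
    "region": dict(
        J=6, theta=math.log(0.76), ld_mode="ar1", ld_rho=0.4, ld_block_size=6,
        gamma_mean=0.06, gamma_sd=0.01,
    ),
}


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic named fixture sets used across the test regimes.

    One sub-directory per regime, each holding ``<exposure>.tsv`` per
    exposure, ``outcome.tsv``, ``truth.json`` and, where LD is simulated,
    ``ld.tsv``.  Re-running with the same seed reproduces every file
    byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for i, (name, overrides) in enumerate(FIXTURE_REGIMES.items()):
        cfg = SimConfig(seed=seed + i, **overrides)
        sim = simulate_two_sample(cfg)
        sub = out_dir / name
        sub.mkdir(exist_ok=True)
        for eid, records in sim.exposures.items():
            write_gwas_table(records, sub / f"{eid}.tsv")
        write_gwas_table(sim.outcome, sub / "outcome.tsv")
        if sim.ld is not None:
            write_ld_matrix(sim.ld, sub / "ld.tsv")
        sim.truth.to_json(sub / "truth.json")
        written[name] = sub
    return written
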