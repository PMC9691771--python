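"""End-to-end study workflow: select → harmonize → estimate → sensitivity.

One YAML config drives the full analysis for every exposure×outcome
pair: instrument selection, harmonization, the univariate estimator
suite with heterogeneity and Steiger diagnostics, MR-PRESSO, optionally
multivariable IVW across all exposures and LD-aware gene-region MR.
Outputs are a results table (TSV + JSON), the harmonization audit trail
and a structured run log; every number is a pure function of the input
files, the config and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import yaml

from ._version import __version__
from .drug_target import RegionalMR, restrict_to_region
from .harmonize import (
    DEFAULT_MAF_LIMIT,
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_THRESHOLD,
    harmonize_sets,
    select_instruments,
)
from .io import AssocRecord, read_gwas_table, read_ld_matrix, write_report
from .mvmr import MultivariableMR
from .presso import MRPRESSO
from .univariate import MREstimate, UnivariateMR


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the log."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyReport:
    """Assembled result bundle of one full study run."""

    univariate: list[MREstimate] = field(default_factory=list)
    presso: list = field(default_factory=list)  # PressoResult
    multivariable: list[MREstimate] = field(default_factory=list)
    drug_target: list[MREstimate] = field(default_factory=list)
    steiger: list[dict] = field(default_factory=list)
    audit: list[tuple[str, str, str, str]] = field(default_factory=list)  # analysis, variant, action, reason
    log: list[str] = field(default_factory=list)

    def all_estimates(self) -> list[MREstimate]:
        presso_estimates = [r.corrected_estimate for r in self.presso]
        return self.univariate + presso_estimates + self.multivariable + self.drug_target

    def to_json_dict(self) -> dict:
        def enc(e: MREstimate) -> dict:
            or_, lo, hi = e.to_odds_ratio()
            return {
                "exposure": e.exposure,
                "outcome": e.outcome,
                "method": e.method,
                "n_snps": e.n_snps,
                "n_outliers": e.n_outliers,
                "beta": e.beta,
                "se": e.se,
                "or": or_,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "pval": e.pval,
                "extras": {k: v for k, v in e.extras.items()},
            }

        return {
            "version": __version__,
            "univariate": [enc(e) for e in self.univariate],
            "presso": [r.to_dict() for r in self.presso],
            "multivariable": [enc(e) for e in self.multivariable],
            "drug_target": [enc(e) for e in self.drug_target],
            "steiger": self.steiger,
            "log": self.log,
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(self.all_estimates(), out_dir / "results.tsv")
        (out_dir / "results.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, default=float) + "\n"
        )
        with open(out_dir / "audit.tsv", "w") as fh:
            fh.write("analysis\tvariant_id\taction\treason\n")
            for row in self.audit:
                fh.write("\t".join(row) + "\n")
        (out_dir / "log.txt").write_text("\n".join(self.log) + "\n")


def _load_records(path: str | Path, trait_id: str) -> list[AssocRecord]:
    result = read_gwas_table(path, trait_id=trait_id)
    return result.records


def run_study(config: str | Path | dict, out_dir: str | Path | None = None) -> StudyReport:
    """Run the configured study end to end and return the report bundle.

    Config keys (YAML file or dict): ``exposures`` (name → table path),
    ``outcomes`` (name → table path), optional ``ld_matrix`` path for
    clumping, ``regions`` (name → {exposure, variants, ld}) for
    gene-region MR, ``multivariable: true/false``, and the thresholds
    ``p_threshold`` (5e-8), ``r2_threshold`` (0.001), ``maf_limit``
    (0.3), ``n_boot``, ``presso_n_sim``, ``alpha`` and ``seed``.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    p_thr = float(cfg.get("p_threshold", DEFAULT_P_THRESHOLD))
    r2_thr = float(cfg.get("r2_threshold", DEFAULT_R2_THRESHOLD))
    maf_limit = float(cfg.get("maf_limit", DEFAULT_MAF_LIMIT))
    n_boot = int(cfg.get("n_boot", 1000))
    presso_n_sim = int(cfg.get("presso_n_sim", 10_000))
    alpha = float(cfg.get("alpha", 0.05))

    report = StudyReport()
    log = report.log
    log.append(f"causalmr {__version__} | seed={seed} | p<{p_thr:g} r2<{r2_thr:g} maf_limit={maf_limit}")

    clump_ld = None
    if cfg.get("ld_matrix"):
        clump_ld = read_ld_matrix(cfg["ld_matrix"])
        log.append(f"ld_matrix: {len(clump_ld.variant_ids)} variants")

    exposures = {
        name: _load_records(path, name) for name, path in cfg.get("exposures", {}).items()
    }
    outcomes = {
        name: _load_records(path, name) for name, path in cfg.get("outcomes", {}).items()
    }
    if not exposures or not outcomes:
        raise StageError("config", "at least one exposure and one outcome required")

    instrument_sets = {}
    for name, records in exposures.items():
        try:
            instruments = select_instruments(records, clump_ld, p_thr, r2_thr)
        except Exception as exc:
            raise StageError("select_instruments", f"{name}: {exc}") from exc
        instrument_sets[name] = instruments
        log.append(f"select[{name}]: {len(records)} in → {len(instruments)} instruments")

    for out_name, out_records in outcomes.items():
        for exp_name, instruments in instrument_sets.items():
            try:
                h = harmonize_sets(instruments, out_records, maf_limit)
            except Exception as exc:
                raise StageError("harmonize", f"{exp_name}×{out_name}: {exc}") from exc
            counts = h.audit_frame()["action"].value_counts().to_dict()
            log.append(f"harmonize[{exp_name}×{out_name}]: {counts} → J={h.n_snps}")
            report.audit.extend(
                (f"{exp_name}×{out_name}", v, a, r) for v, a, r in h.audit
            )
            model = UnivariateMR(h)
            try:
                estimates = model.fit_all(n_boot=n_boot, seed=seed)
            except Exception as exc:
                raise StageError("uni_mr", f"{exp_name}×{out_name}: {exc}") from exc
            report.univariate.extend(estimates)
            q, q_p = model.heterogeneity()
            log.append(f"uni_mr[{exp_name}×{out_name}]: Q={q:.2f} (p={q_p:.3g})")
            try:
                st = model.steiger()
                report.steiger.append(
                    {
                        "exposure": exp_name,
                        "outcome": out_name,
                        "r2_exposure": st.r2_exposure,
                        "r2_outcome": st.r2_outcome,
                        "direction": st.direction,
                        "pval": st.pval,
                    }
                )
            except ValueError:
                log.append(f"steiger[{exp_name}×{out_name}]: skipped (no sample sizes)")
            if h.n_snps >= 4:
                try:
                    pres = MRPRESSO(h).fit(n_sim=presso_n_sim, seed=seed, alpha=alpha)
                except Exception as exc:
                    raise StageError("presso", f"{exp_name}×{out_name}: {exc}") from exc
                for e in (pres.corrected_estimate,):
                    e.exposure, e.outcome = exp_name, out_name
                report.presso.append(pres)
                log.append(
                    f"presso[{exp_name}×{out_name}]: global_p={pres.global_p:.4g}, "
                    f"outliers={len(pres.outliers)}"
                )
            else:
                log.append(f"presso[{exp_name}×{out_name}]: skipped (J<4)")

    if cfg.get("multivariable", False) and len(exposures) >= 2:
        for out_name, out_records in outcomes.items():
            try:
                model = MultivariableMR.from_tables(instrument_sets, exposures, out_records, maf_limit)
                estimates = model.fit()
            except Exception as exc:
                raise StageError("mvmr", f"{out_name}: {exc}") from exc
            for e in estimates:
                e.outcome = out_name
            report.multivariable.extend(estimates)
            report.audit.extend((f"mvmr×{out_name}", v, a, r) for v, a, r in model.data.audit)
            log.append(f"mvmr[{out_name}]: J={model.data.J}, K={model.data.K}")

    for region_name, region_cfg in (cfg.get("regions") or {}).items():
        exp_name = region_cfg["exposure"]
        variants = list(region_cfg["variants"])
        ld = read_ld_matrix(region_cfg["ld"])
        for out_name, out_records in outcomes.items():
            try:
                subset, missing = restrict_to_region(exposures[exp_name], variants)
                if missing:
                    report.audit.extend(
                        (f"region:{region_name}", v, "dropped", "absent from summary table")
                        for v in missing
                    )
                h = harmonize_sets(subset, out_records, maf_limit)
                model = RegionalMR(h, ld)
                est = model.fit()
            except Exception as exc:
                raise StageError("drug_target", f"{region_name}×{out_name}: {exc}") from exc
            est.exposure, est.outcome = region_name, out_name
            for warning in model.correlation_warnings():
                log.append(f"drug_target[{region_name}]: correlated pair {warning}")
            report.drug_target.append(est)
            log.append(
                f"drug_target[{region_name}×{out_name}]: J={est.n_snps}, "
                f"het_p={est.extras.get('Q_pval', float('nan')):.3g}"
            )

    if out_dir is not None:
        report.write(out_dir)
    return report
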