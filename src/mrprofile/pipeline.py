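"""End-to-end analysis: harmonize → Σ → select/clump → fit → diagnose → sweep.

`run_pipeline` is the library-level entry point the command-line interface
wraps; it reads the per-trait summary-statistics files, runs every stage,
and writes a JSON report plus TSV side files under an output prefix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .fit import RobustLoss, fit_effects
from .modes import profile_curve, select_markers
from .replicability import DEFAULT_THRESHOLDS, threshold_sweep
from .shared_correlation import SharedCorrelation, estimate_shared_correlation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML."""

    outcome: str
    exposures: list[str]
    selections: list[str]
    threshold: float = 1e-2
    sweep_thresholds: list[float] = field(
        default_factory=lambda: list(DEFAULT_THRESHOLDS))
    c_fit: float = 4.6851
    c_diag: float = 3.0
    t0: float = 1.0
    t1: float = 2.0
    r2_instruments: float = 0.001
    r2_markers: float = 0.05
    ld_matrix: str | None = None
    assume_independent: bool = False
    sigma: str | None = None  # path to a fixed Σ TSV, else estimated
    run_sweep: bool = False
    seed: int = 0
    out_prefix: str = "mrprofile_run"

    def __post_init__(self) -> None:
        if self.c_fit <= 0 or self.c_diag <= 0 or self.t0 <= 0 or self.t1 <= 0:
            raise ValueError("loss constants and marker cutoffs must be positive")
        if len(self.exposures) != len(self.selections):
            raise ValueError("need one selection file per exposure file")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns the report dictionary that is also written to
    ``<out_prefix>.report.json``.
    """
    for path in [config.outcome, *config.exposures, *config.selections]:
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    outcome = data_io.read_table(config.outcome)
    exposures = [data_io.read_table(p) for p in config.exposures]
    selections = [data_io.read_table(p) for p in config.selections]
    study = data_io.harmonize(outcome, exposures, selections)
    logger.info("harmonized study: %d SNPs, K = %d", study.n_snps, study.K)

    if config.sigma:
        sigma = SharedCorrelation.from_tsv(config.sigma)
        logger.info("loaded fixed Σ from %s", config.sigma)
    else:
        sigma = estimate_shared_correlation(study)
        logger.info("estimated Σ from %d null SNPs", sigma.n_null_snps)

    ld = data_io.read_ld_matrix(config.ld_matrix) if config.ld_matrix else None
    instruments = data_io.build_instrument_set(
        study, config.threshold, ld_r2=ld,
        r2_threshold=config.r2_instruments,
        assume_independent=config.assume_independent)
    logger.info("instrument set: %d SNPs at threshold %g",
                instruments.n_instruments, config.threshold)

    loss = RobustLoss(c=config.c_fit)
    fit = fit_effects(instruments=instruments, sigma=sigma, loss=loss)

    report: dict = {
        "n_snps_harmonized": study.n_snps,
        "K": study.K,
        "trait_names": study.trait_names,
        "threshold": config.threshold,
        "n_instruments": fit.n_instruments,
        "sigma": sigma.matrix.tolist(),
        "fit": {
            "beta_hat": fit.beta_hat.tolist(),
            "se": fit.se.tolist(),
            "ci": fit.ci.tolist(),
            "pvalues": fit.pvalues.tolist(),
            "tau2_hat": fit.tau2_hat,
            "converged": fit.converged,
        },
    }

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"SNP": fit.snp_ids, "t_residual": fit.t_residuals}).to_csv(
        f"{prefix}.residuals.tsv", sep="\t", index=False)

    if study.K == 1 and instruments.n_instruments > 0:
        profile = profile_curve(instruments, sigma, c=config.c_diag,
                                t0=config.t0)
        report["diagnosis"] = {
            "n_modes": profile.n_modes,
            "modes": [dataclasses.asdict(m) for m in profile.modes],
        }
        pd.DataFrame({"b": profile.grid, "l": profile.values}).to_csv(
            f"{prefix}.profile.tsv", sep="\t", index=False)
        if profile.n_modes:
            if ld is not None:
                combined = dict(zip(
                    study.snp_ids,
                    data_io.combined_selection_p(study.sel_pvalues)))
                candidates = data_io.ld_clump(
                    data_io.select_instruments(study, config.threshold),
                    combined, ld, config.r2_markers)
            else:
                candidates = instruments.selected_ids
            markers = select_markers(study, candidates, profile.modes,
                                     sigma, t0=config.t0, t1=config.t1)
            report["markers"] = {
                f"mode_{m}": ids for m, ids in enumerate(markers.markers)
            }
            report["marker_ratios"] = markers.ratios

    if config.run_sweep:
        sweep = threshold_sweep(
            study, sigma, thresholds=config.sweep_thresholds, ld_r2=ld,
            r2_threshold=config.r2_instruments,
            assume_independent=config.assume_independent, loss=loss)
        sweep.to_frame().to_csv(f"{prefix}.sweep.tsv", sep="\t", index=False)
        report["sweep"] = {
            "mean_modes": sweep.mean_modes,
            "combined_p": sweep.combined_p.tolist(),
            "skipped_thresholds": sweep.skipped,
        }

    with open(f"{prefix}.report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("report written to %s.report.json", prefix)
    return report
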