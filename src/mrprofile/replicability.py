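"""Stability of the causal estimate across instrument-selection thresholds.

Rather than committing to one selection p-value cutoff, the analysis is
repeated over a ladder of thresholds (default 1e-8 … 1e-2) and the
per-threshold significance is combined by a partial-conjunction rule:
reject only if the effect is significant at all but at most two of the
seven thresholds, giving combined p-value 5·p₍₃₎ with p₍₃₎ the
third-smallest per-threshold p-value.  The mean mode count across
thresholds summarizes how consistently a multi-pathway signal appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import HarmonizedStudy, build_instrument_set
from .fit import FitResult, RobustLoss, fit_effects
from .modes import profile_curve
from .shared_correlation import SharedCorrelation

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(10.0 ** e for e in range(-8, -1))  # 1e-8 … 1e-2


def partial_conjunction(pvalues) -> float:
    """Partial-conjunction combination of per-threshold p-values.

    For the standard 7-threshold design: min(1, 5·p₍₃₎), p₍₃₎ the third
    smallest — Bonferroni over the 5 remaining thresholds after allowing
    the effect to fail at any 2.  For S ≠ 7 inputs the same logic gives
    min(1, (S−2)·p₍₃₎), an extension of the published rule.
    """
    p = np.asarray(sorted(pvalues), dtype=float)
    if len(p) < 3:
        raise ValueError("partial conjunction needs at least 3 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(min(1.0, (len(p) - 2) * p[2]))


@dataclass
class ThresholdSweep:
    """Per-threshold fits and mode counts, plus the combined summary."""

    thresholds: list[float]
    fits: dict[float, FitResult]
    mode_counts: dict[float, int]
    combined_p: np.ndarray  # per-exposure partial-conjunction p-value
    mean_modes: float
    skipped: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for thr in self.thresholds:
            if thr in self.skipped:
                rows.append({"threshold": thr, "n_instruments": 0})
                continue
            fit = self.fits[thr]
            row = {"threshold": thr, "n_instruments": fit.n_instruments,
                   "tau2_hat": fit.tau2_hat, "n_modes": self.mode_counts[thr]}
            for k in range(len(fit.beta_hat)):
                row[f"beta_{k}"] = fit.beta_hat[k]
                row[f"se_{k}"] = fit.se[k]
                row[f"pvalue_{k}"] = fit.pvalues[k]
            rows.append(row)
        return pd.DataFrame(rows)


def threshold_sweep(
    study: HarmonizedStudy,
    sigma: SharedCorrelation | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    ld_r2: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    assume_independent: bool = False,
    loss: RobustLoss | None = None,
    diagnose_modes: bool = True,
) -> ThresholdSweep:
    """Re-select, re-clump, fit and mode-diagnose at every threshold.

    A threshold yielding too few instruments (p ≤ K) is skipped with a
    warning rather than failing the sweep.  The combined p-value uses the
    per-exposure per-threshold Wald p-values; skipped thresholds do not
    contribute.
    """
    thresholds = sorted(float(t) for t in thresholds)
    if len(thresholds) < 3:
        raise ValueError("a sweep needs at least 3 thresholds")
    sigma = sigma or SharedCorrelation.identity(study.K)

    fits: dict[float, FitResult] = {}
    mode_counts: dict[float, int] = {}
    skipped: list[float] = []
    for thr in thresholds:
        inst = build_instrument_set(study, thr, ld_r2=ld_r2,
                                    r2_threshold=r2_threshold,
                                    assume_independent=assume_independent)
        if inst.n_instruments <= study.K:
            logger.warning("threshold %g: only %d instruments; skipped",
                           thr, inst.n_instruments)
            skipped.append(thr)
            continue
        fits[thr] = fit_effects(instruments=inst, sigma=sigma, loss=loss)
        if diagnose_modes and study.K == 1:
            mode_counts[thr] = profile_curve(inst, sigma).n_modes
        else:
            mode_counts[thr] = 0

    if not fits:
        raise ValueError("every threshold was skipped; no fit possible")

    K = study.K
    combined = np.ones(K)
    usable = [fits[t].pvalues for t in thresholds if t in fits]
    if len(usable) >= 3:
        per_exposure = np.array(usable)  # (S_used, K)
        combined = np.array([partial_conjunction(per_exposure[:, k])
                             for k in range(K)])
    mean_modes = float(np.mean([mode_counts[t] for t in thresholds
                                if t in fits])) if mode_counts else 0.0
    return ThresholdSweep(thresholds=thresholds, fits=fits,
                          mode_counts=mode_counts, combined_p=combined,
                          mean_modes=mean_modes, skipped=skipped)
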