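"""Multi-modality diagnosis of the robust profile likelihood.

With a redescending loss, instruments acting through distinct pleiotropic
pathways pile up at distinct per-SNP ratios Γ̂_j/γ̂_j, and each pile
produces a local maximum of l(b) = −Σ_j ρ_c(t_j(b, 0)).  A SNP associated
with the exposure only through a confounding pathway with effect κ on the
outcome and association δ with the exposure contributes to a mode at
β + κ/δ instead of β.  The diagnostic therefore runs at τ² = 0 with a
sharper loss constant (c = 3 by default) than the fit, trading efficiency
for mode sensitivity.

The same curve diagnoses causal direction: refitting with the roles of
exposure and outcome swapped, a truly downstream "exposure" produces two
modes — one near 0 (variants hitting the true outcome directly) and one
near the reciprocal of the forward effect (variants acting through the
true exposure) — whereas the correct direction stays unimodal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import HarmonizedStudy, InstrumentSet
from .fit import profile_t_vec, tukey_rho
from .shared_correlation import SharedCorrelation

logger = logging.getLogger(__name__)

DEFAULT_C_DIAG = 3.0
DEFAULT_GRID_POINTS = 2001
MERGE_BANDWIDTH_STEPS = 5  # neighbouring grid maxima closer than this merge


@dataclass
class Mode:
    position: float
    height: float
    n_markers: int
    likely_outlier: bool = False


@dataclass
class LikelihoodProfile:
    """l(b) on a grid, with its detected local maxima."""

    grid: np.ndarray
    values: np.ndarray
    c: float
    modes: list[Mode] = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def mode_positions(self) -> np.ndarray:
        return np.array([m.position for m in self.modes])

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else 0.0


@dataclass
class ModeMarkers:
    """Residual matrix over candidate SNPs × modes, and the marker sets."""

    snp_ids: list[str]
    mode_positions: np.ndarray
    residuals: np.ndarray  # (len(G), M): r_jm = t_j(β_m, 0)
    markers: list[list[str]]  # per-mode marker SNP ids, disjoint
    ratios: dict[str, float]  # Γ̂_j/γ̂_j of every marker, for reporting
    t0: float
    t1: float


def _study_of(study_or_instruments) -> HarmonizedStudy:
    if isinstance(study_or_instruments, InstrumentSet):
        return study_or_instruments.study()
    return study_or_instruments


def profile_curve(
    study: HarmonizedStudy | InstrumentSet,
    sigma: SharedCorrelation | None = None,
    c: float = DEFAULT_C_DIAG,
    grid: np.ndarray | None = None,
    n_points: int = DEFAULT_GRID_POINTS,
    min_support: int = 2,
    t0: float = 1.0,
) -> LikelihoodProfile:
    """Evaluate l(b) = −Σ ρ_c(t_j(b, 0)) over a grid of candidate effects.

    The default grid spans the 2.5%–97.5% quantiles of the per-SNP ratios
    Γ̂_j/γ̂_j, widened by 50% on each side, at ``n_points`` points — wide
    enough to contain every ratio cluster a pathway could produce.  Only
    the single-exposure diagnosis is defined.
    """
    data = _study_of(study)
    if data.K != 1:
        raise ValueError("the multi-modality diagnosis is defined for K = 1")
    if data.n_snps == 0:
        raise ValueError("no instruments to profile")
    sigma = sigma or SharedCorrelation.identity(1)

    if grid is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = data.Gamma / data.gamma[:, 0]
        ratios = ratios[np.isfinite(ratios)]
        lo, hi = np.quantile(ratios, [0.025, 0.975])
        if hi <= lo + 1e-12:
            logger.warning("degenerate ratio distribution; single-point profile")
            g = np.array([lo])
            vals = np.array([-np.sum(tukey_rho(profile_t_vec(
                data.Gamma, data.gamma, data.se_Gamma, data.se_gamma,
                np.array([lo]), 0.0, sigma.matrix), c))])
            return LikelihoodProfile(grid=g, values=vals, c=c, degenerate=True)
        half = 0.5 * (hi - lo)
        grid = np.linspace(lo - half, hi + half, n_points)
    grid = np.asarray(grid, dtype=float)

    # vectorized over the grid: residual and variance are affine/quadratic in b
    g1 = data.gamma[:, 0]
    sx, sy = data.se_gamma[:, 0], data.se_Gamma
    theta = sigma.matrix[0, 1]
    resid = data.Gamma[:, None] - np.outer(g1, grid)
    var = (sy ** 2)[:, None] + np.outer(sx ** 2, grid ** 2) \
        - 2.0 * np.outer(sx * sy * theta, grid)
    if np.any(var <= 0):
        raise ValueError("nonpositive profile variance on the grid; Σ invalid")
    values = -np.sum(tukey_rho(resid / np.sqrt(var), c), axis=0)

    profile = LikelihoodProfile(grid=grid, values=values, c=c)
    profile.modes = find_modes(profile, min_support=min_support,
                               study=data, sigma=sigma, t0=t0)
    return profile


def find_modes(
    profile: LikelihoodProfile,
    min_support: int = 2,
    study: HarmonizedStudy | None = None,
    sigma: SharedCorrelation | None = None,
    t0: float = 1.0,
) -> list[Mode]:
    """Local maxima of the gridded curve, merged within one bandwidth.

    A grid point is a mode when strictly greater than both neighbours;
    maxima closer than ``MERGE_BANDWIDTH_STEPS`` grid steps are merged
    (keeping the higher).  When the study is supplied, each mode's support
    is the number of SNPs with |t_j(β_m, 0)| ≤ t0; modes supported by
    fewer than ``min_support`` SNPs are flagged as likely outliers — a
    single aberrant SNP can carve its own bump into a redescending loss —
    but are still reported.
    """
    if profile.degenerate or len(profile.grid) < 3:
        raise ValueError("profile is degenerate; mode detection undefined")
    v = profile.values
    idx = np.where((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1

    merged: list[int] = []
    for i in idx:
        if merged and i - merged[-1] < MERGE_BANDWIDTH_STEPS:
            if v[i] > v[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)

    modes = []
    for i in merged:
        pos, height = float(profile.grid[i]), float(v[i])
        n_support = 0
        if study is not None:
            t = profile_t_vec(study.Gamma, study.gamma, study.se_Gamma,
                              study.se_gamma, np.array([pos]), 0.0,
                              (sigma or SharedCorrelation.identity(1)).matrix)
            n_support = int(np.sum(np.abs(t) <= t0))
        modes.append(Mode(position=pos, height=height, n_markers=n_support,
                          likely_outlier=(study is not None
                                          and n_support < min_support)))
    modes.sort(key=lambda m: m.position)
    return modes


def select_markers(
    study: HarmonizedStudy,
    candidate_ids: list[str],
    modes: list[Mode] | np.ndarray,
    sigma: SharedCorrelation | None = None,
    t0: float = 1.0,
    t1: float = 2.0,
) -> ModeMarkers:
    """Assign marker SNPs to modes by the residual rule.

    SNP j (from a candidate set G, clumped at a looser r² ≤ 0.05 than the
    instruments so that biologically informative SNPs are not pruned away)
    is a marker for mode m iff |r_jm| ≤ t0 and |r_jm′| > t1 for every other
    mode m′, where r_jm = t_j(β_m, 0).  With t0 < t1 the marker sets are
    disjoint by construction, which is asserted.
    """
    if len(modes) == 0:
        raise ValueError("no modes to assign markers to")
    if len(candidate_ids) == 0:
        raise ValueError("empty candidate SNP set G")
    positions = np.array([m.position if isinstance(m, Mode) else float(m)
                          for m in modes])
    sub = study.subset(candidate_ids)
    sigma = sigma or SharedCorrelation.identity(study.K)

    residuals = np.column_stack([
        profile_t_vec(sub.Gamma, sub.gamma, sub.se_Gamma, sub.se_gamma,
                      np.array([pos]), 0.0, sigma.matrix, sub.snp_ids)
        for pos in positions
    ])
    markers = assign_markers(residuals, t0=t0, t1=t1)
    marker_ids = [[sub.snp_ids[j] for j in idx] for idx in markers]

    flat = [s for ids in marker_ids for s in ids]
    assert len(flat) == len(set(flat)), "marker sets must be disjoint"

    with np.errstate(divide="ignore", invalid="ignore"):
        all_ratios = sub.Gamma / sub.gamma[:, 0]
    ratios = {sid: float(all_ratios[j]) for j, sid in enumerate(sub.snp_ids)
              if sid in set(flat)}
    return ModeMarkers(snp_ids=sub.snp_ids, mode_positions=positions,
                       residuals=residuals, markers=marker_ids,
                       ratios=ratios, t0=t0, t1=t1)


def assign_markers(residuals: np.ndarray, t0: float = 1.0,
                   t1: float = 2.0) -> list[list[int]]:
    """Pure residual-matrix form of the marker rule (indices per mode)."""
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, M = residuals.shape
    out: list[list[int]] = [[] for _ in range(M)]
    absr = np.abs(residuals)
    for j in range(n):
        close = absr[j] <= t0
        for m in range(M):
            others = np.delete(absr[j], m)
            if close[m] and np.all(others > t1):
                out[m].append(j)
    return out


@dataclass
class DirectionReport:
    """Mode structure of the profile likelihood in both causal directions."""

    forward: LikelihoodProfile
    reverse: LikelihoodProfile
    call: str  # "forward", "reverse", or "inconclusive"
    reverse_null_mode: float | None = None
    reverse_reciprocal_mode: float | None = None

    def summary(self) -> str:
        lines = [
            f"forward profile: {self.forward.n_modes} mode(s) at "
            f"{np.round(self.forward.mode_positions, 3).tolist()}",
            f"reverse profile: {self.reverse.n_modes} mode(s) at "
            f"{np.round(self.reverse.mode_positions, 3).tolist()}",
            f"direction call: {self.call}",
        ]
        if self.reverse_null_mode is not None:
            lines.append(f"reverse mode near 0: {self.reverse_null_mode:.3f}")
        if self.reverse_reciprocal_mode is not None:
            lines.append("reverse mode near reciprocal of forward estimate: "
                         f"{self.reverse_reciprocal_mode:.3f}")
        return "\n".join(lines)


def direction_diagnostic(
    forward: HarmonizedStudy | InstrumentSet,
    reverse: HarmonizedStudy | InstrumentSet,
    sigma_forward: SharedCorrelation | None = None,
    sigma_reverse: SharedCorrelation | None = None,
    c: float = DEFAULT_C_DIAG,
    null_tol: float = 0.25,
) -> DirectionReport:
    """Compare mode structure with exposure/outcome roles swapped.

    The direction whose profile is unimodal is labelled causally
    consistent.  In the reverse profile the mode nearest 0 (within
    ``null_tol``) and the mode nearest the reciprocal of the forward
    mode position are annotated.  If both directions are multimodal the
    call is "inconclusive" — never forced.
    """
    fwd = profile_curve(forward, sigma_forward, c=c)
    rev = profile_curve(reverse, sigma_reverse, c=c)

    f_modes, r_modes = fwd.n_modes, rev.n_modes
    if f_modes == 1 and r_modes > 1:
        call = "forward"
    elif r_modes == 1 and f_modes > 1:
        call = "reverse"
    elif f_modes == 1 and r_modes == 1:
        call = "forward"  # both unimodal: no contrary evidence
    else:
        call = "inconclusive"

    null_mode = reciprocal_mode = None
    if r_modes >= 1:
        pos = rev.mode_positions
        near0 = np.abs(pos).argmin()
        if abs(pos[near0]) <= null_tol:
            null_mode = float(pos[near0])
        if f_modes >= 1:
            fpos = fwd.mode_positions[np.argmax([m.height for m in fwd.modes])]
            if abs(fpos) > 1e-8:
                recip = 1.0 / fpos
                j = np.abs(pos - recip).argmin()
                if j != near0 or null_mode is None:
                    reciprocal_mode = float(pos[j])
    return DirectionReport(forward=fwd, reverse=rev, call=call,
                           reverse_null_mode=null_mode,
                           reverse_reciprocal_mode=reciprocal_mode)
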