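"""Three-cohort GWAS summary-statistics simulator.

Generates per-SNP summary statistics from the structural model behind the
estimator: true marginal associations γ_j (spike-and-slab), horizontal
pleiotropy α_j (random InSIDE effects, optionally correlated with γ_j,
optionally grouped into confounding pathways), outcome associations
Γ_j = γ_jᵀβ + α_j, and noisy estimates drawn from the multivariate normal
sampling law with per-SNP standard errors implied by cohort sizes and
allele frequencies.  A third, independent selection cohort supplies the
selection p-values, so the three-sample property (no winner's curse in
the estimation cohorts) holds by construction.

Pathway SNPs act on the exposure only through a confounding pathway with
outcome effect κ and exposure association δ: their truth satisfies
γ_j = δ·γ̃_j and Γ_j = (β + κ/δ)·γ_j + α̃_j, so they concentrate at ratio
β + κ/δ and produce a second likelihood mode there.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs (every SNP is independent; LD enters only through user-supplied toy
r² matrices in clumping tests), population stratification, and
individual-genotype sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data_io import HarmonizedStudy, SNPRecord

# non-palindromic allele pairs only, so harmonization keeps every SNP
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class Pathway:
    """A confounding genetic pathway: outcome effect κ, exposure slope δ,
    and the fraction of SNPs acting purely through it."""

    kappa: float
    delta: float
    fraction: float

    @property
    def mode_location(self) -> float:
        if self.delta == 0:
            raise ValueError(
                "pathway with delta = 0 has no finite mode location kappa/delta"
            )
        return self.kappa / self.delta


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for one synthetic three-cohort study.

    Cohort sizes default to 100 000 per cohort with no overlap; SNP effect
    sizes are spike-and-slab per-allele associations on a standardized
    trait scale, giving selection Z-scores spanning weak to strong
    instruments at the default ``gamma_scale``.
    """

    p_total: int = 300
    K: int = 1
    beta: tuple = (1.0,)
    tau2: float = 0.0
    correlated_a: float = 0.0  # slope of α_j on γ_j1 (InSIDE violation)
    pathways: tuple = ()  # Pathway instances; fractions must sum < 1
    direct_outcome_fraction: float = 0.0  # SNPs with γ = 0, Γ ≠ 0
    direct_outcome_scale: float = 0.05
    gamma_nonzero_prob: float = 1.0
    gamma_scale: float = 0.03
    n_exposure: tuple = (100_000,)
    n_outcome: int = 100_000
    n_selection: tuple = (100_000,)
    n_overlap: tuple = (0,)  # samples shared between each exposure and outcome
    overlap_corr: float = 0.0  # per-sample Corr[Y_s, X_ks]
    n_null_snps: int = 0  # extra null SNPs appended (for Σ estimation)
    outcome_is_binary: bool = False
    attenuation: float = 1.0  # >1 shrinks Γ, the binary-outcome caveat
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta) != self.K or len(self.n_exposure) != self.K \
                or len(self.n_selection) != self.K or len(self.n_overlap) != self.K:
            raise ValueError("beta, n_exposure, n_selection, n_overlap must "
                             "all have length K")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        frac = sum(p.fraction for p in self.pathways) + self.direct_outcome_fraction
        if not 0 <= frac <= 1:
            raise ValueError("pathway + direct-outcome fractions must stay in [0,1]")
        for k in range(self.K):
            if self.n_overlap[k] > min(self.n_exposure[k], self.n_outcome):
                raise ValueError("overlap cannot exceed either cohort size")
        for p in self.pathways:
            if p.delta == 0:
                p.mode_location  # raises


@dataclass
class SimulatedStudy:
    """A generated study together with its truth layer."""

    config: SimulationConfig
    study: HarmonizedStudy
    gamma_true: np.ndarray  # (p, K)
    Gamma_true: np.ndarray  # (p,)
    alpha_true: np.ndarray  # (p,)
    pathway_index: np.ndarray  # -1 ordinary, 0.. pathway id, -2 direct-outcome
    outcome_sel_pvalues: np.ndarray  # independent outcome-cohort selection p

    def reverse_study(self) -> HarmonizedStudy:
        """Role-swapped study: the outcome becomes the exposure.

        Uses the independent outcome selection cohort for instrument
        selection, mirroring how a reverse analysis would be run.
        """
        if self.config.K != 1:
            raise ValueError("reverse analysis defined for K = 1")
        fwd = self.study
        records = [
            SNPRecord(
                snp_id=r.snp_id, effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                gamma_hat=np.array([r.Gamma_hat]),
                se_gamma=np.array([r.se_Gamma]),
                Gamma_hat=float(r.gamma_hat[0]),
                se_Gamma=float(r.se_gamma[0]),
                sel_pvalues=np.array([self.outcome_sel_pvalues[j]]),
            )
            for j, r in enumerate(fwd.records)
        ]
        return HarmonizedStudy(
            records=records,
            trait_names=[fwd.trait_names[1], fwd.trait_names[0]],
        )


def sampling_correlation(config: SimulationConfig) -> np.ndarray:
    """The shared error-correlation Σ implied by cohort overlap:
    Σ[0, k] = N_sk/√(N_ek·N_o)·Corr[Y_s, X_ks]."""
    K = config.K
    sigma = np.eye(K + 1)
    for k in range(K):
        rho = (config.n_overlap[k]
               / np.sqrt(config.n_exposure[k] * config.n_outcome)
               * config.overlap_corr)
        sigma[0, k + 1] = sigma[k + 1, 0] = rho
    return sigma


def _standard_errors(n: float, freq: np.ndarray) -> np.ndarray:
    # per-allele association SE for a standardized trait
    return 1.0 / np.sqrt(2.0 * n * freq * (1.0 - freq))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one three-cohort summary-statistics dataset from the truth."""
    rng = np.random.default_rng(config.seed)
    K = config.K
    p = config.p_total + config.n_null_snps
    beta = np.asarray(config.beta, dtype=float)

    freq = rng.uniform(0.05, 0.5, size=p)
    se_gamma = np.column_stack([_standard_errors(config.n_exposure[k], freq)
                                for k in range(K)])
    se_Gamma = _standard_errors(config.n_outcome, freq)
    se_sel = np.column_stack([_standard_errors(config.n_selection[k], freq)
                              for k in range(K)])

    # --- truth layer -------------------------------------------------------
    nonzero = rng.random((p, K)) < config.gamma_nonzero_prob
    gamma = np.where(nonzero, rng.normal(0.0, config.gamma_scale, (p, K)), 0.0)

    pathway_index = np.full(p, -1, dtype=int)
    cursor = config.p_total
    counts = [int(round(pw.fraction * config.p_total)) for pw in config.pathways]
    n_direct = int(round(config.direct_outcome_fraction * config.p_total))
    start = 0
    for i, n_i in enumerate(counts):
        pathway_index[start:start + n_i] = i
        start += n_i
    pathway_index[start:start + n_direct] = -2
    if config.n_null_snps:
        gamma[config.p_total:] = 0.0
        pathway_index[config.p_total:] = -3  # appended null panel

    alpha_tilde = rng.normal(0.0, np.sqrt(config.tau2), p) if config.tau2 > 0 \
        else np.zeros(p)
    alpha = alpha_tilde + config.correlated_a * gamma[:, 0]

    Gamma = gamma @ beta + alpha
    for i, pw in enumerate(config.pathways):
        mask = pathway_index == i
        gamma_tilde = rng.normal(0.0, config.gamma_scale / abs(pw.delta),
                                 mask.sum())
        gamma[mask, 0] = pw.delta * gamma_tilde
        if K > 1:
            gamma[mask, 1:] = 0.0
        Gamma[mask] = (beta[0] + pw.mode_location) * gamma[mask, 0] \
            + alpha_tilde[mask]
    direct = pathway_index == -2
    if direct.any():
        gamma[direct] = 0.0
        Gamma[direct] = rng.normal(0.0, config.direct_outcome_scale,
                                   direct.sum())
    null = pathway_index == -3
    if null.any():
        Gamma[null] = 0.0
    if config.attenuation != 1.0:
        Gamma = Gamma / config.attenuation

    # --- estimation cohorts: correlated errors from cohort overlap ---------
    sigma = sampling_correlation(config)
    L = np.linalg.cholesky(sigma)
    z = rng.standard_normal((p, K + 1)) @ L.T
    Gamma_hat = Gamma + z[:, 0] * se_Gamma
    gamma_hat = gamma + z[:, 1:] * se_gamma

    # --- independent selection cohorts -------------------------------------
    gamma_sel = gamma + rng.standard_normal((p, K)) * se_sel
    sel_p = 2.0 * stats.norm.sf(np.abs(gamma_sel / se_sel))
    out_sel_se = _standard_errors(config.n_outcome, freq)
    Gamma_sel = Gamma + rng.standard_normal(p) * out_sel_se
    outcome_sel_p = 2.0 * stats.norm.sf(np.abs(Gamma_sel / out_sel_se))

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), p)
    width = len(str(p))
    records = [
        SNPRecord(
            snp_id=f"rs{j + 1:0{width}d}",
            effect_allele=_ALLELE_PAIRS[pair_idx[j]][0],
            other_allele=_ALLELE_PAIRS[pair_idx[j]][1],
            gamma_hat=gamma_hat[j], se_gamma=se_gamma[j],
            Gamma_hat=float(Gamma_hat[j]), se_Gamma=float(se_Gamma[j]),
            sel_pvalues=sel_p[j],
        )
        for j in range(p)
    ]
    study = HarmonizedStudy(
        records=records,
        trait_names=["outcome"] + [f"exposure{k + 1}" for k in range(K)],
        outcome_is_binary=config.outcome_is_binary,
    )
    return SimulatedStudy(config=config, study=study, gamma_true=gamma,
                          Gamma_true=Gamma, alpha_true=alpha,
                          pathway_index=pathway_index,
                          outcome_sel_pvalues=outcome_sel_p)


#: documented scenario catalogue; every acceptance-suite simulation starts here
FIXTURES: dict[str, SimulationConfig] = {
    # the "same trait in two disjoint cohorts" construction: Γ_j = γ_j, β = 1
    "no-pleiotropy": SimulationConfig(p_total=300, beta=(1.0,), tau2=0.0),
    # pervasive random pleiotropy at the scale of the outcome's noise
    "inside-pleiotropy": SimulationConfig(p_total=300, beta=(0.5,),
                                          tau2=2.5e-5),
    # one confounding pathway: second ratio cluster at β + κ/δ = 0.7
    "one-pathway": SimulationConfig(
        p_total=200, beta=(0.2,), tau2=0.0, gamma_scale=0.08,
        n_exposure=(200_000,), n_outcome=200_000, n_selection=(200_000,),
        n_overlap=(0,), pathways=(Pathway(kappa=0.3, delta=0.6, fraction=0.35),),
    ),
    # two pathways: truth-layer ratio clusters at 0.2, 0.7 and −0.4
    "two-pathway": SimulationConfig(
        p_total=300, beta=(0.2,), tau2=0.0, gamma_scale=0.08,
        n_exposure=(200_000,), n_outcome=200_000, n_selection=(200_000,),
        n_overlap=(0,),
        pathways=(Pathway(kappa=0.3, delta=0.6, fraction=0.25),
                  Pathway(kappa=-0.24, delta=0.4, fraction=0.25)),
    ),
    # half the outcome's variants bypass the exposure entirely: reversing
    # exposure/outcome roles must split the likelihood into modes at 0 and 1/β
    "reverse-direction": SimulationConfig(
        p_total=300, beta=(0.5,), tau2=0.0, gamma_scale=0.08,
        n_exposure=(200_000,), n_outcome=200_000, n_selection=(200_000,),
        n_overlap=(0,), direct_outcome_fraction=0.5,
        direct_outcome_scale=0.08,
    ),
    # fully shared cohort with per-sample trait correlation 0.5
    "overlapping-cohorts": SimulationConfig(
        p_total=300, beta=(0.5,), tau2=0.0,
        n_overlap=(100_000,), overlap_corr=0.5, n_null_snps=2000,
    ),
}


def make_fixture(name: str, seed: int = 0, **overrides) -> SimulatedStudy:
    """Instantiate a catalogued scenario with a given seed.

    ``overrides`` replace config fields (e.g. ``p_total``); the catalogue
    defaults are the documented study conditions.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"choose from {sorted(FIXTURES)}")
    config = replace(FIXTURES[name], seed=seed, **overrides)
    return simulate_study(config)
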