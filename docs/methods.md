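# Methods

## Model and estimand

For each of p independent genetic instruments the observed summary
statistics (Γ̂_j, γ̂_j) — outcome association and K exposure associations
— are modelled as multivariate normal around true values (Γ_j, γ_j) with
covariance Σ_j = D_j Σ D_j, D_j = diag(σ_Yj, σ_Xj1, …, σ_XjK). Σ is a
single (K+1)×(K+1) correlation matrix shared by all SNPs: the correlation
of estimation errors induced by overlapping GWAS cohorts, equal to
N_sk/√(N_ek·N_o)·Corr[Y_s, X_ks] for the overlap of exposure-k and
outcome cohorts. The structural assumption is linear in the marginal
associations,

    Γ_j = γ_jᵀ β + α_j ,

with α_j the horizontal pleiotropic effect. Pervasive pleiotropy is
modelled as α_j ~ N(0, τ²) independent of γ_j (the InSIDE assumption);
the robust loss additionally tolerates a minority of SNPs for which this
fails outright. For binary outcomes the same linear relation holds
approximately on the log-odds scale with β conservatively attenuated by a
constant factor; estimates are reported on that attenuated scale and no
de-attenuation is attempted.

Profiling the nuisance γ_j out of the Gaussian likelihood leaves the
per-SNP standardized residual

    t_j(β, τ²) = (Γ̂_j − γ̂_jᵀβ) / √(σ_Yj² + βᵀΣ_Xjβ − 2βᵀΣ_XjYj + τ²),

where Σ_Xj is the exposure block of Σ_j and Σ_XjYj its exposure–outcome
column. t_j is standard normal at the truth; every downstream quantity is
a function of it.

## Estimation

The adjusted robust profile likelihood is l(β, τ²) = −Σ_j ρ(t_j) with ρ
Tukey's biweight, ρ(r) = c²/6·[1 − (1 − (r/c)²)³] for |r| ≤ c and c²/6
beyond, at the 95%-efficiency constant c = 4.6851. β̂ maximizes l at
τ² = τ̂², and τ̂² solves the moment condition

    Σ_j ρ(t_j(β̂, τ²)) = p·η ,    η = E[ρ(Z)], Z ~ N(0,1),

which has zero expectation exactly when the residuals are standard
normal, so it estimates τ² consistently where naive joint maximization
would not. η is computed once per c by adaptive quadrature (absolute
accuracy better than 1e-10); tests cross-check it against a closed form
built from truncated normal moments and against independent Gauss–Legendre
quadrature.

Numerically the solver alternates (i) minimization of Σρ(t_j) over β at
fixed τ² — Brent's method for K = 1, BFGS with the analytic gradient for
K > 1 — with (ii) one-dimensional root finding (Brent) of the moment
condition in τ², whose left side is strictly decreasing in τ². The root
bracket starts at max_j Γ̂_j² and expands geometrically; if the equation
is already below target at τ² = 0 the estimate is floored at 0. Iteration
stops when the joint update moves less than 1e-8, with a 100-iteration
budget; non-convergence is flagged on the result, never silent. Because
the redescending loss saturates away from the data, a line search can
terminate on the flat plateau; an update is therefore never accepted if
it increases the objective. The objective is non-convex, so optimization
restarts from the 10%–90% quantiles of the per-SNP ratios Γ̂_j/γ̂_j
(K = 1) or from the error-naive weighted least-squares solution plus
random perturbations (K > 1). Among the converged candidates the one with
the smallest τ̂² wins (objective value breaking ties at τ̂² = 0): at any
joint solution with τ̂² > 0 the robustified likelihood equals p·η
identically, so overdispersion — how much extra variance the mode needs
to explain the data — is the meaningful ranking.

Variances come from the M-estimation sandwich on the stacked score
ψ_j = (−ρ′(t_j)·∂t_j/∂β, ρ(t_j) − η): Var(θ̂) = A⁻¹BA⁻ᵀ/p with A the
Jacobian of the mean score (central finite differences, relative step
1e-5) and B the empirical outer product. When τ̂² sits on the boundary at
0 the τ² equation is dropped and the sandwich runs on the β block alone.
Confidence intervals are Wald with normal quantiles.

## Instrument selection and Σ estimation

Instruments come from an independent selection cohort per exposure (the
three-sample design): SNP j is a candidate when the Bonferroni-combined
selection p-value K·min_k(p_jk), capped at 1, passes the threshold.
Candidates are pruned to pairwise independence by greedy LD clumping
(keep the smallest combined p, drop everything with r² > 0.001 to a kept
SNP, repeat); a missing r² entry is a hard error rather than a silent
independence assumption, and the library requires either an LD matrix or
an explicit `assume_independent=True` (simulated SNPs are independent by
construction). Clumping ranks by selection-cohort p-values so that
selection never touches the estimation cohorts.

Σ is estimated as the sample correlation of the T×(K+1) matrix of
Z-values over SNPs whose selection p-values are ≥ 0.5 for every exposure
(null for all exposures, hence pure noise), requiring at least 100 such
SNPs (configurable). The null panel is taken before clumping: correlated
null SNPs reduce the effective T but do not bias the correlation. An
indefinite plug-in estimate is projected to the nearest positive
semidefinite correlation matrix by eigenvalue clipping at 1e-6 and
rescaling to unit diagonal (logged). The null panel is not LD-pruned
first; with the panel sizes involved the loss of effective sample size is
immaterial and the choice is documented rather than hidden.

## Multi-modality diagnosis

The diagnostic curve is l(b) = −Σ_j ρ_c(t_j(b, 0)) for a single exposure,
at τ² = 0 and c = 3 — sharper than the fitting constant so that SNP
subpopulations at different ratios separate instead of blurring into one
bump. A SNP associated with the exposure only through a confounding
pathway (outcome effect κ, exposure association δ) satisfies
γ_j = δγ̃_j and Γ_j = (β + κ/δ)γ_j + α̃_j, so such SNPs support a mode at
β + κ/δ. The grid spans the 2.5%–97.5% quantiles of the ratios Γ̂_j/γ̂_j
widened by 50% on each side, at 2 001 points — enough to resolve modes
separated by about 1% of the plausible effect range. Grid construction
and resolution are this package's choices; there is no canonical
prescription. Local maxima (strictly greater than both neighbours) closer
than 5 grid steps are merged, keeping the higher: floating-point ripple
on a flat top otherwise fabricates twin modes. A mode's support is the
number of SNPs with |t_j(β_m, 0)| ≤ t0; modes with fewer than 2
supporters are flagged likely-outlier — a single aberrant precise SNP can
carve its own bump into a redescending loss — but still reported, with no
formal test for the number of modes attempted.

Marker SNPs are drawn from a candidate set clumped at the looser
r² ≤ 0.05 so that informative loci are not pruned away: SNP j is a marker
for mode m iff |r_jm| ≤ t0 and |r_jm′| > t1 for **every** other mode m′
(defaults t0 = 1, t1 = 2). The exclusion quantifier is deliberately
universal — it is what makes marker sets disjoint across modes, which the
code asserts on every run. Mode heights are reported but carry no
significance claim.

Direction diagnosis fits the profile both ways. The direction whose curve
is unimodal is labelled causally consistent; in the reverse direction the
mode near 0 (variants reaching the true outcome directly) and the mode
near the reciprocal of the forward estimate (variants acting through the
true exposure) are annotated. Two multimodal directions yield
"inconclusive", never a forced call.

## Threshold sweep and replicability

The analysis is repeated over selection thresholds 1e-8 … 1e-2 (seven by
default). A threshold selecting p ≤ K instruments is skipped with a
warning, not a failure. Per-exposure Wald p-values across the seven
thresholds combine as the partial-conjunction p-value min(1, 5·p₍₃₎),
p₍₃₎ the third smallest: rejection requires the effect to replicate at
all but at most two thresholds. The cap at 1 and the generalization
(S−2)·p₍₃₎ for S ≠ 7 user-supplied thresholds are this package's
extensions. The mean mode count across thresholds summarizes pathway
evidence; single-SNP outlier modes are included in that mean (they are
flagged at the per-threshold level where the user can see them).

## Synthetic data

The generator emulates the full three-cohort design. Per SNP: allele
frequency f ~ U(0.05, 0.5); true γ_j spike-and-slab normal
(default scale 0.03, all-nonzero); pleiotropy α_j = a·γ_j1 + α̃_j with
α̃_j ~ N(0, τ²); pathway SNPs overridden to γ_j = δγ̃_j,
Γ_j = (β + κ/δ)γ_j + α̃_j; optional direct-outcome SNPs (γ = 0, Γ ≠ 0)
for the reverse-direction scenario. Standard errors follow the
per-allele law 1/√(2Nf(1−f)) for a standardized trait — any positive SE
law satisfies the sampling model, and this one gives realistic
heterogeneity of instrument strength. Estimation-cohort errors are drawn
jointly with the overlap correlation N_s/√(N_e·N_o)·Corr[Y_s, X_ks]; the
selection cohort is always independent. A binary-outcome option divides
Γ by a constant attenuation factor to exercise the conservative-scale
caveat. Everything is reproducible from a single seed, byte-identically.

Defaults are 300 SNPs and cohorts of 100 000, giving selection Z-scores
mostly in the 3–7 range — moderate instruments of which roughly two
thirds pass a 1e-2 threshold. Pathway and direction scenarios use scale
0.08 and cohorts of 200 000 so that ratio clusters are tight enough for
mode detection at the documented grid resolution; these are the study
conditions the acceptance checks run at. What the generator does **not**
emulate: LD between SNPs (instruments are independent by construction, so
clumping is exercised only on toy r² matrices), population structure,
allele-frequency-dependent architectures, and nonlinear structural
equations (the linear relation above holds regardless of the structural
form, and the generator instantiates the linear case). Passing tests
therefore demonstrate correctness of the estimator under its stated
sampling model, not robustness to LD misspecification.

## Acceptance checks

`scripts/acceptance.py --seed S --out F` recomputes, from scratch at each
run: (t1) the mean β̂ over 100 no-pleiotropy replicates with Γ_j = γ_j
(true β = 1) at selection threshold 1e-2 — checks weak-instrument
unbiasedness; (t2) empirical 95% CI coverage over 500 replicates with
small uncorrelated pleiotropy (true β = 0.5, τ² = 2.5e-5) — checks the
sandwich calibration, expected in [0.92, 0.98] by binomial noise. Both
derive every replicate seed from `--seed`. The test suite additionally
verifies reverse-direction bimodality (50 replicates, ≥90% with exactly
two modes and one within 0.05 of zero), oracle equivalences (grid-search
maximizer, brute-force clumping, quadrature η, Monte-Carlo variance of
the profile denominator), the β + κ/δ mode-location law over a (κ, δ)
grid, exact marker assignment on hand-enumerated residual matrices, and
the partial-conjunction arithmetic.

## Known limitations

- The diagnosis (modes, markers, direction) is defined for a single
  exposure; multivariable fits share all other machinery.
- Wald intervals rely on the sandwich at an interior τ̂²; at the τ̂² = 0
  boundary the τ² score is dropped, which is slightly conservative.
- Mode detection has no significance test; the likely-outlier flag and
  the cross-threshold mean mode count are the intended evidence summary.
- No genome-build handling, VCF parsing, reference-panel LD computation,
  or annotation services; inputs are plain per-trait summary tables.
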