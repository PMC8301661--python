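"""Estimate and use the cohort-overlap correlation Σ.

When the exposure and outcome GWAS share participants, the sampling
errors of the two association estimates are correlated.  The scenario
fully overlaps the two cohorts of 100 000 samples with per-sample trait
correlation 0.5; SNPs that are null for the exposure (all selection
p-values ≥ 0.5) reveal that correlation in their Z-values.
"""

from mrprofile import (
    build_instrument_set,
    estimate_shared_correlation,
    fit_effects,
    make_fixture,
)

sim = make_fixture("overlapping-cohorts", seed=5)
sigma = estimate_shared_correlation(sim.study)
print(f"null panel size: {sigma.n_null_snps} SNPs")
print(f"estimated overlap correlation theta = {sigma.theta:.3f} "
      f"(generative truth 0.5)")

instruments = build_instrument_set(sim.study, 1e-2, assume_independent=True)
with_sigma = fit_effects(instruments=instruments, sigma=sigma)
print("\nfit accounting for overlap:")
print(with_sigma.summary())
print("\nignoring a positive overlap correlation would misweight the "
      "per-SNP variances; passing the estimated Σ keeps the profile "
      "residuals standard normal under the truth.")
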