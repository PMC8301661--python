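"""Replicability of the estimate across instrument-selection thresholds.

Re-selects, re-fits and mode-diagnoses at seven p-value cutoffs from 1e-8
to 1e-2 and combines the per-threshold significance into one
partial-conjunction p-value: significant only if the effect replicates at
all but at most two thresholds.
"""

from mrprofile import make_fixture, threshold_sweep

sim = make_fixture("no-pleiotropy", seed=30, beta=(0.5,))
sweep = threshold_sweep(sim.study, assume_independent=True)

print(sweep.to_frame().to_string(index=False,
                                 float_format=lambda v: f"{v:.4g}"))
print(f"\nmean mode count across thresholds: {sweep.mean_modes:.2f} "
      f"(1.0 = consistently unimodal, no pathway signal)")
print(f"partial-conjunction p-value: {sweep.combined_p[0]:.3g} "
      f"(5 x the third-smallest per-threshold p-value, capped at 1)")
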