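"""Remove scanner effects with empirical-Bayes (ComBat) harmonisation.

Fits per-edge location and scale batch effects (shrunk across edges),
preserving age, sex, days-between-scans and scan-daytime effects, then
compares scanner variance and cross-scanner pattern similarity before and
after adjustment.
"""

from connrel import (
    SimConfig,
    apply_combat,
    fit_combat,
    pattern_similarity,
    scanner_variance_report,
    simulate_cohort,
)

data = simulate_cohort(SimConfig(n_regions=40, rng_seed=2))
model = fit_combat(data, eb=True)
harmonised = apply_combat(data, model)

rep = scanner_variance_report(data, harmonised)
print(f"mean scanner-variance fraction: {rep['mean_before']:.1f}% -> "
      f"{rep['mean_after']:.1f}% after harmonisation")

for label, d in (("before", data), ("after ", harmonised)):
    g = pattern_similarity(d, level="group").pcc
    s = pattern_similarity(d, level="subject").pcc
    print(f"pattern similarity {label}: group PCC {g:.2f}, mean subject PCC {s:.2f}")

print(f"\nEB shrinkage converged in {model.n_iterations.tolist()} iterations per batch.")
print("Group-level similarity improves sharply because the per-edge batch "
      "shifts cancel; subject-level similarity improves less — harmonisation "
      "cannot remove subject-specific residual noise.")
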