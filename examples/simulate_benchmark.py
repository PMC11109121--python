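"""Head-to-head of CODRP vs AUC-only calls on simulated cohorts.

Simulates cohorts of 30 patients in which organoid growth rate confounds
the in-vitro AUC (target corr(growth, AUC) = -0.5), runs the full fitting
and scoring pipeline per cohort, and compares each mode's calls with the
clinical labels.
"""

from codrp import SimConfig, benchmark_indices

cfg = SimConfig(n_patients=30, growth_auc_corr=-0.5, seed=11)
bench = benchmark_indices(cfg, 20)

print(bench[["run", "accuracy_codrp", "accuracy_auc"]].to_string(index=False))
print(f"\nmean accuracy: CODRP {bench['accuracy_codrp'].mean():.3f}  "
      f"AUC-only {bench['accuracy_auc'].mean():.3f}")
print("\nUnder growth confounding the AUC alone misreads growth-extreme "
      "patients;\nfolding the growth rate into the index recovers them.")
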