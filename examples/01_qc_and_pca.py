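"""Missing-value filtering and PCA on a synthetic repeated-measures study.

Simulates a paired design where between-subject variation dwarfs the
condition effect, then compares ordinary PCA with multilevel PCA (PCA on
within-subject deviations).  The separation score is the standardized
distance between condition means along PC1 — higher means the component
reflects the treatment, not the subjects.
"""

import numpy as np

from proteoflow import SimulationSpec, qc, simulate_expression

spec = SimulationSpec(n_proteins=600, paired=True, n_subjects=6,
                      subject_sd=3.0, effect_size=0.6, seed=42)
matrix, design, truth = simulate_expression(spec)
print(f"simulated {matrix.n_proteins} proteins x {matrix.n_samples} samples, "
      f"{matrix.mask.to_numpy().mean():.1%} missing")

filtered, report = qc.filter_missing(matrix, cutoff=0.0)
print(f"complete-case filter removed {report.n_removed} proteins, "
      f"kept {report.n_kept}")

standard = qc.run_pca(filtered)
multilevel = qc.run_multilevel_pca(filtered, design)

is_b = np.array([c == "B" for c in design.conditions])
for name, res in [("standard PCA", standard), ("multilevel PCA", multilevel)]:
    pc1 = res.scores.to_numpy()[:, 0]
    a, b = pc1[~is_b], pc1[is_b]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    sep = abs(a.mean() - b.mean()) / pooled
    print(f"{name}: PC1 explains {res.explained_variance_ratio[0]:.1%} "
          f"of variance, condition separation {sep:.2f}")
print("multilevel removes subject-to-subject offsets, so the condition "
      "signal surfaces on PC1")
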