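"""Simulate a panel of ROP experts and quantify their agreement.

Each simulated expert converts a latent severity in [1, 5] to an ordinal
grade through personal cut-points plus grading noise — the mechanism
behind real-world inter-expert disagreement on Plus disease.  We compute
linearly weighted kappa between experts, the reference standard
diagnosis (RSD), and each expert's error against the panel average.
"""

import numpy as np

from plusquant.grading import rater_losses
from plusquant.phantom import SimulatedPanel, simulate_grades

rng = np.random.default_rng(3)
thetas = rng.uniform(1.0, 5.0, 120)
panel = SimulatedPanel(n_experts=4, seed=9)
table = simulate_grades(thetas, panel, seed=4)

report = rater_losses(table)
print("pairwise weighted kappa (linear):")
for (a, b), k in sorted(report.pairwise_kappa.items()):
    if a < b:
        print(f"  {a}-{b}: {k:.3f}")
print("\nkappa vs RSD:", {e: round(k, 3) for e, k in report.kappa_vs_rsd.items()})
print("MSE vs average score:", {e: round(v, 3) for e, v in report.mse_vs_avg.items()})

ties = table.rsd()["tie_flag"].sum()
print(f"\n{ties} of {len(thetas)} images had tied majority votes "
      "(resolved by the flagged round-half-up rule).")
print("Moderate pairwise kappas with higher kappa-vs-RSD is the typical")
print("pattern for ordinal grading with expert-specific cut-points.")
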