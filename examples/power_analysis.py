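"""Detection power of G12 for hard versus soft sweeps on aDNA-like data.

Simulates hard-sweep, soft-sweep (recurrent, theta_A = 10) and neutral
201-SNP pseudo-haploid windows with realistic missingness, then reports
the true positive rate at a 1% false discovery rate and the ROC AUC for
each sweep class.
"""

import numpy as np

from g12scan import (
    ClusteringParams,
    SweepConfig,
    fit_missingness_model,
    g12_window,
    power_and_roc,
    sample_to_pseudohap_window,
    simulate,
    simulate_neutral_coalescent,
)

rng = np.random.default_rng(21)
model = fit_missingness_model(0.55, 0.23)
params = ClusteringParams(0.9)
N = 60  # replicates per class; increase for tighter intervals


def g12_of(sample):
    window = sample_to_pseudohap_window(sample, rng, missingness=model)
    return g12_window(window.calls, params)


neutral_cfg = SweepConfig(mode="neutral", rescale=10, t_onset=1000, t_sample=40)
neutral = [g12_of(simulate_neutral_coalescent(neutral_cfg, rng)) for _ in range(2 * N)]

for label, cfg in {
    "hard (s=0.1)": SweepConfig(mode="hard_de_novo", s=0.1, t_onset=1000, t_sample=40, rescale=10),
    "soft (theta_A=10, s=0.1)": SweepConfig(
        mode="recurrent", s=0.1, theta_a=10.0, t_onset=1000, t_sample=40, rescale=10
    ),
}.items():
    values = [g12_of(simulate(cfg, rng)) for _ in range(N)]
    res = power_and_roc(values, neutral, fdr=0.01)
    print(
        f"{label}: TPR at 1% FDR = {res.tpr:.2f} "
        f"[{res.ci95[0]:.2f}, {res.ci95[1]:.2f}], AUC = {res.auc:.2f}"
    )
print("hard sweeps concentrate the window into one haplotype class and are")
print("detected almost always; very soft sweeps spread across many origins")
print("and approach the neutral G12 distribution.")
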