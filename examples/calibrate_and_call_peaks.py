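"""Neutral-simulation threshold, QC masking and peak calling.

Draws neutral 201-SNP windows to set the order-statistic significance
threshold, scans a synthetic chromosome containing one sweep-like region,
applies the recombination/missingness QC masks and prints the called
peaks.
"""

import numpy as np

from g12scan import (
    CalibrationParams,
    ClusteringParams,
    ScanParams,
    SweepConfig,
    call_peaks,
    fit_missingness_model,
    g12_window,
    neutral_threshold,
    qc_masks,
    sample_to_pseudohap_window,
    scan_g12,
    simulate_neutral_coalescent,
)
from g12scan.geno_io import PSEUDO_HAPLOID, AlleleCallMatrix, SampleRecord, SnpRecord

rng = np.random.default_rng(11)
model = fit_missingness_model(0.55, 0.23)
cfg = SweepConfig(mode="neutral", rescale=10, t_onset=1000, t_sample=40)

neutral = []
for _ in range(300):
    sample = simulate_neutral_coalescent(cfg, rng)
    window = sample_to_pseudohap_window(sample, rng, missingness=model)
    neutral.append(g12_window(window.calls, ClusteringParams(0.9)))
threshold = neutral_threshold(neutral, CalibrationParams())
print(f"threshold from {len(neutral)} neutral replicates: G12 > {threshold:.4f}")

# synthetic chromosome: background singletons, one shared haplotype block
n_ind, n_snp = 100, 600
calls = rng.integers(0, 2, size=(n_ind, n_snp)).astype(np.int8)
calls[: n_ind // 2, 250:350] = rng.integers(0, 2, size=100).astype(np.int8)
snps = [SnpRecord(f"rs{j}", "1", j * 5e-6, 500 * (j + 1), "A", "G") for j in range(n_snp)]
matrix = AlleleCallMatrix(
    calls, PSEUDO_HAPLOID, snps, [SampleRecord(f"i{i}") for i in range(n_ind)]
)
track = scan_g12(matrix, ScanParams(window=101, jump=1))
track = qc_masks(track)
peaks = call_peaks(track, threshold)
for p in peaks:
    print(
        f"peak {p.chromosome}:{p.start_pos}-{p.end_pos}  "
        f"G12max = {p.representative_g12:.3f}  ({p.n_windows} windows)"
    )
print("each peak is a maximal run of adjacent super-threshold windows,")
print("represented by its highest G12 value.")
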