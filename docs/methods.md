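# Methods

## The G12 statistic on pseudo-haploid data

G12 summarizes multi-locus genotype homozygosity in a window of a fixed
number of SNPs. Let q₁ ≥ q₂ ≥ … ≥ qₙ be the frequencies of the unique
multi-site genotype clusters among the sampled individuals; then
G12 = (q₁+q₂)² + Σ_{i≥3} qᵢ². The pooling of the top two classes targets
both hard sweeps (one common haplotype) and soft sweeps (two). On
pseudo-haploid data each individual contributes a single allele per site,
so the clustered objects are pseudo-haplotypes over {0, 1, missing}; on
diploid data they are unphased multi-locus genotypes over {0, 1, 2,
missing}.

**Clustering semantics.** Clustering is greedy first-fit in fixed input
row order: an individual joins the first existing cluster whose *founding*
row matches at every site where both are non-missing; otherwise it founds
a new cluster. Individuals missing more than `m` of the window (default
m = 0.9) are always singletons — they neither join nor accept members.
This rule exists because match-on-non-missing clustering under heavy
missingness glues unrelated rows into one giant cluster and inflates G12.
The greedy order-dependence is deliberate and documented: fixing input
order makes the statistic deterministic, and with complete data the
procedure reduces exactly to unique-row counting (property-tested against
a sort-based oracle). Frequency ties are broken by cluster creation index;
G12 itself is tie-invariant.

**Windows.** Default 201 SNPs (odd, centered on the focal SNP) advancing
by 1 SNP. Windows that would overhang a chromosome end are skipped rather
than truncated, because G12's magnitude depends on the window's SNP count.
Per-window mean missing fraction (mean over SNPs of the fraction of
missing individuals) and mean recombination rate are recorded for QC.

## aDNA mimicking transforms

Applied in the fixed order ascertain → damage → missingness →
pseudo-haploidize, each stage seeded from a named substream of one master
seed.

* **Ascertainment** restricts to a capture-panel position list.
* **Damage** emulates post-mortem deamination: walking each individual's
  called positions in genomic order, every 100th (the stride) that carries
  a C where the SNP's other allele is T is flipped to T. The stride is
  counted over *called* positions per individual — the natural reading of
  a per-individual rule — and only the recorded allele letters are
  touched (no complementary-strand G→A emulation). C→T flips at non-C/T
  SNPs are impossible by construction and such sites are left unchanged.
* **Missingness** draws a per-SNP missing fraction p_j from a beta
  distribution fitted by the method of moments (defaults mean 0.55,
  sd 0.23, the levels typical of 1240k-captured aDNA panels; shapes
  α ≈ 2.02, β ≈ 1.66) and masks each individual's call independently with
  probability p_j. Draws are truncated to [1e-6, 1−1e-6] to avoid
  degenerate all-missing SNPs. Per-SNP fractions are retained so the
  positional autocorrelation diagnostic can verify the independence
  assumption (i.i.d. draws give |acf| < 0.05 at all lags).
* **Pseudo-haploidization** maps homozygotes deterministically and
  heterozygotes to a fair Bernoulli allele choice, preserving allele
  frequencies in expectation.

## Forward Wright–Fisher simulator

Discrete generations; every gamete picks a diploid parent with probability
proportional to fitness (additive scheme 1, 1+s/2, 1+s — dominance of the
beneficial allele is ½, a conventional choice since nothing else is
implied by the scan's use case), starts on a random parental chromosome,
and receives Poisson(rL) crossovers at uniform positions and
Poisson(μL) infinite-sites mutations. Defaults: μ = 1.25e-8/bp,
r = 1e-8/bp, L = 5e5 bp, 177 diploids sampled without replacement at the
sampling time.

**Demography.** Built-in piecewise-exponential European model (ancestral
7,310 diploids; African expansion 14,474 at generation 5,920;
out-of-Africa bottleneck 1,861 at 2,040; European founding 1,032 at 920
growing 0.307%/generation, accelerating to 1.95%/generation at 205 and
reaching ~512,000 at present; generation time 25 y), stored as a
versioned table, plus a constant-size model for testing. Rescaling by λ
divides sizes and times by λ and multiplies μ, r, s and growth rates by
λ, preserving θ, ρ and N·s; λ = 10 is the desk-scale default for
scenarios that carry genotype windows.

**Initialization.** Neutral variation ahead of the forward phase comes by
default from an msprime coalescent simulation of the same (rescaled)
demography, sampling the whole population at the forward start time; a
literal neutral forward burn-in of 10·N_ancestral generations is available
behind `init="burnin"` and is tested to give equivalent diversity. Under
full neutrality the forward phase adds nothing, so neutral calibration
replicates are drawn directly from the coalescent at the sampling time
(`simulate_neutral_coalescent`); the forward simulator's neutral mode is
cross-checked against this oracle (segregating-site distributions,
Watterson expectation, rescaling invariance).

**Scenarios and conditioning.** `hard_de_novo` introduces one beneficial
copy at the chromosome center at the onset time. `recurrent` introduces
Poisson(θ_A/2) fresh adaptive copies per generation (θ_A held constant
through time by recomputing μ_A against the current size; a fixed-μ_A
variant sits behind a flag), each tagged with its mutational origin.
`sgv` introduces a neutral central mutation at the stated introduction
time; selection switches on at the first generation its frequency reaches
f_init, with the carrier haplotypes snapshotted at that moment. All
non-neutral runs are conditioned on the adaptive allele surviving to the
sampling time: any loss of every adaptive copy restarts the replicate
with fresh randomness.

**Softness bookkeeping.** Recurrent-origin sweeps are *soft* when two or
more origin labels survive among the sampled adaptive copies; standing-
variation sweeps are soft when the carriers sat on two or more distinct
full-region haplotypes at the onset of selection; single-introduction
sweeps are hard by construction.

**Bookkeeping-only fast path.** With `record_haplotypes=False` the
simulator tracks full haplotypes only while they inform the requested
bookkeeping and otherwise iterates the exact allele-count marginal of the
same reproduction scheme (p' = p(1+s(1+p)/2)/(1+sp) followed by
(multi)nomial sampling). For the SGV scenario this takes a three-phase
form, each phase exact: (1) rejection sampling on the pure allele-count
drift of the standing variant until it crosses f_init (neutral counts are
independent of the haplotype background, so failed excursions cost
nothing); (2) one coalescent initialization and a haplotype replay of the
drift phase conditioned on the accepted count trajectory, using the
re-parameterization of the gamete law by the chromosome contributing the
adaptive-site segment (that source is uniform over parental chromosomes,
so conditioning on the offspring carrier count reduces to drawing sources
from the carrier and non-carrier pools at exchangeable positions);
(3) selection forward to sampling. This makes *unrescaled* softness
studies affordable, which matters because the carrier count at onset,
⌈f_init·2N⌉, is an absolute copy number that rescaling shrinks (λ = 10
turns ~38 standing copies into 4) and with it the chance of observing
several distinct carrier haplotypes. Softness fractions are therefore
computed at λ = 1; genotype-window analyses (power, calibration,
fidelity) use λ = 10.

**Known limitation.** Under the first-crossing onset rule, accepted drift
excursions are fast upward fluctuations, so the carrier genealogy at
onset is star-like and shallow; with f_init = 0.01 (≈38 copies at onset,
introduction 1000 generations before present) about 80% of replicates
show ≥2 distinct carrier haplotypes, whereas a conditioning that holds
the variant near f_init until a fixed onset time would push this fraction
above 90% at the cost of grossly inflating the corresponding fraction for
f_init = 0.001 (which this package computes at ~5%, the bottom of the
plausible range). The first-crossing rule is kept as the overall better-
behaved definition.

**aDNA-style window sampling.** A simulated sample is paired into 177
diploids, pseudo-haploidized, thinned to 201 uniformly chosen segregating
sites (genomic order preserved) and optionally given beta-model
missingness — the same sparsity as a real capture-panel window.

**Sweep footprint.** The expected extent of a hard-sweep footprint,
s/[ln(N_e·s)·r] bp (natural log), is exposed for window-size reasoning:
at s = 0.04, N_e = 1e5, r = 1e-8 it is ≈4.8e5 bp, the scale of one
201-SNP window, so sweeps with s ≳ 0.04 fill a window.

## Calibration, peaks, QC, power

* **Threshold**: the k-th highest of n neutral replicate G12 values; at
  the reference n = 58,350, k = 5, otherwise k = max(1, round(5·n/58,350))
  (a literal-k mode exists). Rank-based, hence equivariant under monotone
  transforms; each neutral replicate contributes the single G12 of its
  201-SNP window (per-window pooling for whole-genome tracks sits behind
  the same API by passing all window values).
* **Peaks**: seed-and-extend from the highest unconsumed super-threshold
  window over focal-index-adjacent windows (adjacency = one jump);
  property-tested equivalent to maximal-run merging. Masked windows are
  excluded and break contiguity. Representative = run maximum.
* **QC masks** (flagged separately, combined by union): window mean
  recombination in the lowest 5th percentile; window mean missing fraction
  above Q3 + 0.75·IQR; window inside a top-20 peak of *every* supplied
  cross-population track (needs ≥2 tracks, else skipped with a warning).
* **Power**: detection threshold = (1−fdr) inverse-ECDF quantile of the
  neutral values (default fdr = 0.01); TPR with a Wilson 95% interval;
  ROC/AUC over pooled values (scikit-learn).
* **Z-scores**: per-focal-SNP z against the neutral mean/sd with
  upper-tail Gaussian p-values.
* **Variance diagnostic**: OLS R² of G12 on window bp span, missingness
  and recombination over unmasked windows; a well-masked scan leaves this
  small (the package's simulated scans come in well under 0.05).

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure that drives the scan —
window-level haplotype frequency spectra under neutral and sweep
dynamics, capture-panel sparsity (201 SNPs/window, 177 individuals),
beta-distributed per-SNP missingness, deamination-style C→T flips,
pseudo-haploid calling. It does not emulate read-level artifacts
(fragment-length and terminal-damage gradients), contamination,
reference bias, SNP ascertainment bias toward common variants, or
population structure and admixture within a sample. Passing tests
therefore demonstrate correctness of the statistics and the simulator's
population-genetic behavior, not robustness to every artifact of real
aDNA.

## Numerical and design choices

* Missing calls are −1 in int8 matrices; coordinates 1-based inclusive
  internally, 0-based half-open only in BED output.
* EIGENSTRAT genotype digits count copies of the `.snp` ref-column allele;
  pseudo-haploid files use {0, 2, 9}, normalized to {0, 1, missing}.
* Recombination lookup is piecewise-constant by enclosing map interval;
  positions before the first point take the first rate.
* Beta shapes are capped at 1e9 as sd → 0 (degenerate point mass).
* Cluster-frequency sums are validated to 1e-12; spectra must be
  descending with positive entries.
* Problem sizes in the test suite (200 replicates per power/softness
  scenario, 2,000 neutral calibration replicates, 100 fidelity datasets)
  were chosen to give binomial/Monte-Carlo error comfortably inside each
  asserted tolerance.
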