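"""Forward Wright-Fisher simulation of neutral and sweep scenarios.

The simulator produces 500 kb haplotype samples under a piecewise
(European-style) demography with four scenario modes:

* ``neutral`` — no adaptive site;
* ``hard_de_novo`` — a single beneficial mutation introduced at the
  chromosome center at the onset of selection;
* ``recurrent`` — adaptive mutations arise every generation as a Poisson
  process with population rate theta_A / 2, each copy tagged with a fresh
  mutational origin label (soft sweeps when two or more origins survive);
* ``sgv`` — a neutral central mutation drifts from a single copy and
  becomes beneficial at the first generation its frequency reaches
  ``f_init`` (soft sweeps when the standing copies sit on two or more
  distinct haplotypes at that moment).

Reproduction is discrete-generation Wright-Fisher: every gamete picks a
parent with probability proportional to diploid fitness 1, 1 + s/2, 1 + s
(additive, dominance 1/2), starts on a random parental chromosome, and
receives Poisson(r L) crossovers and Poisson(mu L) infinite-sites
mutations.  All non-neutral runs are conditioned on the adaptive allele
being present at sampling time: runs that lose it are restarted with fresh
randomness.

Population-size rescaling by ``lambda`` divides sizes and times by
``lambda`` and multiplies mu, r, s and growth rates by ``lambda`` so that
population-scaled parameters (theta, rho, N s) are preserved; theta_A is a
population rate and is left untouched.  The default for desk-scale work is
``lambda = 10``.

Neutral haplotype state ahead of the forward phase comes, by default, from
a coalescent (msprime) simulation of the same rescaled demography sampled
at the forward start time; a literal neutral forward burn-in of
10 N_ancestral generations is available behind ``init="burnin"``.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, replace
from itertools import chain

import msprime
import numpy as np

from .adna_mimic import MissingnessModel, inject_missingness, pseudo_haploidize
from .geno_io import DIPLOID_MLG, AlleleCallMatrix, SampleRecord, SnpRecord

logger = logging.getLogger(__name__)

MODES = ("neutral", "hard_de_novo", "recurrent", "sgv")

_NUCLEOTIDES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographyEpoch:
    """One piecewise-exponential epoch, looking back in time.

    ``end_generation`` is the younger boundary (generations before
    present), ``start_generation`` the older; ``size`` is the diploid
    effective size at the younger boundary and ``growth_rate`` the
    per-generation exponential rate toward the present within the epoch,
    so N(t) = size * exp(-growth_rate * (t - end_generation)).
    """

    end_generation: float
    start_generation: float
    size: float
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("epoch size must be positive")
        if self.end_generation >= self.start_generation:
            raise ValueError("epoch must extend backward in time")


@dataclass(frozen=True)
class Demography:
    """Contiguous epoch list back to the ancestral epoch, plus helpers."""

    epochs: tuple[DemographyEpoch, ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for ep in self.epochs:
            if not math.isclose(ep.end_generation, prev_end):
                raise ValueError("epochs must be contiguous from the present")
            prev_end = ep.start_generation
        if not math.isinf(self.epochs[-1].start_generation):
            raise ValueError("final (ancestral) epoch must extend to infinity")

    @property
    def ancestral_size(self) -> float:
        return self.epochs[-1].size

    def size_at(self, t: float) -> float:
        """Diploid N at ``t`` generations before present (continuous)."""
        for ep in self.epochs:
            if ep.end_generation <= t < ep.start_generation:
                return ep.size * math.exp(-ep.growth_rate * (t - ep.end_generation))
        return self.ancestral_size

    def n_at(self, t: float) -> int:
        return max(2, round(self.size_at(t)))

    def rescaled(self, lam: float) -> "Demography":
        if lam == 1:
            return self
        return Demography(
            tuple(
                DemographyEpoch(
                    end_generation=ep.end_generation / lam,
                    start_generation=ep.start_generation / lam,
                    size=ep.size / lam,
                    growth_rate=ep.growth_rate * lam,
                )
                for ep in self.epochs
            )
        )

    def to_msprime(self) -> msprime.Demography:
        demo = msprime.Demography()
        first = self.epochs[0]
        demo.add_population(
            name="pop", initial_size=first.size, growth_rate=first.growth_rate
        )
        for ep in self.epochs[1:]:
            demo.add_population_parameters_change(
                time=ep.end_generation,
                population="pop",
                initial_size=ep.size,
                growth_rate=ep.growth_rate,
            )
        return demo


#: European demographic history after Tennessen et al.: ancestral size 7310
#: to generation 5920, African expansion to 14474, out-of-Africa bottleneck
#: 1861 at generation 2040, European founding at 1032 with 0.307%/gen growth
#: from generation 920, accelerating to 1.95%/gen at generation 205 and
#: reaching ~512,000 diploids at present (generation time 25 y).
TENNESSEN_EUROPEAN_TABLE_VERSION = "tennessen-2012-european-v1"
_TENNESSEN_EUROPEAN = Demography(
    (
        DemographyEpoch(0.0, 205.0, 512_000.0, 0.0195),
        DemographyEpoch(205.0, 920.0, 9_279.0, 0.00307),
        DemographyEpoch(920.0, 2040.0, 1_861.0, 0.0),
        DemographyEpoch(2040.0, 5920.0, 14_474.0, 0.0),
        DemographyEpoch(5920.0, math.inf, 7_310.0, 0.0),
    )
)


def build_demography(model_name: str, lam: float = 1.0, constant_size: float = 10_000.0) -> Demography:
    """Build a (rescaled) demographic model by name.

    ``tennessen_european`` is the built-in European table above;
    ``constant`` is a single epoch of ``constant_size`` diploids.
    Rescaling divides sizes and epoch times by ``lam`` and multiplies
    growth rates by ``lam``, preserving theta = 4 N mu per site once the
    per-site rates are scaled up by the same factor.
    """
    if model_name == "tennessen_european":
        base = _TENNESSEN_EUROPEAN
    elif model_name == "constant":
        base = Demography((DemographyEpoch(0.0, math.inf, float(constant_size), 0.0),))
    else:
        raise ValueError(f"unknown demographic model {model_name!r}")
    return base.rescaled(lam)


# ---------------------------------------------------------------------------
# Configuration and sample container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepConfig:
    """Full parameterization of one forward simulation."""

    mode: str = "neutral"
    s: float = 0.0
    theta_a: float | None = None  # recurrent mode: theta_A = 4 N_{e,t} mu_A
    f_init: float | None = None  # sgv mode: frequency at which selection starts
    t_onset: float = 1000.0  # generations before present; introduction time
    t_sample: float = 40.0
    mu: float = 1.25e-8  # per bp per generation
    r: float = 1e-8  # crossover events per bp per generation
    L: float = 5e5  # chromosome length, bp
    sample_n: int = 177  # diploid individuals drawn at t_sample
    rescale: float = 10.0  # lambda
    demography_model: str = "tennessen_european"
    constant_size: float = 10_000.0
    init: str = "coalescent"  # or "burnin"
    fixed_adaptive_mu: bool = False  # recurrent: freeze mu_A at its ancestral value
    max_restarts: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.rescale < 1:
            raise ValueError("rescale factor must be >= 1")
        if self.t_sample >= self.t_onset:
            raise ValueError("t_sample must be more recent than t_onset")
        if self.mode == "recurrent" and not self.theta_a:
            raise ValueError("recurrent mode requires theta_a")
        if self.mode == "sgv" and not self.f_init:
            raise ValueError("sgv mode requires f_init")
        if self.init not in ("coalescent", "burnin"):
            raise ValueError("init must be 'coalescent' or 'burnin'")

    # rescaled quantities -------------------------------------------------
    @property
    def lam(self) -> float:
        return self.rescale

    @property
    def s_r(self) -> float:
        return self.s * self.lam

    @property
    def mu_r(self) -> float:
        return self.mu * self.lam

    @property
    def r_r(self) -> float:
        return self.r * self.lam

    @property
    def t_onset_r(self) -> int:
        return max(1, round(self.t_onset / self.lam))

    @property
    def t_sample_r(self) -> int:
        t = round(self.t_sample / self.lam)
        if t >= self.t_onset_r:
            raise ValueError("rescaled sampling time collides with onset; lower rescale")
        return t

    def demography(self) -> Demography:
        return build_demography(self.demography_model, self.lam, self.constant_size)


@dataclass
class SimulatedSample:
    """Output of one accepted (conditioned) simulation replicate.

    ``haplotypes`` is a 2*sample_n x S binary matrix of derived alleles at
    the segregating ``positions`` (float bp on [0, L)); it is ``None`` when
    the run was bookkeeping-only (``record_haplotypes=False``).
    """

    config: SweepConfig
    haplotypes: np.ndarray | None
    positions: np.ndarray | None
    adaptive_site: float
    origin_labels: np.ndarray | None  # per sampled chromosome; 0 = non-carrier
    origins_at_sampling: int
    carrier_haplotypes_at_onset: int | None  # sgv: distinct count at onset
    carrier_snapshot: tuple | None  # sgv: the carrier haplotype tuples at onset
    selection_onset_generation: int | None  # rescaled gens before present
    final_adaptive_freq: float
    n_restarts: int


@dataclass(frozen=True)
class SoftnessReport:
    origins_at_sampling: int
    distinct_carrier_haplotypes_at_onset: int | None
    label: str  # "hard" | "soft"


def classify_softness(sample: SimulatedSample) -> SoftnessReport:
    """Label a conditioned sweep replicate hard or soft.

    Recurrent-mutation sweeps are soft when two or more independent
    mutational origins survive among the sampled adaptive copies; standing-
    variation sweeps are soft when the adaptive copies sat on two or more
    distinct haplotypes at the onset of selection; single-introduction
    hard sweeps are hard by construction.
    """
    mode = sample.config.mode
    if mode == "neutral":
        raise ValueError("neutral simulations carry no sweep to classify")
    if mode == "hard_de_novo":
        return SoftnessReport(1, None, "hard")
    if mode == "recurrent":
        label = "soft" if sample.origins_at_sampling >= 2 else "hard"
        return SoftnessReport(sample.origins_at_sampling, None, label)
    k = sample.carrier_haplotypes_at_onset
    label = "soft" if (k is not None and k >= 2) else "hard"
    return SoftnessReport(sample.origins_at_sampling, k, label)


def expected_footprint(s: float, n_e: float, r: float) -> float:
    """Expected bp extent of a hard-sweep footprint, s / [ln(N_e s) r].

    Natural log, as is standard in the hitchhiking literature.  Requires
    N_e * s > 1 so the log is positive.
    """
    if n_e * s <= 1:
        raise ValueError("footprint undefined for N_e * s <= 1")
    return s / (math.log(n_e * s) * r)


# ---------------------------------------------------------------------------
# Forward machinery
# ---------------------------------------------------------------------------

def _coalescent_init(config: SweepConfig, demo: Demography, t_start: int, rng) -> list[tuple]:
    """Neutral haplotypes for the whole population at ``t_start``."""
    n0 = demo.n_at(t_start)
    seed1, seed2 = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(2 * n0, population="pop", time=t_start, ploidy=1)],
        demography=demo.to_msprime(),
        sequence_length=config.L,
        recombination_rate=config.r_r,
        random_seed=seed1,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mu_r, model=msprime.BinaryMutationModel(), discrete_genome=False, random_seed=seed2
    )
    pos = ts.tables.sites.position
    gm = ts.genotype_matrix()  # sites x samples
    return [tuple(pos[gm[:, k] > 0]) for k in range(gm.shape[1])]


def _burnin_init(config: SweepConfig, demo: Demography, t_start: int, rng) -> list[tuple]:
    """Literal neutral forward burn-in of 10 N_ancestral generations."""
    t_burn = t_start + round(10 * demo.ancestral_size)
    haps = np.empty(2 * demo.n_at(t_burn), dtype=object)
    for i in range(haps.size):
        haps[i] = ()
    adapt = np.zeros(haps.size, dtype=np.int32)
    for t in range(t_burn, t_start, -1):
        haps, adapt = _reproduce(haps, adapt, demo.n_at(t - 1), 0.0, config, rng)
    return list(haps)


def _recombine(h_a: tuple, h_b: tuple, breaks: np.ndarray) -> tuple:
    segs = []
    cur, other = h_a, h_b
    prev = 0.0
    for b in breaks:
        i0 = bisect_left(cur, prev)
        i1 = bisect_left(cur, b)
        segs.append(cur[i0:i1])
        prev = b
        cur, other = other, cur
    segs.append(cur[bisect_left(cur, prev):])
    return tuple(chain.from_iterable(segs))


def _reproduce(haps, adapt, n_next: int, s_eff: float, config: SweepConfig, rng):
    """One Wright-Fisher generation; returns the offspring (haps, adapt).

    Every gamete independently picks a parent proportional to fitness
    (additive: 1, 1+s/2, 1+s), a starting chromosome, and Poisson numbers
    of crossovers and new infinite-sites mutations.
    """
    n_cur = len(haps) // 2
    n_gam = 2 * n_next
    carrier = adapt > 0
    if s_eff > 0.0 and carrier.any():
        dosage = carrier.reshape(n_cur, 2).sum(axis=1)
        w = 1.0 + s_eff * dosage / 2.0
        parents = rng.choice(n_cur, size=n_gam, p=w / w.sum())
    else:
        parents = rng.integers(0, n_cur, size=n_gam)
    start = rng.integers(0, 2, size=n_gam)
    n_cross = rng.poisson(config.r_r * config.L, size=n_gam)
    n_mut = rng.poisson(config.mu_r * config.L, size=n_gam)

    src = 2 * parents + start
    new_haps = np.empty(n_gam, dtype=object)
    new_adapt = adapt[src].copy()
    simple = (n_cross == 0) & (n_mut == 0)
    new_haps[simple] = haps[src[simple]]

    half_l = config.L / 2.0
    for g in np.flatnonzero(~simple):
        p, c = parents[g], start[g]
        hap = haps[2 * p + c]
        if n_cross[g]:
            breaks = np.sort(rng.uniform(0.0, config.L, n_cross[g]))
            other = haps[2 * p + 1 - c]
            hap = _recombine(hap, other, breaks)
            # adaptive site rides on whichever parental chromosome holds L/2
            side = int(np.searchsorted(breaks, half_l, side="right")) % 2
            new_adapt[g] = adapt[2 * p + c] if side == 0 else adapt[2 * p + 1 - c]
        if n_mut[g]:
            hap = tuple(sorted(hap + tuple(rng.uniform(0.0, config.L, n_mut[g]))))
        new_haps[g] = hap
    return new_haps, new_adapt


def _freq_step(p: float, s_eff: float) -> float:
    """Post-selection gamete allele probability under random mating.

    Marginal of the fitness-weighted parent choice used in ``_reproduce``:
    p' = p (1 + s(1+p)/2) / (1 + s p).
    """
    if s_eff == 0.0:
        return p
    return p * (1.0 + s_eff * (1.0 + p) / 2.0) / (1.0 + s_eff * p)


class _Restart(Exception):
    """Adaptive allele lost (or sgv onset never reached); retry the run."""


def simulate(config: SweepConfig, rng: np.random.Generator, *, record_haplotypes: bool = True) -> SimulatedSample:
    """Run one conditioned replicate of the configured scenario.

    Non-neutral runs are restarted (with fresh randomness, up to
    ``config.max_restarts`` attempts) whenever every adaptive copy is lost
    before the sampling time; accepted replicates therefore always carry
    the adaptive allele at sampling.  With ``record_haplotypes=False`` the
    run keeps full haplotypes only while they inform the softness
    bookkeeping (the SGV drift phase) and otherwise iterates the exact
    allele-count marginal of the same reproduction scheme — much faster,
    but the returned sample then has no genotype matrix.
    """
    if config.mode == "neutral" and not record_haplotypes:
        raise ValueError("a neutral run without haplotypes records nothing")
    for attempt in range(config.max_restarts):
        try:
            sample = _attempt(config, rng, record_haplotypes)
        except _Restart:
            continue
        sample.n_restarts = attempt
        return sample
    raise RuntimeError(
        f"adaptive mutation failed to establish in {config.max_restarts} attempts"
    )


def _attempt(config: SweepConfig, rng, record_haplotypes: bool) -> SimulatedSample:
    demo = config.demography()
    if config.mode == "sgv":
        return _attempt_sgv(config, demo, rng, record_haplotypes)
    return _attempt_standard(config, demo, rng, record_haplotypes)


def _as_object_array(haps_list) -> np.ndarray:
    # np.array() would build a 2-D array from equal-length tuples
    arr = np.empty(len(haps_list), dtype=object)
    for i, h in enumerate(haps_list):
        arr[i] = h
    return arr


def _init_population(config: SweepConfig, demo: Demography, t_start: int, rng):
    if config.init == "coalescent":
        haps = _as_object_array(_coalescent_init(config, demo, t_start, rng))
    else:
        haps = _as_object_array(_burnin_init(config, demo, t_start, rng))
    return haps, np.zeros(haps.size, dtype=np.int32)


def _attempt_standard(config: SweepConfig, demo: Demography, rng, record_haplotypes: bool) -> SimulatedSample:
    """Neutral, hard_de_novo and recurrent scenarios."""
    t_start, t_samp = config.t_onset_r, config.t_sample_r
    next_label = 1
    counts: np.ndarray | None = None  # bookkeeping-only per-origin copy counts
    labels: np.ndarray | None = None

    # hard/recurrent bookkeeping-only runs never consult neutral haplotypes,
    # so they skip initialization and track per-origin copy counts throughout
    if not record_haplotypes:
        haps = adapt = None  # type: ignore[assignment]
        pop_2n = 2 * demo.n_at(t_start)
        if config.mode == "hard_de_novo":
            counts, labels = np.array([1], dtype=np.int64), np.array([1])
            next_label = 2
        else:
            counts = np.empty(0, dtype=np.int64)
            labels = np.empty(0, dtype=np.int64)
    else:
        haps, adapt = _init_population(config, demo, t_start, rng)
        pop_2n = haps.size
        if config.mode == "hard_de_novo":
            adapt[rng.integers(0, adapt.size)] = next_label
            next_label += 1

    def total_adaptive() -> int:
        return int(counts.sum()) if counts is not None else int((adapt > 0).sum())

    any_existed = total_adaptive() > 0

    for t in range(t_start, t_samp, -1):
        n_next = demo.n_at(t - 1)
        s_eff = config.s_r if config.mode != "neutral" else 0.0

        if counts is None:
            haps, adapt = _reproduce(haps, adapt, n_next, s_eff, config, rng)
            pop_2n = haps.size
        else:
            p = counts.sum() / pop_2n
            p_sel = _freq_step(p, s_eff)
            scale = p_sel / p if p > 0 else 0.0
            probs = counts * scale / pop_2n
            pop_2n = 2 * n_next
            draw = rng.multinomial(pop_2n, np.append(probs, max(0.0, 1.0 - probs.sum())))
            counts = draw[:-1].astype(np.int64)

        if config.mode == "recurrent":
            rate = config.theta_a / 2.0
            if config.fixed_adaptive_mu:
                rate *= demo.size_at(t - 1) / demo.ancestral_size
            n_new = rng.poisson(rate)
            if n_new:
                if counts is None:
                    free = np.flatnonzero(adapt == 0)
                    pick = rng.choice(free.size, size=min(n_new, free.size), replace=False)
                    for idx in free[pick]:
                        adapt[idx] = next_label
                        next_label += 1
                else:
                    n_wild = pop_2n - counts.sum()
                    n_new = min(n_new, int(n_wild))
                    counts = np.append(counts, np.ones(n_new, dtype=np.int64))
                    labels = np.append(labels, np.arange(next_label, next_label + n_new))
                    next_label += n_new

        n_adaptive = total_adaptive()
        if config.mode != "neutral" and any_existed and n_adaptive == 0:
            raise _Restart  # all adaptive copies lost before sampling
        any_existed = any_existed or n_adaptive > 0

        if counts is not None and counts.size:
            keep = counts > 0
            counts, labels = counts[keep], labels[keep]

    if config.mode != "neutral" and total_adaptive() == 0:
        raise _Restart
    onset_gen = t_start if config.mode != "neutral" else None
    if counts is not None:
        return _finalize_counts(config, counts, pop_2n, None, None, onset_gen, rng)
    return _finalize_full(config, haps, adapt, None, None, onset_gen, rng)


def _neutral_crossing_trajectory(config: SweepConfig, demo: Demography, rng):
    """Copy counts of the standing variant from introduction to f_init crossing.

    Pure allele-count drift (the exact marginal of the neutral reproduction
    scheme), so failed excursions are discarded without ever touching
    haplotypes.  Returns (counts per generation, onset generation) or None
    when the variant is lost or never reaches f_init before sampling.
    """
    t_start, t_samp = config.t_onset_r, config.t_sample_r
    k = 1
    ks = [1]
    if 1 / (2 * demo.n_at(t_start)) >= config.f_init:
        return ks, t_start  # a single fresh copy already clears f_init
    for t in range(t_start, t_samp, -1):
        two_n_cur = 2 * demo.n_at(t)
        two_n_next = 2 * demo.n_at(t - 1)
        k = int(rng.binomial(two_n_next, k / two_n_cur))
        if k == 0:
            return None
        ks.append(k)
        if k / two_n_next >= config.f_init:
            return ks, t - 1
    return None


def _replay_generation(haps, adapt, k_next: int, n_next: int, config: SweepConfig, rng):
    """One neutral WF generation conditioned on the offspring carrier count.

    Re-parameterizes the unconditional gamete law by the chromosome that
    contributes the adaptive-site segment: that source is uniform over all
    parental chromosomes, so conditioning the offspring carrier count on
    ``k_next`` amounts to drawing sources uniformly from the carrier and
    non-carrier pools at exchangeable gamete positions.
    """
    n_gam = 2 * n_next
    carrier_idx = np.flatnonzero(adapt > 0)
    noncar_idx = np.flatnonzero(adapt == 0)
    src = np.empty(n_gam, dtype=np.int64)
    order = rng.permutation(n_gam)
    src[order[:k_next]] = carrier_idx[rng.integers(0, carrier_idx.size, size=k_next)]
    src[order[k_next:]] = noncar_idx[rng.integers(0, noncar_idx.size, size=n_gam - k_next)]
    n_cross = rng.poisson(config.r_r * config.L, size=n_gam)
    n_mut = rng.poisson(config.mu_r * config.L, size=n_gam)

    new_haps = np.empty(n_gam, dtype=object)
    new_adapt = adapt[src].copy()
    simple = (n_cross == 0) & (n_mut == 0)
    new_haps[simple] = haps[src[simple]]
    half_l = config.L / 2.0
    for g in np.flatnonzero(~simple):
        hap = haps[src[g]]
        if n_cross[g]:
            breaks = np.sort(rng.uniform(0.0, config.L, n_cross[g]))
            homolog = haps[src[g] ^ 1]
            # the segment containing the adaptive site must come from src
            if int(np.searchsorted(breaks, half_l, side="right")) % 2 == 0:
                hap = _recombine(hap, homolog, breaks)
            else:
                hap = _recombine(homolog, hap, breaks)
        if n_mut[g]:
            hap = tuple(sorted(hap + tuple(rng.uniform(0.0, config.L, n_mut[g]))))
        new_haps[g] = hap
    return new_haps, new_adapt


def _attempt_sgv(config: SweepConfig, demo: Demography, rng, record_haplotypes: bool) -> SimulatedSample:
    """Standing-variation scenario in three exact phases.

    1. allele-count drift of the neutral variant until it crosses f_init
       (cheap rejection sampling, no haplotypes);
    2. coalescent initialization and a haplotype replay of the drift phase
       conditioned on the accepted count trajectory;
    3. selection forward to the sampling time.
    """
    t_start, t_samp = config.t_onset_r, config.t_sample_r

    traj = None
    for _ in range(config.max_restarts):
        traj = _neutral_crossing_trajectory(config, demo, rng)
        if traj is not None:
            break
    if traj is None:
        raise RuntimeError(
            f"standing variant failed to reach f_init={config.f_init} in "
            f"{config.max_restarts} attempts"
        )
    ks, onset_gen = traj

    haps, adapt = _init_population(config, demo, t_start, rng)
    adapt[rng.integers(0, adapt.size)] = 1
    for i, t in enumerate(range(t_start, onset_gen, -1)):
        haps, adapt = _replay_generation(haps, adapt, ks[i + 1], demo.n_at(t - 1), config, rng)

    snapshot = tuple(haps[adapt > 0])
    carriers_at_onset = len(set(snapshot))

    if record_haplotypes:
        for t in range(onset_gen, t_samp, -1):
            haps, adapt = _reproduce(haps, adapt, demo.n_at(t - 1), config.s_r, config, rng)
            if not (adapt > 0).any():
                raise _Restart
        return _finalize_full(config, haps, adapt, carriers_at_onset, snapshot, onset_gen, rng)

    k = int((adapt > 0).sum())
    pop_2n = haps.size
    haps = adapt = None
    for t in range(onset_gen, t_samp, -1):
        p = k / pop_2n
        pop_2n = 2 * demo.n_at(t - 1)
        k = int(rng.binomial(pop_2n, _freq_step(p, config.s_r)))
        if k == 0:
            raise _Restart
    return _finalize_counts(
        config, np.array([k], dtype=np.int64), pop_2n, carriers_at_onset, snapshot, onset_gen, rng
    )


def _finalize_counts(config, counts, pop_2n, carriers_at_onset, snapshot, onset_gen, rng) -> SimulatedSample:
    """Sample-level bookkeeping for a counts-only run (no genotype matrix)."""
    colors = np.append(counts, pop_2n - counts.sum())
    drawn = rng.multivariate_hypergeometric(colors.astype(np.int64), 2 * config.sample_n)
    origins = int((drawn[:-1] > 0).sum())
    return SimulatedSample(
        config=config,
        haplotypes=None,
        positions=None,
        adaptive_site=config.L / 2.0,
        origin_labels=None,
        origins_at_sampling=origins,
        carrier_haplotypes_at_onset=carriers_at_onset,
        carrier_snapshot=snapshot,
        selection_onset_generation=onset_gen,
        final_adaptive_freq=float(counts.sum() / pop_2n),
        n_restarts=0,
    )


def _finalize_full(config, haps, adapt, carriers_at_onset, snapshot, onset_gen, rng) -> SimulatedSample:
    """Draw the diploid sample and build the binary haplotype matrix."""
    site = config.L / 2.0
    pop_2n = haps.size
    n_dip = pop_2n // 2
    if config.sample_n > n_dip:
        raise ValueError(f"cannot sample {config.sample_n} diploids from {n_dip}")
    final_freq = float((adapt > 0).sum() / pop_2n)

    dip_idx = rng.choice(n_dip, size=config.sample_n, replace=False)
    chrom_idx = np.empty(2 * config.sample_n, dtype=np.int64)
    chrom_idx[0::2] = 2 * dip_idx
    chrom_idx[1::2] = 2 * dip_idx + 1
    samp_haps = [haps[c] for c in chrom_idx]
    samp_adapt = adapt[chrom_idx]

    all_pos = np.unique(
        np.concatenate([np.array(h, dtype=float) for h in samp_haps if h] or [np.empty(0)])
    )
    mat = np.zeros((len(samp_haps), all_pos.size), dtype=np.int8)
    for i, h in enumerate(samp_haps):
        if h:
            mat[i, np.searchsorted(all_pos, np.array(h, dtype=float))] = 1
    if (samp_adapt > 0).any():
        col = (samp_adapt > 0).astype(np.int8)[:, None]
        j = int(np.searchsorted(all_pos, site))
        all_pos = np.insert(all_pos, j, site)
        mat = np.hstack([mat[:, :j], col, mat[:, j:]])
    seg = (mat.sum(axis=0) > 0) & (mat.sum(axis=0) < mat.shape[0])
    mat, all_pos = mat[:, seg], all_pos[seg]

    origins = int(np.unique(samp_adapt[samp_adapt > 0]).size)
    return SimulatedSample(
        config=config,
        haplotypes=mat,
        positions=all_pos,
        adaptive_site=site,
        origin_labels=samp_adapt,
        origins_at_sampling=origins,
        carrier_haplotypes_at_onset=carriers_at_onset,
        carrier_snapshot=snapshot,
        selection_onset_generation=onset_gen,
        final_adaptive_freq=final_freq,
        n_restarts=0,
    )


def simulate_neutral_coalescent(config: SweepConfig, rng: np.random.Generator) -> SimulatedSample:
    """Neutral replicate drawn directly from the coalescent.

    Under neutrality the coalescent-initialized forward run adds no
    selected dynamics, so the sampled haplotypes can equivalently (and far
    more cheaply) be drawn from msprime at the sampling time under the
    same rescaled demography.  The forward simulator's neutral mode is the
    cross-check for this equivalence.
    """
    demo = config.demography()
    seed1, seed2 = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(2 * config.sample_n, population="pop", time=config.t_sample_r, ploidy=1)
        ],
        demography=demo.to_msprime(),
        sequence_length=config.L,
        recombination_rate=config.r_r,
        random_seed=seed1,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mu_r, model=msprime.BinaryMutationModel(), discrete_genome=False, random_seed=seed2
    )
    gm = ts.genotype_matrix().T.astype(np.int8)  # chromosomes x sites
    gm = np.minimum(gm, 1)
    pos = ts.tables.sites.position
    seg = (gm.sum(axis=0) > 0) & (gm.sum(axis=0) < gm.shape[0])
    cfg = config if config.mode == "neutral" else replace(config, mode="neutral", s=0.0, theta_a=None, f_init=None)
    return SimulatedSample(
        config=cfg,
        haplotypes=gm[:, seg],
        positions=pos[seg],
        adaptive_site=config.L / 2.0,
        origin_labels=np.zeros(2 * config.sample_n, dtype=np.int32),
        origins_at_sampling=0,
        carrier_haplotypes_at_onset=None,
        carrier_snapshot=None,
        selection_onset_generation=None,
        final_adaptive_freq=0.0,
        n_restarts=0,
    )


# ---------------------------------------------------------------------------
# aDNA-style sampling of a simulated window
# ---------------------------------------------------------------------------

def sample_to_pseudohap_window(
    sample: SimulatedSample,
    rng: np.random.Generator,
    n_snps: int = 201,
    missingness: MissingnessModel | None = None,
    chromosome: str = "1",
    pseudo_haploid: bool = True,
) -> AlleleCallMatrix:
    """Turn a simulated sample into a 177 x 201 pseudo-haploid window.

    Chromosomes are paired into diploids in sampling order, the diploid
    matrix is pseudo-haploidized, ``n_snps`` segregating sites are drawn
    uniformly without replacement (genomic order preserved), and beta-model
    missingness is optionally injected.  ``pseudo_haploid=False`` keeps the
    diploid multi-locus genotypes instead (for MLG-vs-pseudo-haplotype
    comparisons).
    """
    if sample.haplotypes is None:
        raise ValueError("sample carries no haplotypes (bookkeeping-only run)")
    n_sites = sample.haplotypes.shape[1]
    if n_sites < n_snps:
        raise ValueError(
            f"only {n_sites} segregating sites < {n_snps}; increase L or theta"
        )
    keep = np.sort(rng.choice(n_sites, size=n_snps, replace=False))
    hap = sample.haplotypes[:, keep]
    pos = sample.positions[keep]
    diploid = (hap[0::2] + hap[1::2]).astype(np.int8)

    bp = np.floor(pos).astype(np.int64) + 1
    for j in range(1, bp.size):  # de-collide after rounding; keeps order strict
        if bp[j] <= bp[j - 1]:
            bp[j] = bp[j - 1] + 1
    anc = rng.integers(0, 4, size=n_snps)
    der = (anc + rng.integers(1, 4, size=n_snps)) % 4
    snps = [
        SnpRecord(
            snp_id=f"sim_{chromosome}_{bp[j]}",
            chromosome=chromosome,
            genetic_pos=bp[j] * 1e-8,
            physical_pos=int(bp[j]),
            allele_ref=str(_NUCLEOTIDES[der[j]]),  # calls count the derived allele
            allele_alt=str(_NUCLEOTIDES[anc[j]]),
        )
        for j in range(n_snps)
    ]
    samples = [SampleRecord(sample_id=f"ind{i}", group_label="SIM") for i in range(diploid.shape[0])]
    matrix = AlleleCallMatrix(calls=diploid, ploidy_mode=DIPLOID_MLG, snps=snps, samples=samples)
    if pseudo_haploid:
        matrix = pseudo_haploidize(matrix, rng)
    if missingness is not None:
        matrix, _ = inject_missingness(matrix, missingness, rng)
    return matrix
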