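import math

import numpy as np
import pytest
from scipy import stats

from g12scan.adna_mimic import pseudo_haploidize
from g12scan.geno_io import DIPLOID_MLG, PSEUDO_HAPLOID
from g12scan.sweep_sim import (
    SimulatedSample,
    SweepConfig,
    build_demography,
    classify_softness,
    expected_footprint,
    sample_to_pseudohap_window,
    simulate,
    simulate_neutral_coalescent,
)


def constant_config(**kw):
    base = dict(
        mode="neutral",
        demography_model="constant",
        constant_size=500,
        rescale=1,
        t_onset=25,
        t_sample=5,
        sample_n=20,
        L=5e4,
    )
    base.update(kw)
    return SweepConfig(**base)


class TestDemography:
    def test_constant_model_single_epoch(self):
        demo = build_demography("constant", constant_size=1000)
        assert len(demo.epochs) == 1
        assert demo.size_at(0) == demo.size_at(1e6) == 1000

    def test_rescaling_preserves_theta(self):
        demo = build_demography("tennessen_european", lam=10)
        base = build_demography("tennessen_european", lam=1)
        for t in (0, 100, 500, 3000):
            # theta = 4 N mu invariant: N/lam with mu*lam
            assert demo.size_at(t / 10) * 10 == pytest.approx(base.size_at(t), rel=1e-9)

    def test_tennessen_epochs_monotone_with_recent_growth(self):
        demo = build_demography("tennessen_european")
        # recent growth: present-day size far exceeds ancestral
        assert demo.size_at(0) > 5e5 > demo.size_at(1000) > demo.ancestral_size / 10
        assert demo.epochs[0].growth_rate > demo.epochs[1].growth_rate > 0
        # sizes non-increasing going back through the recent growth phase
        ts = np.linspace(0, 900, 50)
        sizes = [demo.size_at(t) for t in ts]
        assert all(a >= b - 1e-9 for a, b in zip(sizes, sizes[1:]))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_demography("wright_1931")


class TestFootprint:
    def test_worked_examples(self):
        assert expected_footprint(0.04, 1e5, 1e-8) == pytest.approx(0.04 / (math.log(4000) * 1e-8))
        assert expected_footprint(0.05, 1e4, 1e-8) == pytest.approx(804_600, rel=1e-3)

    def test_domain_boundary(self):
        with pytest.raises(ValueError):
            expected_footprint(1e-4, 1e4, 1e-8)  # N_e s = 1


class TestNeutral:
    def test_segregating_sites_match_watterson(self, rng):
        cfg = constant_config()
        n_chrom = 2 * cfg.sample_n
        theta = 4 * cfg.constant_size * cfg.mu * cfg.L
        expect = theta * sum(1 / i for i in range(1, n_chrom))
        sd = math.sqrt(
            theta * sum(1 / i for i in range(1, n_chrom)) + theta**2 * sum(1 / i**2 for i in range(1, n_chrom))
        )
        counts = [simulate(cfg, rng).haplotypes.shape[1] for _ in range(8)]
        assert abs(np.mean(counts) - expect) < 3 * sd / math.sqrt(len(counts))

    def test_forward_neutral_matches_coalescent_oracle(self, rng):
        cfg = constant_config()
        fwd = [simulate(cfg, rng).haplotypes.shape[1] for _ in range(12)]
        coal = [simulate_neutral_coalescent(cfg, rng).haplotypes.shape[1] for _ in range(12)]
        assert stats.mannwhitneyu(fwd, coal).pvalue > 0.01

    def test_burnin_init_equivalent_diversity(self, rng):
        cfg = constant_config(constant_size=100, L=2e4, t_onset=10, t_sample=0, sample_n=10)
        coal = [simulate(cfg, rng).haplotypes.shape[1] for _ in range(10)]
        burn = [
            simulate(SweepConfig(**{**cfg.__dict__, "init": "burnin"}), rng).haplotypes.shape[1]
            for _ in range(10)
        ]
        assert stats.mannwhitneyu(coal, burn).pvalue > 0.01

    def test_theta_invariance_under_rescaling(self, rng):
        # neutral segregating-site counts indistinguishable between lam=1 and lam=5
        s1 = [
            simulate_neutral_coalescent(constant_config(), rng).haplotypes.shape[1]
            for _ in range(100)
        ]
        s5 = [
            simulate_neutral_coalescent(constant_config(rescale=5), rng).haplotypes.shape[1]
            for _ in range(100)
        ]
        assert stats.ks_2samp(s1, s5).pvalue > 0.05


class TestSweeps:
    def test_hard_sweep_conditioning_and_fixation(self, rng):
        # strong selection over a long window: fixation expected
        cfg = constant_config(mode="hard_de_novo", s=0.2, t_onset=300, t_sample=0)
        sample = simulate(cfg, rng, record_haplotypes=False)
        assert sample.final_adaptive_freq > 0.95

    def test_hard_sweep_present_at_sampling(self, rng):
        cfg = constant_config(mode="hard_de_novo", s=0.1, t_onset=40, t_sample=5)
        sample = simulate(cfg, rng)
        assert sample.final_adaptive_freq > 0
        assert (sample.origin_labels > 0).any() or sample.final_adaptive_freq > 0

    def test_classify_softness_contracts(self, rng):
        cfg = constant_config(mode="hard_de_novo", s=0.1, t_onset=40, t_sample=5)
        sample = simulate(cfg, rng, record_haplotypes=False)
        report = classify_softness(sample)
        assert report.label == "hard" and report.origins_at_sampling == 1

        neutral = simulate_neutral_coalescent(constant_config(), rng)
        with pytest.raises(ValueError):
            classify_softness(neutral)

    def test_recurrent_softness_labels(self):
        cfg = constant_config(mode="recurrent", s=0.1, theta_a=10.0, t_onset=40, t_sample=5)
        two = SimulatedSample(
            config=cfg, haplotypes=None, positions=None, adaptive_site=2.5e4,
            origin_labels=None, origins_at_sampling=2, carrier_haplotypes_at_onset=None,
            carrier_snapshot=None, selection_onset_generation=40,
            final_adaptive_freq=0.5, n_restarts=0,
        )
        assert classify_softness(two).label == "soft"

    def test_sgv_single_carrier_is_hard(self, rng):
        cfg = constant_config(mode="sgv", s=0.1, f_init=1e-4, t_onset=40, t_sample=5)
        # f_init below 1/(2N): selection starts at the first (single) copy
        sample = simulate(cfg, rng, record_haplotypes=False)
        assert sample.carrier_haplotypes_at_onset == 1
        assert classify_softness(sample).label == "hard"

    def test_softness_monotone_in_theta_a(self, rng):
        fracs = []
        for theta in (0.1, 1.0, 10.0):
            cfg = constant_config(mode="recurrent", s=0.1, theta_a=theta, t_onset=100, t_sample=5)
            soft = [
                classify_softness(simulate(cfg, rng, record_haplotypes=False)).label == "soft"
                for _ in range(60)
            ]
            fracs.append(np.mean(soft))
        assert fracs[0] <= fracs[1] + 0.1 and fracs[1] <= fracs[2] + 0.1
        assert fracs[2] > 0.9

    def test_softness_monotone_in_f_init(self, rng):
        fracs = []
        for f_init in (0.001, 0.01):
            cfg = constant_config(
                mode="sgv", s=0.1, f_init=f_init, constant_size=2000, t_onset=200, t_sample=5
            )
            multi = [
                simulate(cfg, rng, record_haplotypes=False).carrier_haplotypes_at_onset >= 2
                for _ in range(60)
            ]
            fracs.append(np.mean(multi))
        assert fracs[0] <= fracs[1] + 0.1


class TestWindowSampling:
    def test_dimensions_and_reproducibility(self, rng):
        cfg = constant_config(constant_size=2000, sample_n=177, L=5e5)
        sample = simulate_neutral_coalescent(cfg, rng)
        w1 = sample_to_pseudohap_window(sample, np.random.default_rng(3))
        w2 = sample_to_pseudohap_window(sample, np.random.default_rng(3))
        assert w1.calls.shape == (177, 201)
        assert w1.ploidy_mode == PSEUDO_HAPLOID
        assert np.array_equal(w1.calls, w2.calls)
        positions = [s.physical_pos for s in w1.snps]
        assert positions == sorted(positions)

    def test_diploid_window_preserves_frequencies(self, rng):
        cfg = constant_config(constant_size=2000, sample_n=50, L=5e5)
        sample = simulate_neutral_coalescent(cfg, rng)
        w = sample_to_pseudohap_window(sample, np.random.default_rng(5), pseudo_haploid=False)
        assert w.ploidy_mode == DIPLOID_MLG
        # every retained column's allele count matches some original column's
        orig = set((sample.haplotypes[0::2] + sample.haplotypes[1::2]).sum(axis=0).tolist())
        assert set(w.calls.sum(axis=0).tolist()) <= orig

    def test_too_few_sites_rejected(self, rng):
        cfg = constant_config(constant_size=100, L=1e4, sample_n=10)
        sample = simulate_neutral_coalescent(cfg, rng)
        with pytest.raises(ValueError, match="segregating"):
            sample_to_pseudohap_window(sample, rng)

    def test_pseudo_haploidization_applied(self, rng):
        cfg = constant_config(constant_size=2000, sample_n=30, L=5e5)
        sample = simulate_neutral_coalescent(cfg, rng)
        w = sample_to_pseudohap_window(sample, rng)
        assert set(np.unique(w.calls)) <= {0, 1}
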