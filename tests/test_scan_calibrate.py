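import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g12scan.mlg_g12 import ScanParams, ScanTrack
from g12scan.scan_calibrate import (
    CalibrationParams,
    QcMaskParams,
    call_peaks,
    neutral_threshold,
    neutral_zscores,
    power_and_roc,
    qc_masks,
    variance_explained_diagnostic,
    with_threshold,
)


def make_track(g12, chromosome="1", miss=None, recomb=None, jump=1, masked=None):
    g12 = np.asarray(g12, dtype=float)
    n = g12.size
    frame = pd.DataFrame(
        {
            "chromosome": [chromosome] * n,
            "focal_index": np.arange(n) * jump + 5,
            "focal_pos": (np.arange(n) + 5) * 1000,
            "start_index": np.arange(n) * jump,
            "end_index": np.arange(n) * jump + 10,
            "window_start": (np.arange(n)) * 1000 + 1,
            "window_end": (np.arange(n) + 10) * 1000,
            "g12": g12,
            "miss_frac": miss if miss is not None else np.zeros(n),
            "recomb_rate": recomb if recomb is not None else np.full(n, np.nan),
            "mask_recomb": np.zeros(n, dtype=bool),
            "mask_missing": np.zeros(n, dtype=bool),
            "mask_cross_pop": masked if masked is not None else np.zeros(n, dtype=bool),
        }
    )
    return ScanTrack(frame=frame, params=ScanParams(window=11, jump=jump))


def runs_oracle(track, threshold):
    """Maximal-run merging: the reference implementation for call_peaks."""
    out = []
    frame = track.unmasked()
    for chrom, grp in frame.groupby("chromosome", sort=False):
        grp = grp.sort_values("focal_index")
        run = []
        prev_idx = None
        for _, row in grp.iterrows():
            above = row.g12 > threshold
            adjacent = prev_idx is not None and row.focal_index - prev_idx == track.params.jump
            if above and (not run or adjacent):
                run.append(row)
            elif above:
                out.append(run)
                run = [row]
            elif run:
                out.append(run)
                run = []
            prev_idx = row.focal_index
        if run:
            out.append(run)
    return sorted(
        (str(r[0].chromosome), int(r[0].focal_index), int(r[-1].focal_index), max(x.g12 for x in r))
        for r in out
    )


class TestNeutralThreshold:
    def test_fifth_highest(self):
        assert neutral_threshold([5, 4, 3, 2, 1, 0.5], CalibrationParams(neutral_k=5, scale_k=False)) == 1

    def test_reference_size_uses_k_exactly(self):
        values = np.arange(58_350, dtype=float)
        assert neutral_threshold(values) == 58_345.0  # 5th highest

    def test_small_set_scales_to_maximum(self):
        values = np.linspace(0, 1, 1000)
        assert neutral_threshold(values) == 1.0  # k = max(1, round(5*1000/58350)) = 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            neutral_threshold([1.0, 2.0], CalibrationParams(neutral_k=5, neutral_n_reference=2, scale_k=False))

    @given(st.lists(st.floats(0.001, 1.0), min_size=6, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_transform_equivariance(self, values):
        thr = neutral_threshold(values)
        thr_exp = neutral_threshold(np.exp(values))
        assert thr_exp == pytest.approx(np.exp(thr))


class TestCallPeaks:
    def test_worked_example_two_peaks(self):
        track = make_track([0.1, 0.9, 0.95, 0.2, 0.8])
        peaks = call_peaks(track, 0.7)
        assert len(peaks) == 2
        assert (peaks[0].start_index, peaks[0].end_index) == (6, 7)
        assert peaks[0].representative_g12 == 0.95
        assert peaks[1].n_windows == 1 and peaks[1].representative_g12 == 0.8

    def test_all_below_threshold(self):
        assert call_peaks(make_track([0.1, 0.2]), 0.7) == []

    def test_plateau_single_peak(self):
        peaks = call_peaks(make_track([0.8, 0.8, 0.8]), 0.7)
        assert len(peaks) == 1
        assert peaks[0].representative_g12 == 0.8 and peaks[0].n_windows == 3

    def test_masked_windows_break_runs(self):
        masked = np.array([False, False, True, False, False])
        peaks = call_peaks(make_track([0.9, 0.9, 0.9, 0.9, 0.9], masked=masked), 0.7)
        assert len(peaks) == 2

    def test_seed_and_extend_equals_run_merging_oracle(self, rng):
        for _ in range(300):
            n = rng.integers(3, 40)
            track = make_track(
                rng.random(n),
                masked=rng.random(n) < 0.2,
                jump=int(rng.integers(1, 3)),
            )
            threshold = float(rng.random())
            got = sorted(
                (p.chromosome, p.start_index, p.end_index, p.representative_g12)
                for p in call_peaks(track, threshold)
            )
            assert got == runs_oracle(track, threshold)


class TestQcMasks:
    def test_lowest_recomb_percentile(self):
        track = make_track(np.full(100, 0.5), recomb=np.arange(1.0, 101.0))
        out = qc_masks(track, QcMaskParams())
        assert np.flatnonzero(out.frame["mask_recomb"]).tolist() == [0, 1, 2, 3, 4]

    def test_missing_iqr_rule(self):
        # constructed quartiles: Q3=0.6, IQR=0.2 -> mask iff miss > 0.75
        miss = np.array([0.4, 0.45, 0.5, 0.55, 0.6, 0.74, 0.76, 0.9])
        q1, q3 = np.percentile(miss, [25, 75])
        cut = q3 + 0.75 * (q3 - q1)
        track = make_track(np.full(miss.size, 0.5), miss=miss)
        out = qc_masks(track)
        assert out.frame["mask_missing"].tolist() == (miss > cut).tolist()

    def test_cross_population_consistent_top_peaks(self):
        high = make_track(np.array([0.1, 0.9, 0.1, 0.1]))
        low = make_track(np.array([0.1, 0.1, 0.1, 0.9]))
        target = make_track(np.array([0.2, 0.8, 0.2, 0.2]))
        three_hit = [with_threshold(high, 0.5)] * 3
        out = qc_masks(target, cross_pop_tracks=three_hit)
        assert out.frame["mask_cross_pop"].tolist() == [False, True, False, False]
        mixed = [with_threshold(high, 0.5)] * 2 + [with_threshold(low, 0.5)]
        out2 = qc_masks(target, cross_pop_tracks=mixed)
        assert not out2.frame["mask_cross_pop"].any()

    def test_cross_population_needs_two_tracks(self, caplog):
        track = make_track(np.array([0.1, 0.9]))
        out = qc_masks(track, cross_pop_tracks=[with_threshold(track, 0.5)])
        assert not out.frame["mask_cross_pop"].any()

    def test_masks_only_remove_windows(self, rng):
        # peak set after masking is a subset of the peak set before
        for _ in range(50):
            n = 50
            track = make_track(rng.random(n), miss=rng.random(n) * 0.5, recomb=rng.random(n))
            out = qc_masks(track)
            thr = 0.5
            before = {(p.start_index, p.end_index) for p in call_peaks(track, thr)}
            after_windows = set()
            for p in call_peaks(out, thr):
                after_windows.update(range(p.start_index, p.end_index + 1))
            before_windows = set()
            for a, b in before:
                before_windows.update(range(a, b + 1))
            assert after_windows <= before_windows


class TestPowerRoc:
    def test_calibration_identity(self, rng):
        neutral = rng.normal(size=20_000)
        sweep = rng.normal(size=20_000)
        res = power_and_roc(sweep, neutral, fdr=0.01)
        assert res.tpr == pytest.approx(0.01, abs=0.005)
        assert res.auc == pytest.approx(0.5, abs=0.02)

    def test_perfect_separation(self, rng):
        res = power_and_roc(rng.normal(10, 1, 500), rng.normal(0, 1, 500), fdr=0.01)
        assert res.tpr == 1.0 and res.auc == 1.0
        assert res.ci95[0] > 0.98

    def test_wilson_interval_brackets_tpr(self, rng):
        res = power_and_roc(rng.normal(1, 1, 200), rng.normal(0, 1, 500), fdr=0.05)
        assert res.ci95[0] <= res.tpr <= res.ci95[1]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_and_roc([], [1.0])


class TestZScores:
    def test_gaussian_quantiles(self, rng):
        neutral = rng.normal(0.2, 0.05, 10_000)
        mean, sd = neutral.mean(), neutral.std(ddof=1)
        track = make_track([mean, mean + 1.96 * sd, mean + 3 * sd])
        out = neutral_zscores(track, neutral)
        assert out["z"].iloc[0] == pytest.approx(0, abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(0.5)
        assert out["p"].iloc[1] == pytest.approx(0.025, abs=1e-4)
        assert out["p"].is_monotonic_decreasing

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            neutral_zscores(make_track([0.5]), [0.3, 0.3])


class TestVarianceDiagnostic:
    def test_independent_covariates_give_small_r2(self, rng):
        n = 500
        track = make_track(rng.random(n), miss=rng.random(n), recomb=rng.random(n))
        track.frame["window_end"] = track.frame["window_start"] + rng.integers(1000, 2000, n)
        assert variance_explained_diagnostic(track) < 0.05

    def test_linear_function_of_missingness_gives_r2_one(self, rng):
        n = 100
        miss = rng.random(n)
        track = make_track(0.1 + 0.5 * miss, miss=miss, recomb=rng.random(n))
        assert variance_explained_diagnostic(track) > 0.999

    def test_requires_enough_windows(self):
        with pytest.raises(ValueError, match="10"):
            variance_explained_diagnostic(make_track([0.1] * 5))
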