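"""Simulation-calibrated significance, peak calling, QC and power.

The genome-wide significance threshold for a G12 scan is an order
statistic of neutral-simulation values: by default the 5th highest of
58,350 neutral replicates (10x the number of independent analysis
windows); for other neutral-set sizes n the rank scales as
k = max(1, round(5 n / 58,350)).  Consecutive super-threshold analysis
windows are merged into "peaks", each represented by its maximum G12.

QC masks remove windows whose signal is plausibly artifactual: mean
recombination rate in the lowest 5th percentile genome-wide, mean missing
fraction above Q3 + 0.75 x IQR, or membership in a peak that ranks in the
top 20 in *every* population of a cross-population panel (the same sweep
across very different ancestries and times is more likely a data-
processing artifact than biology).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .mlg_g12 import ScanTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationParams:
    """Order-statistic threshold rule for neutral calibration."""

    neutral_k: int = 5
    neutral_n_reference: int = 58_350
    fdr: float = 0.01
    scale_k: bool = True  # rescale k with the neutral-set size; False = literal k


@dataclass(frozen=True)
class QcMaskParams:
    recomb_percentile: float = 5.0
    missing_iqr_factor: float = 0.75
    cross_pop_top_k: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.recomb_percentile < 100:
            raise ValueError("recomb_percentile must be in (0, 100)")


@dataclass(frozen=True)
class Peak:
    """A maximal run of contiguous super-threshold analysis windows."""

    chromosome: str
    start_index: int  # focal SNP index of the first member window
    end_index: int
    start_pos: int  # bp (1-based inclusive)
    end_pos: int
    representative_g12: float  # maximum over member windows
    n_windows: int


def neutral_threshold(neutral_values, params: CalibrationParams | None = None) -> float:
    """k-th highest neutral G12 value, with k rescaled for the set size.

    With the defaults and n = 58,350 neutral values this is the 5th
    highest; for other n, k = max(1, round(5 n / 58,350)).  The rule is
    rank-based, hence equivariant under monotone transforms.
    """
    params = params or CalibrationParams()
    values = np.sort(np.asarray(neutral_values, dtype=float))[::-1]
    n = values.size
    if n == 0:
        raise ValueError("no neutral values supplied")
    if n == params.neutral_n_reference or not params.scale_k:
        k = params.neutral_k
    else:
        k = max(1, round(params.neutral_k * n / params.neutral_n_reference))
    if k > n:
        raise ValueError(f"order statistic k={k} exceeds n={n}")
    return float(values[k - 1])


def call_peaks(track: ScanTrack, threshold: float) -> list[Peak]:
    """Merge contiguous super-threshold windows into peaks.

    Implemented as seed-and-extend: repeatedly take the highest unconsumed
    super-threshold window and grow it upstream/downstream over adjacent
    (focal-index step == jump) super-threshold windows.  This is
    equivalent to merging maximal runs; the seed of each run is its
    representative (maximum) G12.  Masked windows are excluded and break
    contiguity.
    """
    jump = track.params.jump
    peaks: list[Peak] = []
    frame = track.unmasked()
    for chrom, grp in frame.groupby("chromosome", sort=False):
        grp = grp.sort_values("focal_index")
        idx = grp["focal_index"].to_numpy()
        g12 = grp["g12"].to_numpy()
        pos = grp["focal_pos"].to_numpy()
        above = g12 > threshold
        consumed = np.zeros(idx.size, dtype=bool)
        order = np.argsort(-g12, kind="stable")
        for seed in order:
            if consumed[seed] or not above[seed]:
                continue
            lo = hi = seed
            while lo - 1 >= 0 and above[lo - 1] and not consumed[lo - 1] and idx[lo] - idx[lo - 1] == jump:
                lo -= 1
            while hi + 1 < idx.size and above[hi + 1] and not consumed[hi + 1] and idx[hi + 1] - idx[hi] == jump:
                hi += 1
            consumed[lo : hi + 1] = True
            peaks.append(
                Peak(
                    chromosome=str(chrom),
                    start_index=int(idx[lo]),
                    end_index=int(idx[hi]),
                    start_pos=int(pos[lo]),
                    end_pos=int(pos[hi]),
                    representative_g12=float(g12[seed]),
                    n_windows=int(hi - lo + 1),
                )
            )
    peaks.sort(key=lambda p: (p.chromosome, p.start_index))
    return peaks


def top_peaks(track: ScanTrack, threshold: float, k: int) -> list[Peak]:
    """The k highest-representative peaks of a track."""
    return sorted(call_peaks(track, threshold), key=lambda p: -p.representative_g12)[:k]


def qc_masks(
    track: ScanTrack,
    params: QcMaskParams | None = None,
    cross_pop_tracks: list[ScanTrack] | None = None,
    cross_pop_thresholds: list[float] | None = None,
) -> ScanTrack:
    """Flag windows failing QC; returns a new track with masks set.

    Rules (flagged separately, combined by :attr:`ScanTrack.masked`):

    a. mean window recombination rate in the lowest ``recomb_percentile``
       of all windows (skipped when no recombination map was supplied);
    b. mean missing fraction above Q3 + 0.75 x IQR of all windows;
    c. window lies inside a top-``cross_pop_top_k`` peak of *every*
       supplied cross-population track (skipped with a warning when fewer
       than two tracks are supplied).
    """
    params = params or QcMaskParams()
    frame = track.frame.copy()

    rates = frame["recomb_rate"].to_numpy()
    if np.isfinite(rates).all() and rates.size:
        cutoff = np.percentile(rates, params.recomb_percentile)
        frame["mask_recomb"] = rates <= cutoff
    elif np.isfinite(rates).any():
        raise ValueError("recombination rates are partially missing")

    miss = frame["miss_frac"].to_numpy()
    q1, q3 = np.percentile(miss, [25, 75])
    frame["mask_missing"] = miss > q3 + params.missing_iqr_factor * (q3 - q1)

    if cross_pop_tracks is not None:
        if len(cross_pop_tracks) < 2:
            logger.warning("cross-population rule needs >= 2 tracks; skipped")
        else:
            if cross_pop_thresholds is None:
                cross_pop_thresholds = [t.threshold for t in cross_pop_tracks]
            if any(thr is None for thr in cross_pop_thresholds):
                raise ValueError("cross-population tracks need thresholds")
            interval_sets = []
            for t, thr in zip(cross_pop_tracks, cross_pop_thresholds):
                peaks = top_peaks(t, thr, params.cross_pop_top_k)
                interval_sets.append([(p.chromosome, p.start_pos, p.end_pos) for p in peaks])
            chroms = frame["chromosome"].to_numpy()
            pos = frame["focal_pos"].to_numpy()
            in_all = np.ones(len(frame), dtype=bool)
            for intervals in interval_sets:
                hit = np.zeros(len(frame), dtype=bool)
                for chrom, a, b in intervals:
                    hit |= (chroms == chrom) & (pos >= a) & (pos <= b)
                in_all &= hit
            frame["mask_cross_pop"] = in_all

    return ScanTrack(frame=frame, params=track.params, threshold=track.threshold)


@dataclass(frozen=True)
class PowerResult:
    tpr: float
    ci95: tuple[float, float]
    threshold: float
    fpr_grid: np.ndarray
    tpr_grid: np.ndarray
    auc: float


def power_and_roc(sweep_values, neutral_values, fdr: float = 0.01) -> PowerResult:
    """True-positive rate at an FDR-calibrated threshold, plus the ROC.

    The detection threshold is the (1 - fdr) inverse-ECDF quantile of the
    neutral values; TPR is the fraction of sweep values above it, with a
    Wilson 95% interval.  The ROC sweeps the threshold over the pooled
    values; AUC by the trapezoid rule (scikit-learn).
    """
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import roc_curve
    from statsmodels.stats.proportion import proportion_confint

    sweep = np.asarray(sweep_values, dtype=float)
    neutral = np.asarray(neutral_values, dtype=float)
    if sweep.size == 0 or neutral.size == 0:
        raise ValueError("both sweep and neutral value lists must be non-empty")
    if neutral.size < 1 / fdr:
        logger.warning("only %d neutral values for FDR %.3g; quantile unstable", neutral.size, fdr)
    threshold = float(np.quantile(neutral, 1 - fdr, method="inverted_cdf"))
    n_above = int((sweep > threshold).sum())
    tpr = n_above / sweep.size
    lo, hi = proportion_confint(n_above, sweep.size, alpha=0.05, method="wilson")
    labels = np.concatenate([np.ones(sweep.size), np.zeros(neutral.size)])
    fpr_grid, tpr_grid, _ = roc_curve(labels, np.concatenate([sweep, neutral]))
    return PowerResult(
        tpr=tpr,
        ci95=(float(lo), float(hi)),
        threshold=threshold,
        fpr_grid=fpr_grid,
        tpr_grid=tpr_grid,
        auc=float(_auc(fpr_grid, tpr_grid)),
    )


def neutral_zscores(track: ScanTrack, neutral_values) -> pd.DataFrame:
    """Per-focal-SNP z-scores and upper-tail Gaussian p against neutrality.

    z = (G12 - mean_neutral) / sd_neutral; p = P(Z > z) under the standard
    Gaussian.  Requires at least two neutral values with positive spread.
    """
    neutral = np.asarray(neutral_values, dtype=float)
    if neutral.size < 2:
        raise ValueError("need >= 2 neutral values")
    mean, sd = neutral.mean(), neutral.std(ddof=1)
    if sd == 0:
        raise ValueError("neutral values have zero variance")
    z = (track.frame["g12"].to_numpy() - mean) / sd
    return pd.DataFrame(
        {
            "chromosome": track.frame["chromosome"],
            "focal_pos": track.frame["focal_pos"],
            "g12": track.frame["g12"],
            "z": z,
            "p": stats.norm.sf(z),
        }
    )


def variance_explained_diagnostic(track: ScanTrack) -> float:
    """Joint OLS R^2 of G12 on window bp span, missingness and recombination.

    A well-masked scan should leave these nuisance covariates explaining
    only a small share of the variance in G12.  Masked windows are
    excluded; all-NaN covariates (e.g. no recombination map) are dropped
    with a warning.
    """
    import statsmodels.api as sm

    frame = track.unmasked().copy()
    if len(frame) < 10:
        raise ValueError("need at least 10 unmasked windows for the regression")
    frame["span"] = frame["window_end"] - frame["window_start"] + 1
    cols = ["span", "miss_frac", "recomb_rate"]
    use = []
    for c in cols:
        if frame[c].notna().all():
            use.append(c)
        else:
            logger.warning("covariate %s missing; dropped from the diagnostic", c)
    X = sm.add_constant(frame[use].to_numpy(dtype=float))
    fit = sm.OLS(frame["g12"].to_numpy(dtype=float), X).fit()
    return float(fit.rsquared)


def with_threshold(track: ScanTrack, threshold: float) -> ScanTrack:
    """Attach a calibrated threshold to a track (functional update)."""
    return dc_replace(track, threshold=threshold)
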