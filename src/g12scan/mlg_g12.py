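"""Multi-locus genotype clustering and the G12 scan statistic.

G12 summarizes how concentrated the multi-site genotype (or pseudo-
haplotype) frequency spectrum is inside a fixed-SNP analysis window:

    G12 = (q1 + q2)^2 + q3^2 + ... + qn^2

with q1 >= q2 >= ... >= qn the descending frequencies of the unique
multi-site genotype clusters.  Pooling the two most common classes makes
the statistic sensitive to soft as well as hard sweeps.

Missing-data handling follows the pseudo-haploid aDNA protocol: within a
window, an individual joins the first existing cluster whose founding row
matches at every site where both are non-missing; individuals missing more
than a threshold fraction ``m`` (default 0.9) of the window are kept as
singletons so that mostly-missing rows cannot glue unrelated clusters
together and inflate G12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, AlleleCallMatrix, RecombinationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringParams:
    """Parameters of the missing-data-aware genotype clustering.

    ``singleton_missing_threshold``: rows with a missing fraction strictly
    greater than this are never merged and never founded upon.  Set to 1.0
    (or use :func:`cluster_window` with ``params=None``) to disable.
    """

    singleton_missing_threshold: float = 0.9

    def __post_init__(self) -> None:
        m = self.singleton_missing_threshold
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"singleton_missing_threshold must be in [0,1], got {m}")


@dataclass(frozen=True)
class ClusterSpectrum:
    """Descending cluster frequencies q1 >= ... >= qn within one window."""

    q: tuple[float, ...]
    sample_count: int

    def __post_init__(self) -> None:
        if not self.q:
            raise ValueError("empty cluster spectrum")
        arr = np.asarray(self.q, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("all cluster frequencies must be positive")
        if np.any(np.diff(arr) > 1e-12):
            raise ValueError("cluster frequencies must be sorted descending")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"cluster frequencies sum to {arr.sum()}, not 1")
        if len(self.q) > self.sample_count:
            raise ValueError("more clusters than individuals")

    @property
    def n(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class ScanParams:
    """Window geometry of the scan: SNPs per window and focal-SNP jump."""

    window: int = 201
    jump: int = 1

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must span at least 2 SNPs")
        if self.jump < 1:
            raise ValueError("jump must be >= 1")
        if self.window % 2 == 0:
            logger.warning("even window size %d; an odd, centered window is recommended", self.window)


@dataclass
class ScanTrack:
    """Per-focal-SNP G12 values with window metadata and QC mask flags."""

    frame: pd.DataFrame
    params: ScanParams = field(default_factory=ScanParams)
    threshold: float | None = None

    COLUMNS = [
        "chromosome",
        "focal_index",
        "focal_pos",
        "start_index",
        "end_index",
        "window_start",
        "window_end",
        "g12",
        "miss_frac",
        "recomb_rate",
        "mask_recomb",
        "mask_missing",
        "mask_cross_pop",
    ]

    @property
    def masked(self) -> pd.Series:
        f = self.frame
        return f["mask_recomb"] | f["mask_missing"] | f["mask_cross_pop"]

    def unmasked(self) -> pd.DataFrame:
        return self.frame[~self.masked]


def cluster_window(window_calls: np.ndarray, params: ClusteringParams | None = None) -> ClusterSpectrum:
    """Greedily cluster window rows into multi-site genotype classes.

    Rows are processed in fixed input order; a row joins the first existing
    cluster whose *founding* row matches at every position where both are
    non-missing.  Rows with a missing fraction exceeding the singleton
    threshold are always singletons.  ``params=None`` disables the
    singleton rule (equivalent to threshold 1.0 on rows that are not fully
    missing).
    """
    calls = np.asarray(window_calls)
    if calls.ndim != 2 or calls.shape[1] == 0:
        raise ValueError("window must be a non-empty individuals x SNPs matrix")
    n_ind, width = calls.shape
    if n_ind == 0:
        raise ValueError("window contains no individuals")
    m = params.singleton_missing_threshold if params is not None else 1.0

    miss = calls == MISSING
    miss_frac = miss.mean(axis=1)
    always_singleton = miss_frac > m

    if not miss.any() and not always_singleton.any():
        # no missing data: greedy first-fit reduces to exact unique-row counting
        _, first_idx, counts = np.unique(calls, axis=0, return_index=True, return_counts=True)
        order = np.argsort(first_idx)  # creation order
        counts = counts[order]
    else:
        reps: list[np.ndarray] = []
        rep_miss: list[np.ndarray] = []
        open_cluster: list[bool] = []
        counts_l: list[int] = []
        for i in range(n_ind):
            row = calls[i]
            row_miss = miss[i]
            if not always_singleton[i] and reps:
                open_idx = [k for k, o in enumerate(open_cluster) if o]
                if open_idx:
                    R = np.stack([reps[k] for k in open_idx])
                    RM = np.stack([rep_miss[k] for k in open_idx])
                    ok = ((R == row) | RM | row_miss).all(axis=1)
                    hit = np.flatnonzero(ok)
                    if hit.size:
                        counts_l[open_idx[int(hit[0])]] += 1
                        continue
            if always_singleton[i]:
                reps.append(row)
                rep_miss.append(row_miss)
                open_cluster.append(False)
                counts_l.append(1)
            else:
                reps.append(row)
                rep_miss.append(row_miss)
                open_cluster.append(True)
                counts_l.append(1)
        counts = np.asarray(counts_l)

    # descending frequency, ties broken by cluster creation index (stable sort)
    order = np.argsort(-counts, kind="stable")
    q = tuple((counts[order] / n_ind).tolist())
    return ClusterSpectrum(q=q, sample_count=n_ind)


def g12_from_spectrum(spectrum: ClusterSpectrum) -> float:
    """Evaluate G12 = (q1+q2)^2 + sum_{i>=3} qi^2 (G12 = q1^2 = 1 if n = 1)."""
    q = np.asarray(spectrum.q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("cluster frequencies do not sum to 1")
    if q.size == 1:
        return float(q[0] ** 2)
    return float((q[0] + q[1]) ** 2 + np.sum(q[2:] ** 2))


def g12_window(window_calls: np.ndarray, params: ClusteringParams | None = None) -> float:
    """Convenience: cluster one window and return its G12."""
    return g12_from_spectrum(cluster_window(window_calls, params))


def scan_g12(
    matrix: AlleleCallMatrix,
    scan_params: ScanParams | None = None,
    clustering_params: ClusteringParams | None = None,
    recomb_map: RecombinationMap | None = None,
) -> ScanTrack:
    """Slide fixed-SNP windows along each chromosome and compute G12.

    Windows advance by ``jump`` in SNP-index space with the focal SNP at the
    window center; windows that would extend past either chromosome end are
    skipped entirely (G12 magnitude depends on window SNP count, so
    truncated windows would mix scales).  Per-window mean missing fraction
    and mean recombination rate are recorded for downstream QC.
    """
    scan_params = scan_params or ScanParams()
    if clustering_params is None:
        clustering_params = ClusteringParams()
    w, jump = scan_params.window, scan_params.jump
    left = w // 2
    right = w - left - 1

    if matrix.snps:
        chroms = pd.Series([s.chromosome for s in matrix.snps])
        positions = np.array([s.physical_pos for s in matrix.snps])
    else:
        chroms = pd.Series(["1"] * matrix.n_sites)
        positions = np.arange(1, matrix.n_sites + 1)

    rows = []
    for chrom in chroms.unique():
        idx = np.flatnonzero((chroms == chrom).to_numpy())
        n = idx.size
        if n < w:
            logger.info("chromosome %s has %d SNPs < window %d; skipped", chrom, n, w)
            continue
        snp_rates = (
            recomb_map.rates_for([matrix.snps[j] for j in idx])
            if (recomb_map is not None and matrix.snps)
            else None
        )
        for focal in range(left, n - right, jump):
            a, b = focal - left, focal + right
            cols = idx[a : b + 1]
            sub = matrix.calls[:, cols]
            g12 = g12_from_spectrum(cluster_window(sub, clustering_params))
            rows.append(
                {
                    "chromosome": chrom,
                    "focal_index": int(idx[focal]),
                    "focal_pos": int(positions[idx[focal]]),
                    "start_index": int(cols[0]),
                    "end_index": int(cols[-1]),
                    "window_start": int(positions[cols[0]]),
                    "window_end": int(positions[cols[-1]]),
                    "g12": g12,
                    "miss_frac": float((sub == MISSING).mean()),
                    "recomb_rate": float(snp_rates[a : b + 1].mean()) if snp_rates is not None else np.nan,
                    "mask_recomb": False,
                    "mask_missing": False,
                    "mask_cross_pop": False,
                }
            )
    frame = pd.DataFrame(rows, columns=ScanTrack.COLUMNS)
    # geno_io score tables use focal_pos/window bounds; keep dtypes tidy
    return ScanTrack(frame=frame, params=scan_params)
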