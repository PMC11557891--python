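"""Genotype I/O and the in-memory genotype model.

This module reads and writes the standard population-genetics formats the
scan touches — ASCII EIGENSTRAT triplets (``.geno``/``.snp``/``.ind``),
biallelic-SNP VCF, whitespace-delimited recombination maps — and assembles
the :class:`AlleleCallMatrix` that every downstream stage consumes.

Conventions
-----------
* Internal coordinates are 1-based inclusive; BED output is 0-based
  half-open.
* ``MISSING`` calls are stored as ``-1`` in the integer call matrix.
* EIGENSTRAT genotype digits count copies of the ``.snp`` file's *ref*
  allele column; VCF genotypes count ALT alleles (0/0 -> 0, 1/1 -> 2).
  The scan statistics are label-invariant so the two conventions coexist.
* Pseudo-haploid EIGENSTRAT files encode single-allele calls as {0, 2, 9};
  the reader normalizes these to {0, 1, MISSING}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele call in any call matrix.
MISSING: int = -1

DIPLOID_MLG = "diploid_mlg"
PSEUDO_HAPLOID = "pseudo_haploid"


class FormatError(ValueError):
    """A file violated the structural contract of its format."""


@dataclass(frozen=True)
class SnpRecord:
    """One site on the SNP panel (1-based physical coordinates)."""

    snp_id: str
    chromosome: str
    genetic_pos: float  # Morgans
    physical_pos: int  # 1-based bp
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.physical_pos <= 0:
            raise ValueError(f"physical_pos must be positive, got {self.physical_pos}")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"ref and alt alleles identical at {self.snp_id}")


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual with its population / epoch label."""

    sample_id: str
    group_label: str = ""


@dataclass
class AlleleCallMatrix:
    """Individuals x sites matrix of allele calls.

    ``calls[i, j]`` is the call of individual ``i`` at site ``j``:
    {0, 1, 2, MISSING} for ``diploid_mlg`` (allele copy counts) or
    {0, 1, MISSING} for ``pseudo_haploid`` (a single sampled allele).
    """

    calls: np.ndarray
    ploidy_mode: str
    snps: list[SnpRecord] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x sites matrix")
        if self.ploidy_mode not in (DIPLOID_MLG, PSEUDO_HAPLOID):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.snps and len(self.snps) != self.calls.shape[1]:
            raise ValueError(
                f"{len(self.snps)} SNP records for {self.calls.shape[1]} matrix columns"
            )
        if self.samples and len(self.samples) != self.calls.shape[0]:
            raise ValueError(
                f"{len(self.samples)} sample records for {self.calls.shape[0]} matrix rows"
            )
        allowed = {0, 1, 2, MISSING} if self.ploidy_mode == DIPLOID_MLG else {0, 1, MISSING}
        present = set(np.unique(self.calls).tolist())
        if not present <= allowed:
            raise ValueError(f"calls contain values {present - allowed} not allowed in {self.ploidy_mode}")
        # panel must be position-sorted with no duplicate positions per chromosome
        seen: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        for rec in self.snps:
            key = (rec.chromosome, rec.physical_pos)
            if key in seen:
                raise ValueError(f"duplicate SNP position {key}")
            seen.add(key)
            if prev is not None and rec.chromosome == prev[0] and rec.physical_pos < prev[1]:
                raise ValueError(f"SNPs not sorted by position at {key}")
            prev = key

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def take_sites(self, idx: Sequence[int]) -> "AlleleCallMatrix":
        """Subset to the site columns ``idx`` (order preserved)."""
        idx = list(idx)
        return AlleleCallMatrix(
            calls=self.calls[:, idx],
            ploidy_mode=self.ploidy_mode,
            snps=[self.snps[j] for j in idx] if self.snps else [],
            samples=self.samples,
        )


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rates keyed by chromosome.

    A SNP takes the rate of the map interval containing it; positions
    before the first map point take the first rate, positions at or past
    the last map point take the last rate.  Rates are in whatever unit the
    source file uses (typically cM/Mb); the scan only compares them.
    """

    positions: dict[str, np.ndarray]  # 1-based bp, strictly increasing
    rates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            rate = np.asarray(self.rates[chrom], dtype=float)
            if pos.shape != rate.shape:
                raise ValueError(f"positions/rates length mismatch on {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"map positions not strictly increasing on {chrom}")
            if np.any(rate < 0):
                raise FormatError(f"negative recombination rate on {chrom}")
            self.positions[chrom] = pos
            self.rates[chrom] = rate

    def rate_at(self, chromosome: str, physical_pos: int) -> float:
        """Rate of the interval enclosing ``physical_pos``."""
        pos = self.positions[chromosome]
        rates = self.rates[chromosome]
        i = int(np.searchsorted(pos, physical_pos, side="right")) - 1
        return float(rates[max(i, 0)])

    def rates_for(self, snps: Iterable[SnpRecord]) -> np.ndarray:
        return np.array([self.rate_at(s.chromosome, s.physical_pos) for s in snps])


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path) -> AlleleCallMatrix:
    """Read an ASCII EIGENSTRAT triplet into an :class:`AlleleCallMatrix`.

    Genotype digits count copies of the ``.snp`` *ref* allele; ``9`` is
    missing.  A file containing only {0, 2, 9} is interpreted as
    pseudo-haploid (one allele call per site) and remapped to
    {0, 1, MISSING}; any ``1`` marks the file as diploid MLG.
    """
    snps: list[SnpRecord] = []
    with open(snp_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise FormatError(f"{snp_path}:{line_no}: expected 6 columns, got {len(parts)}")
            snps.append(
                SnpRecord(
                    snp_id=parts[0],
                    chromosome=parts[1],
                    genetic_pos=float(parts[2]),
                    physical_pos=int(parts[3]),
                    allele_ref=parts[4],
                    allele_alt=parts[5],
                )
            )
    samples: list[SampleRecord] = []
    with open(ind_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(SampleRecord(sample_id=parts[0], group_label=parts[-1]))

    rows: list[np.ndarray] = []
    with open(geno_path) as fh:
        for row_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(samples):
                raise FormatError(
                    f"{geno_path}:{row_no}: row width {len(line)} != {len(samples)} individuals"
                )
            row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = ~np.isin(row, (0, 1, 2, 9))
            if bad.any():
                col = int(np.argmax(bad)) + 1
                raise FormatError(f"{geno_path}:{row_no}: invalid genotype character at column {col}")
            rows.append(row.astype(np.int8))
    if len(rows) != len(snps):
        raise FormatError(
            f"{geno_path}: {len(rows)} genotype rows but {snp_path} lists {len(snps)} SNPs"
        )

    calls = np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    if np.any(calls == 1):
        mode = DIPLOID_MLG
        calls = np.where(calls == 9, MISSING, calls).astype(np.int8)
    else:
        mode = PSEUDO_HAPLOID
        remap = {0: 0, 2: 1, 9: MISSING}
        calls = np.vectorize(remap.get, otypes=[np.int8])(calls) if calls.size else calls
    return AlleleCallMatrix(calls=calls, ploidy_mode=mode, snps=snps, samples=samples)


def write_eigenstrat(matrix: AlleleCallMatrix, out_prefix) -> None:
    """Write ``<prefix>.geno/.snp/.ind`` in the ASCII dialect read above."""
    out_prefix = str(out_prefix)
    with open(out_prefix + ".snp", "w") as fh:
        for s in matrix.snps:
            fh.write(
                f"{s.snp_id}\t{s.chromosome}\t{s.genetic_pos:.6f}\t{s.physical_pos}"
                f"\t{s.allele_ref}\t{s.allele_alt}\n"
            )
    with open(out_prefix + ".ind", "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s.sample_id}\tU\t{s.group_label or 'POP'}\n")
    calls = matrix.calls
    if matrix.ploidy_mode == PSEUDO_HAPLOID:
        coded = np.where(calls == MISSING, 9, np.where(calls == 1, 2, 0))
    else:
        coded = np.where(calls == MISSING, 9, calls)
    coded = coded.astype(np.uint8) + ord("0")
    with open(out_prefix + ".geno", "w") as fh:
        for j in range(matrix.n_sites):
            fh.write(coded[:, j].tobytes().decode("ascii") + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_biallelic(vcf_path) -> AlleleCallMatrix:
    """Read biallelic SNPs from a VCF into a diploid-MLG matrix.

    Multi-allelic records are skipped (a count is logged).  GT is mapped to
    the ALT-allele count; any missing allele in the GT makes the call
    MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = [SampleRecord(sample_id=s) for s in vcf.samples]
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF is None:
            n_skipped += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1); last col = phased flag
        alleles = gts[:, :-1]
        call = np.where(
            (alleles < 0).any(axis=1), MISSING, (alleles > 0).sum(axis=1)
        ).astype(np.int8)
        snps.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}_{var.POS}",
                chromosome=str(var.CHROM),
                genetic_pos=0.0,
                physical_pos=int(var.POS),
                allele_ref=str(var.REF),
                allele_alt=str(var.ALT[0]),
            )
        )
        columns.append(call)
    if n_skipped:
        logger.info("read_vcf_biallelic: skipped %d multi-allelic records", n_skipped)
    calls = (
        np.vstack(columns).T if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return AlleleCallMatrix(calls=calls, ploidy_mode=DIPLOID_MLG, snps=snps, samples=samples)


# ---------------------------------------------------------------------------
# Panel ascertainment
# ---------------------------------------------------------------------------

def ascertain_to_panel(
    matrix: AlleleCallMatrix, panel_positions: Iterable[tuple[str, int]]
) -> AlleleCallMatrix:
    """Restrict the matrix to sites present on a capture panel.

    ``panel_positions`` is an iterable of ``(chromosome, physical_pos)``
    keys.  Site order of the matrix is preserved; the sample set is
    untouched.  Idempotent by construction.
    """
    panel = set(panel_positions)
    keep = [
        j for j, s in enumerate(matrix.snps) if (s.chromosome, s.physical_pos) in panel
    ]
    if not keep:
        raise ValueError("panel and matrix share no positions; scan would be undefined")
    return matrix.take_sites(keep)


def read_snp_panel(path) -> list[tuple[str, int]]:
    """Read (chromosome, position) keys from a .snp file or two-column text."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) >= 6:  # EIGENSTRAT .snp
                out.append((parts[1], int(parts[3])))
            else:
                out.append((parts[0], int(parts[1])))
    return out


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

def read_recombination_map(path) -> RecombinationMap:
    """Read a whitespace-delimited ``chromosome position rate`` map."""
    positions: dict[str, list[int]] = {}
    rates: dict[str, list[float]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].lower() in ("chr", "chrom", "chromosome"):
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: expected 3 columns")
            chrom, pos, rate = parts[0], int(parts[1]), float(parts[2])
            if rate < 0:
                raise FormatError(f"{path}:{line_no}: negative rate {rate}")
            positions.setdefault(chrom, []).append(pos)
            rates.setdefault(chrom, []).append(rate)
    return RecombinationMap(
        positions={c: np.array(p, dtype=np.int64) for c, p in positions.items()},
        rates={c: np.array(r, dtype=float) for c, r in rates.items()},
    )


# ---------------------------------------------------------------------------
# Scan output
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "chromosome",
    "focal_pos",
    "window_start",
    "window_end",
    "g12",
    "miss_frac",
    "recomb_rate",
    "mask_recomb",
    "mask_missing",
    "mask_cross_pop",
]


def write_scan_outputs(track, peaks, out_prefix) -> dict[str, Path]:
    """Write per-window scores (TSV), peaks (BED + summary TSV).

    ``track`` is a :class:`~g12scan.mlg_g12.ScanTrack`; ``peaks`` a list of
    :class:`~g12scan.scan_calibrate.Peak`.  BED records are 0-based
    half-open; all other tables keep 1-based inclusive coordinates.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    scores_path = Path(str(out_prefix) + ".scores.tsv")
    bed_path = Path(str(out_prefix) + ".peaks.bed")
    summary_path = Path(str(out_prefix) + ".peaks.tsv")

    frame = track.frame.copy()
    frame["g12"] = frame["g12"].map(lambda v: f"{v:.6f}")
    frame.to_csv(scores_path, sep="\t", index=False, columns=SCORE_COLUMNS)

    with open(bed_path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chromosome}\t{p.start_pos - 1}\t{p.end_pos}\n")
    with open(summary_path, "w") as fh:
        fh.write("chromosome\tstart_pos\tend_pos\trepresentative_g12\tn_windows\n")
        for p in peaks:
            fh.write(
                f"{p.chromosome}\t{p.start_pos}\t{p.end_pos}"
                f"\t{p.representative_g12:.6f}\t{p.n_windows}\n"
            )
    return {"scores": scores_path, "bed": bed_path, "summary": summary_path}


def read_scan_scores(path) -> pd.DataFrame:
    """Round-trip reader for the score table written above."""
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
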