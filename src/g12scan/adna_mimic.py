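"""Transforms that make diploid genotype matrices look like aDNA.

Low-coverage ancient DNA differs from modern diploid calls in four ways
that matter for a multi-locus scan, each emulated here:

* **ascertainment** to a fixed capture panel (delegated to
  :func:`g12scan.geno_io.ascertain_to_panel`);
* **deamination damage**: post-mortem C->T substitutions, applied at a
  fixed stride along each individual's called positions;
* **missingness**: per-SNP missing-data fractions drawn from a beta
  distribution fitted by the method of moments (default mean 0.55,
  sd 0.23);
* **pseudo-haploidization**: one allele per site chosen at random, so each
  individual contributes a single allele call per position.

The canonical order of the full mimic pipeline is
ascertain -> damage -> missingness -> pseudo-haploidize, each stage seeded
from a named substream of one master seed so the whole pipeline is
reproducible bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geno_io import DIPLOID_MLG, MISSING, PSEUDO_HAPLOID, AlleleCallMatrix, ascertain_to_panel

logger = logging.getLogger(__name__)

_SHAPE_CAP = 1e9  # cap on beta shapes as sd -> 0


@dataclass(frozen=True)
class MissingnessModel:
    """Beta model of per-SNP missing-data fractions.

    ``alpha``/``beta`` are derived from (mean, sd) by the method of
    moments: alpha + beta = mean(1-mean)/sd^2 - 1, alpha = mean(alpha+beta).
    A model with ``mean == 0`` is the degenerate no-missingness model.
    """

    mean: float
    sd: float
    alpha: float
    beta: float


def fit_missingness_model(mean: float = 0.55, sd: float = 0.23) -> MissingnessModel:
    """Fit the beta missingness model by the method of moments."""
    if mean == 0.0:
        return MissingnessModel(mean=0.0, sd=0.0, alpha=0.0, beta=0.0)
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean missingness must be in (0,1), got {mean}")
    var = sd**2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: variance {var:.4g} >= mean(1-mean) = {mean * (1 - mean):.4g}"
        )
    if var == 0.0:
        logger.warning("sd=0 requested; capping beta shapes at %.0e", _SHAPE_CAP)
        total = _SHAPE_CAP
    else:
        total = mean * (1.0 - mean) / var - 1.0
        if total > _SHAPE_CAP:
            logger.warning("tiny sd; capping beta shapes at %.0e", _SHAPE_CAP)
            total = _SHAPE_CAP
    return MissingnessModel(mean=mean, sd=sd, alpha=mean * total, beta=(1.0 - mean) * total)


def draw_missing_fractions(model: MissingnessModel, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-SNP missing fractions, truncated away from 0 and 1."""
    if model.mean == 0.0:
        return np.zeros(n_snps)
    p = rng.beta(model.alpha, model.beta, size=n_snps)
    return np.clip(p, 1e-6, 1.0 - 1e-6)


def inject_missingness(
    matrix: AlleleCallMatrix, model: MissingnessModel, rng: np.random.Generator
) -> tuple[AlleleCallMatrix, np.ndarray]:
    """Set calls to MISSING at beta-distributed per-SNP rates.

    For SNP ``j`` a fraction ``p_j ~ Beta(alpha, beta)`` is drawn and each
    individual's call at ``j`` is independently set to MISSING with
    probability ``p_j``.  Already-missing calls stay missing.  Returns the
    new matrix together with the drawn per-SNP fractions (for the
    autocorrelation diagnostic).
    """
    p = draw_missing_fractions(model, matrix.n_sites, rng)
    if model.mean == 0.0:
        return matrix, p
    hit = rng.random(matrix.calls.shape) < p[None, :]
    calls = np.where(hit, MISSING, matrix.calls).astype(np.int8)
    out = AlleleCallMatrix(
        calls=calls, ploidy_mode=matrix.ploidy_mode, snps=matrix.snps, samples=matrix.samples
    )
    return out, p


def pseudo_haploidize(matrix: AlleleCallMatrix, rng: np.random.Generator) -> AlleleCallMatrix:
    """Randomly sample one allele per diploid call.

    Homozygous calls map deterministically (0 -> 0, 2 -> 1); heterozygous
    calls become a fair Bernoulli choice of either allele; MISSING is
    preserved.  Double haploidization is refused.
    """
    if matrix.ploidy_mode == PSEUDO_HAPLOID:
        raise ValueError("matrix is already pseudo-haploid")
    calls = matrix.calls
    coin = rng.integers(0, 2, size=calls.shape, dtype=np.int8)
    out = np.where(
        calls == MISSING,
        MISSING,
        np.where(calls == 1, coin, (calls // 2)),
    ).astype(np.int8)
    return AlleleCallMatrix(
        calls=out, ploidy_mode=PSEUDO_HAPLOID, snps=matrix.snps, samples=matrix.samples
    )


@dataclass(frozen=True)
class DamageScheme:
    """Deamination mimic: C->T at every ``stride``-th called position."""

    stride: int = 100
    substitution: tuple[str, str] = ("C", "T")

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def apply_damage(
    matrix: AlleleCallMatrix,
    scheme: DamageScheme | None = None,
) -> tuple[AlleleCallMatrix, np.ndarray]:
    """Flip C-called alleles to T at a fixed stride along each individual.

    For each individual, that individual's non-missing called positions are
    walked in genomic order; at every ``stride``-th of them (ranks 100,
    200, ... for the default), if the called genotype carries the damaged
    nucleotide (C) and the other allele at that SNP is the substitution
    product (T), the call is flipped to the T allele.  SNPs whose allele
    pair is not C/T are left unchanged, as is anything past the last full
    stride.  Returns the damaged matrix and the per-individual flip counts.

    Calls are resolved to nucleotides through the SNP records' allele
    letters under the convention that a call counts copies of
    ``allele_ref`` (the EIGENSTRAT dialect used throughout this package).
    """
    scheme = scheme or DamageScheme()
    if not matrix.snps:
        raise ValueError("damage requires SNP records with allele letters")
    dmg_from, dmg_to = scheme.substitution
    ref = np.array([s.allele_ref for s in matrix.snps])
    alt = np.array([s.allele_alt for s in matrix.snps])
    ref_is_c = (ref == dmg_from) & (alt == dmg_to)
    alt_is_c = (alt == dmg_from) & (ref == dmg_to)

    calls = matrix.calls.copy()
    max_call = 2 if matrix.ploidy_mode == DIPLOID_MLG else 1
    flips = np.zeros(matrix.n_individuals, dtype=np.int64)
    for i in range(matrix.n_individuals):
        called = np.flatnonzero(calls[i] != MISSING)
        inspect = called[scheme.stride - 1 :: scheme.stride]
        for j in inspect:
            v = calls[i, j]
            if ref_is_c[j] and v > 0:
                # carries >= 1 copy of C (= ref); all C copies become T (= alt)
                calls[i, j] = 0
                flips[i] += 1
            elif alt_is_c[j] and v < max_call:
                calls[i, j] = max_call
                flips[i] += 1
    out = AlleleCallMatrix(
        calls=calls, ploidy_mode=matrix.ploidy_mode, snps=matrix.snps, samples=matrix.samples
    )
    return out, flips


def missingness_autocorrelation(per_snp_fractions: np.ndarray, max_lag: int = 10) -> np.ndarray:
    """Sample autocorrelation of per-SNP missing fractions at lags 1..max_lag.

    A constant series has undefined autocorrelation; NaNs are returned for
    every lag in that case.
    """
    x = np.asarray(per_snp_fractions, dtype=float)
    if x.size < max_lag + 2:
        raise ValueError(f"need at least {max_lag + 2} SNPs for {max_lag} lags")
    if np.allclose(x, x[0]):
        return np.full(max_lag, np.nan)
    from statsmodels.tsa.stattools import acf

    return acf(x, nlags=max_lag, fft=True)[1:]


def mimic_adna(
    matrix: AlleleCallMatrix,
    seed: int,
    panel_positions=None,
    damage_scheme: DamageScheme | None = None,
    missingness: MissingnessModel | None = None,
) -> AlleleCallMatrix:
    """Run the full mimic pipeline: ascertain -> damage -> missingness -> pseudo-haploidize.

    Each random stage draws from a named substream of ``seed`` so the
    output is reproducible bit-exactly regardless of which stages are
    enabled.
    """
    ss = np.random.SeedSequence(seed)
    miss_rng, hap_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    out = matrix
    if panel_positions is not None:
        out = ascertain_to_panel(out, panel_positions)
    if damage_scheme is not None:
        out, _ = apply_damage(out, damage_scheme)
    if missingness is None:
        missingness = fit_missingness_model()
    out, _ = inject_missingness(out, missingness, miss_rng)
    if out.ploidy_mode == DIPLOID_MLG:
        out = pseudo_haploidize(out, hap_rng)
    return out
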