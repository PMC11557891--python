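import numpy as np
import pytest

from g12scan.geno_io import DIPLOID_MLG, AlleleCallMatrix, SampleRecord, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(calls, ploidy_mode=DIPLOID_MLG, chromosome="1", alleles=None, positions=None):
    """Small AlleleCallMatrix with synthetic SNP/sample records."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snp = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_snp)]
    if alleles is None:
        alleles = [("A", "G")] * n_snp
    snps = [
        SnpRecord(
            snp_id=f"rs{j}",
            chromosome=chromosome,
            genetic_pos=positions[j] * 1e-8,
            physical_pos=positions[j],
            allele_ref=alleles[j][0],
            allele_alt=alleles[j][1],
        )
        for j in range(n_snp)
    ]
    samples = [SampleRecord(sample_id=f"s{i}", group_label="T") for i in range(n_ind)]
    return AlleleCallMatrix(calls=calls, ploidy_mode=ploidy_mode, snps=snps, samples=samples)


@pytest.fixture
def small_diploid_matrix():
    return make_matrix([[0, 1, 2, 1], [2, 2, 0, -1], [1, 0, 1, 2]])
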