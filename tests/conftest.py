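import numpy as np
import pytest

from cisqtl import SimConfig, simulate_covariates, simulate_genotypes, simulate_phenotypes, write_fixture

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1
1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\t1/1
1\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def sim_small(tmp_path):
    """Small fixture with one planted eQTL, written to disk."""
    cfg = SimConfig(
        n_samples=120, n_variants=30, n_phenotypes=8,
        effects={0: (12, 1.2)}, noise_sd=1.0, seed=11,
    )
    g = simulate_genotypes(cfg)
    p = simulate_phenotypes(g, cfg)
    paths = write_fixture(g, p, None, tmp_path / "fix")
    return cfg, g, p, paths


def make_standardized(rng, L, N, rho=0.0):
    """Raw dosage-like matrix from the AR(1) generator for scheme tests."""
    cfg = SimConfig(n_samples=N, n_variants=L, ld_rho=rho,
                    seed=int(rng.integers(2**31)))
    return simulate_genotypes(cfg).dosages
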