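import numpy as np
import pandas as pd
import pytest

from synpop import (
    FounderPoolSpec,
    GenotypeMatrix,
    NoiseSpec,
    generate_founder_pool,
    generate_phenotypes,
    sample_qtl_effects,
)


@pytest.fixture(scope="session")
def small_pool():
    """Site-independent founder pool: 60 individuals, 4 chromosomes x 50 SNPs."""
    spec = FounderPoolSpec(
        n_individuals=60, n_chromosomes=4, n_snp_per_chromosome=50, seed=2
    )
    return generate_founder_pool(spec)


@pytest.fixture(scope="session")
def ld_pool():
    """Founder pool with planted block LD (ancestral-haplotype mosaics)."""
    spec = FounderPoolSpec(
        n_individuals=120,
        n_chromosomes=6,
        n_snp_per_chromosome=48,
        ld_ancestral_haplotypes=8,
        ld_block_snps=8,
        seed=5,
    )
    return generate_founder_pool(spec)


@pytest.fixture(scope="session")
def cycle1_like():
    """Prediction-scale training population: 400 individuals, ~1,000 markers,
    block LD calibrated to a realistic GBS r2 level, h2 = 0.6 trait with two
    evaluation years."""
    spec = FounderPoolSpec(
        n_individuals=400,
        n_chromosomes=21,
        n_snp_per_chromosome=48,
        ld_ancestral_haplotypes=8,
        ld_block_snps=8,
        seed=7,
    )
    pool = generate_founder_pool(spec)
    trait = sample_qtl_effects(pool, n_qtl=200, target_h2=0.6, rng=11)
    noise = NoiseSpec(per_snp_missing_rate=0.0, year_effects=(0.0, 0.5))
    pheno = generate_phenotypes(pool, trait, noise, years=2, seed=13)
    return pool, trait, pheno


def toy_matrix(dosage, chrom=None, pos=None, prefix="I"):
    """GenotypeMatrix around a plain dosage array with minimal metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chrom = ["1"] * m if chrom is None else list(chrom)
    pos = np.arange(1, m + 1) if pos is None else np.asarray(pos)
    return GenotypeMatrix(
        individual_ids=[f"{prefix}{i + 1}" for i in range(n)],
        snp_ids=[f"S{j + 1}" for j in range(m)],
        chrom=np.array(chrom, dtype=object),
        pos_bp=pos,
        dosage=dosage,
    )
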