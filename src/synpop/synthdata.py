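"""Synthetic founder pools, GBS-style degraded genotype matrices, and
multi-year phenotypes.

The generators emulate the statistical structure of a GBS-genotyped breeding
population of an outcrossing grass: ~21 chromosomes, a genome-wide mean minor
allele frequency around 0.22, per-SNP missingness that occasionally exceeds
downstream filter thresholds, a handful of low-call-rate individuals, and
phenotypes with additive genetic values, fixed year effects, and Gaussian
residual noise at a configurable heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .population import HaplotypePopulation, make_locus_map

__all__ = [
    "FounderPoolSpec",
    "NoiseSpec",
    "generate_founder_pool",
    "degrade_to_gbs",
    "generate_phenotypes",
]


@dataclass
class FounderPoolSpec:
    """Configuration of the synthetic founder (base) population.

    The minor-allele-frequency sampler is a Beta distribution rescaled to
    (0, 0.5]: with ``u = maf_mean / 0.5`` the shape parameters are
    ``a = u * maf_concentration`` and ``b = (1 - u) * maf_concentration``, so
    the expected MAF equals ``maf_mean`` for any concentration.

    When ``ld_ancestral_haplotypes`` is set, each founder haplotype is a
    block-mosaic of that many ancestral haplotypes per chromosome (blocks of
    ``ld_block_snps`` consecutive SNPs), which plants linkage disequilibrium;
    by default sites are drawn independently (no ancestral LD).
    """

    n_individuals: int = 80
    n_chromosomes: int = 21
    n_snp_per_chromosome: int = 649
    maf_mean: float = 0.22
    maf_concentration: float = 3.0
    chrom_length_cm: float = 150.0
    chrom_length_bp: int = 100_000_000
    ld_ancestral_haplotypes: int | None = None
    ld_block_snps: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_chromosomes", "n_snp_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.maf_mean <= 0.5:
            raise ValueError("maf_mean must be in (0, 0.5]")
        if self.maf_concentration <= 0:
            raise ValueError("maf_concentration must be positive")
        if self.chrom_length_cm < 0 or self.chrom_length_bp < 1:
            raise ValueError("chromosome lengths must be non-negative / positive")
        if self.ld_ancestral_haplotypes is not None and self.ld_ancestral_haplotypes < 2:
            raise ValueError("ld_ancestral_haplotypes must be >= 2")
        if self.ld_block_snps < 1:
            raise ValueError("ld_block_snps must be >= 1")


def _sample_mafs(spec: FounderPoolSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    u = spec.maf_mean / 0.5
    if u >= 1.0:  # degenerate sampler: every locus at MAF 0.5
        return np.full(size, 0.5)
    a = u * spec.maf_concentration
    b = (1.0 - u) * spec.maf_concentration
    maf = 0.5 * rng.beta(a, b, size=size)
    # keep frequencies strictly inside (0, 0.5]
    return np.clip(maf, 1e-6, 0.5)


def generate_founder_pool(spec: FounderPoolSpec) -> HaplotypePopulation:
    """Generate a phased diploid founder pool in Hardy-Weinberg proportions.

    Per locus an allele frequency is drawn from the MAF sampler and each of
    the ``2 n`` haplotype alleles is an independent Bernoulli draw at that
    frequency (HWE by construction).  With ``ld_ancestral_haplotypes`` set,
    haplotypes instead copy blocks from a per-chromosome ancestral pool,
    creating realistic LD while preserving the expected frequency spectrum.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    loci = make_locus_map(
        spec.n_chromosomes,
        spec.n_snp_per_chromosome,
        spec.chrom_length_cm,
        spec.chrom_length_bp,
        rng=rng,
    )
    n_loci = len(loci)
    freqs = _sample_mafs(spec, rng, n_loci)
    n = spec.n_individuals
    if spec.ld_ancestral_haplotypes is None:
        haps = (rng.random((n, 2, n_loci)) < freqs).astype(np.int8)
    else:
        A = spec.ld_ancestral_haplotypes
        haps = np.empty((n, 2, n_loci), dtype=np.int8)
        start = 0
        for _ in range(spec.n_chromosomes):
            m = spec.n_snp_per_chromosome
            sl = slice(start, start + m)
            anc = (rng.random((A, m)) < freqs[sl]).astype(np.int8)
            n_blocks = -(-m // spec.ld_block_snps)
            block_of_snp = np.arange(m) // spec.ld_block_snps
            choice = rng.integers(0, A, size=(n * 2, n_blocks))
            haps[:, :, sl] = anc[choice[:, block_of_snp], np.arange(m)].reshape(n, 2, m)
            start += m
    return HaplotypePopulation(
        haplotypes=haps,
        loci=loci,
        generation="Founder",
        individual_ids=[f"F{i + 1:04d}" for i in range(n)],
    )


@dataclass
class NoiseSpec:
    """GBS missingness and phenotype-noise configuration.

    ``per_snp_missing_rate`` is the mean per-SNP missing fraction; individual
    SNP rates are drawn from a Beta distribution with that mean and
    concentration ``rate_heterogeneity`` (set to ``None`` for a uniform rate),
    so a fraction of SNPs exceeds a 10% missingness filter threshold.  A
    fraction ``low_call_fraction`` of individuals receives extra missingness
    that pushes their call rate below ``per_individual_call_rate_floor``.
    """

    per_snp_missing_rate: float = 0.05
    rate_heterogeneity: float | None = 2.0
    per_individual_call_rate_floor: float = 0.80
    low_call_fraction: float = 0.0
    year_effects: tuple[float, ...] = (0.0, 0.0)
    error_variance_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_snp_missing_rate < 1.0:
            raise ValueError("per_snp_missing_rate must be in [0, 1)")
        if not 0.0 <= self.per_individual_call_rate_floor <= 1.0:
            raise ValueError("per_individual_call_rate_floor must be in [0, 1]")
        if not 0.0 <= self.low_call_fraction < 1.0:
            raise ValueError("low_call_fraction must be in [0, 1)")
        if self.error_variance_scale <= 0:
            raise ValueError("error_variance_scale must be positive")


def degrade_to_gbs(
    geno: GenotypeMatrix, noise: NoiseSpec, seed: int = 0
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Introduce GBS-like missingness into a complete dosage matrix.

    Returns the degraded (unphased dosage) matrix and the boolean mask of
    masked cells, so imputation accuracy can be scored against the truth.
    """
    if np.isnan(geno.dosage).any():
        raise ValueError("input matrix must be complete (no missing calls)")
    rng = np.random.default_rng(seed)
    out = geno.copy()
    n, m = out.dosage.shape
    rate = noise.per_snp_missing_rate
    if rate == 0 and noise.low_call_fraction == 0:
        return out, np.zeros((n, m), dtype=bool)
    if rate > 0:
        if noise.rate_heterogeneity is None:
            snp_rates = np.full(m, rate)
        else:
            c = noise.rate_heterogeneity
            snp_rates = rng.beta(rate * c, (1 - rate) * c, size=m)
        mask = rng.random((n, m)) < snp_rates
    else:
        mask = np.zeros((n, m), dtype=bool)
    n_low = int(np.floor(noise.low_call_fraction * n))
    if n_low > 0:
        low_ind = rng.choice(n, size=n_low, replace=False)
        # push expected call rate ~0.1 below the filter floor
        target_missing = min(0.95, 1.0 - noise.per_individual_call_rate_floor + 0.10)
        mask[low_ind] |= rng.random((n_low, m)) < target_missing
    out.dosage[mask] = np.nan
    return out, mask


def generate_phenotypes(
    pop: HaplotypePopulation,
    trait,
    noise: NoiseSpec,
    years: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one phenotype record per individual x year.

    ``value = genetic value + year effect + Normal(0, varE * scale)`` where the
    genetic value (including the trait intercept) comes from
    ``trait.genetic_values`` and ``varE`` is the trait's residual variance.
    The returned frame has columns ``genotype_id, year, trait, value,
    genetic_value``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if len(noise.year_effects) < years:
        raise ValueError(
            f"NoiseSpec.year_effects has {len(noise.year_effects)} entries; "
            f"{years} needed"
        )
    rng = np.random.default_rng(seed)
    gv = trait.genetic_values(pop)
    var_e = trait.var_e * noise.error_variance_scale
    frames = []
    for y in range(years):
        eps = rng.normal(0.0, np.sqrt(var_e), size=pop.n_individuals) if var_e > 0 else 0.0
        frames.append(
            pd.DataFrame(
                {
                    "genotype_id": pop.individual_ids,
                    "year": y + 1,
                    "trait": trait.name,
                    "value": gv + noise.year_effects[y] + eps,
                    "genetic_value": gv,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
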