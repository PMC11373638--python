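"""Phased diploid population container used by the forward simulator and the
synthetic-data generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = ["HaplotypePopulation", "make_locus_map"]


def make_locus_map(
    n_chromosomes: int,
    n_snp_per_chromosome: int,
    chrom_length_cm: float = 150.0,
    chrom_length_bp: int = 100_000_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build a locus map with strictly increasing physical positions per
    chromosome and genetic positions proportional to physical ones.

    Positions are drawn uniformly when ``rng`` is given, otherwise spaced
    evenly.  Columns: ``snp_id, chrom, pos_bp, pos_cm``.
    """
    frames = []
    for c in range(1, n_chromosomes + 1):
        m = n_snp_per_chromosome
        if rng is None:
            bp = np.linspace(1, chrom_length_bp, m).astype(np.int64)
        else:
            raw = np.sort(rng.random(m))
            # strictly increasing integers in [1, chrom_length_bp]
            bp = (raw * (chrom_length_bp - m)).astype(np.int64) + np.arange(m) + 1
        cm = bp / chrom_length_bp * chrom_length_cm
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"S{c}_{j + 1}" for j in range(m)],
                    "chrom": str(c),
                    "pos_bp": bp,
                    "pos_cm": cm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class HaplotypePopulation:
    """Phased diploid individuals over mapped biallelic loci.

    Attributes
    ----------
    haplotypes
        ``(n_individuals, 2, n_loci)`` int8 array of alleles in {0, 1}.
    loci
        Locus map with columns ``snp_id, chrom, pos_bp, pos_cm``; positions
        sorted within chromosome.
    generation
        Free-form label, e.g. ``"Founder"`` or ``"SYN2"``.
    """

    haplotypes: np.ndarray
    loci: pd.DataFrame
    generation: str = "Founder"
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if len(self.loci) != self.haplotypes.shape[2]:
            raise ValueError("locus map length does not match haplotypes")
        if not self.individual_ids:
            self.individual_ids = [
                f"{self.generation}_{i + 1:05d}" for i in range(self.n_individuals)
            ]
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual_ids length mismatch")
        for _, grp in self.loci.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_bp"].to_numpy()) < 0):
                raise ValueError("map positions not sorted within chromosome")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosage(self) -> np.ndarray:
        """Unphased alternate-allele dosage matrix (n_individuals x n_loci)."""
        return self.haplotypes.sum(axis=1).astype(float)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def segregating(self) -> np.ndarray:
        """Boolean mask of loci with 0 < allele frequency < 1."""
        f = self.allele_frequencies()
        return (f > 0) & (f < 1)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice per chromosome (map is chromosome-blocked)."""
        out: dict[str, slice] = {}
        chroms = self.loci["chrom"].to_numpy()
        start = 0
        for c in pd.unique(chroms):
            n = int((chroms == c).sum())
            out[str(c)] = slice(start, start + n)
            start += n
        return out

    def subset(self, indices) -> "HaplotypePopulation":
        indices = np.asarray(indices)
        return HaplotypePopulation(
            haplotypes=self.haplotypes[indices].copy(),
            loci=self.loci,
            generation=self.generation,
            individual_ids=[self.individual_ids[i] for i in indices],
        )

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            snp_ids=self.loci["snp_id"].tolist(),
            chrom=self.loci["chrom"].to_numpy(dtype=object),
            pos_bp=self.loci["pos_bp"].to_numpy(),
            dosage=self.dosage(),
            pos_cm=self.loci["pos_cm"].to_numpy(),
        )
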