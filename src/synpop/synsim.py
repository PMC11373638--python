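"""Forward-in-time simulation of synthetic (SYN) generation advancement.

A SYN cultivar starts from a small set of parents intermated in an isolated
crossing block; the harvest is SYN1, and each later generation (SYN2, SYN3,
...) is produced by open pollination of the previous one without selection.
This module simulates that process for an additive polygenic trait:

* a trait architecture of ``n_qtl`` causative loci with normal effects,
  rescaled so the founder pool has a chosen additive variance ``v0`` and a
  chosen mean genetic value;
* meiosis with Poisson crossovers on the genetic map (no interference,
  i.e. Haldane's model);
* random mating without selfing, ``n_crosses`` crosses x ``progeny_per_cross``
  progeny per generation;
* per-generation estimates of additive variance, phenotypic variance, and
  realized heritability.

Because the trait is purely additive, the additive variance equals the total
genetic variance; the residual variance is fixed once at founder calibration,
``varE = v0 (1 - H2) / H2``, so realized heritability drifts as the genetic
variance drifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .population import HaplotypePopulation
from .stats import TukeyResult, tukey_hsd  # noqa: F401  (re-exported)

__all__ = [
    "TraitArchitecture",
    "SimulationDesign",
    "VarianceTable",
    "VarianceEstimate",
    "sample_qtl_effects",
    "meiosis",
    "batch_meiosis",
    "advance_generation",
    "estimate_variances",
    "hwe_additive_variance",
    "run_synthetic_experiment",
    "tukey_hsd",
]


@dataclass
class TraitArchitecture:
    """Additive QTL trait: effects, intercept, and variance parameters.

    ``var_e`` is tied to the base additive variance by
    ``var_e = v0 (1 - target_h2) / target_h2`` so that a founder-pool
    individual has heritability ``target_h2``.
    """

    qtl_indices: np.ndarray
    effects: np.ndarray
    intercept: float
    target_mean: float = 1.0
    target_h2: float = 0.6
    v0: float = 0.3
    var_e: float = 0.2
    name: str = "trait"

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.qtl_indices.shape != self.effects.shape:
            raise ValueError("qtl_indices and effects must have the same length")
        if not 0.0 < self.target_h2 <= 1.0:
            raise ValueError("target_h2 must be in (0, 1]")
        if self.var_e < 0:
            raise ValueError("var_e must be non-negative")

    def with_h2(self, h2: float) -> "TraitArchitecture":
        """Same architecture with the residual variance recalibrated for a
        different target heritability."""
        return TraitArchitecture(
            qtl_indices=self.qtl_indices,
            effects=self.effects,
            intercept=self.intercept,
            target_mean=self.target_mean,
            target_h2=h2,
            v0=self.v0,
            var_e=self.v0 * (1.0 - h2) / h2,
            name=self.name,
        )

    def genetic_values(self, pop) -> np.ndarray:
        """True genetic value per individual: intercept + sum of QTL dosages
        times effects.  Accepts a HaplotypePopulation or a dosage array."""
        dos = pop.dosage() if hasattr(pop, "dosage") else np.asarray(pop, dtype=float)
        return self.intercept + dos[:, self.qtl_indices] @ self.effects


def sample_qtl_effects(
    founder_pool: HaplotypePopulation,
    n_qtl: int = 1000,
    target_mean: float = 1.0,
    v0: float = 0.3,
    target_h2: float = 0.6,
    rng: np.random.Generator | int | None = None,
) -> TraitArchitecture:
    """Sample a polygenic architecture calibrated on the founder pool.

    QTL positions are drawn uniformly (without replacement) from segregating
    loci; raw effects are standard normal and rescaled so the sample variance
    of genetic values over the full founder pool equals ``v0`` exactly; the
    intercept shifts the founder-pool mean genetic value to ``target_mean``.
    """
    rng = np.random.default_rng(rng)
    seg = np.flatnonzero(founder_pool.segregating())
    if seg.size < n_qtl:
        raise ValueError(
            f"founder pool segregates at {seg.size} loci; {n_qtl} QTL requested"
        )
    qtl = np.sort(rng.choice(seg, size=n_qtl, replace=False))
    raw = rng.standard_normal(n_qtl)
    dos = founder_pool.dosage()[:, qtl]
    g = dos @ raw
    v = g.var(ddof=1)
    if v == 0:
        raise ValueError("genetic values have zero variance in the founder pool")
    effects = raw * np.sqrt(v0 / v)
    intercept = target_mean - float((dos @ effects).mean())
    return TraitArchitecture(
        qtl_indices=qtl,
        effects=effects,
        intercept=intercept,
        target_mean=target_mean,
        target_h2=target_h2,
        v0=v0,
        var_e=v0 * (1.0 - target_h2) / target_h2,
    )


# ---------------------------------------------------------------------------
# Meiosis and generation advancement
# ---------------------------------------------------------------------------


def batch_meiosis(
    genomes: np.ndarray, loci: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Produce one gamete per diploid genome in a batch.

    ``genomes`` has shape ``(M, 2, n_loci)``.  Per chromosome the crossover
    count is Poisson with mean ``map length / 100`` (length taken as the cM
    position of the last locus; crossovers beyond it cannot affect the
    gamete), crossover positions are uniform on the map (no interference),
    and the starting haplotype is a fair coin.  Returns ``(M, n_loci)``.
    """
    genomes = np.asarray(genomes)
    M = genomes.shape[0]
    gametes = np.empty((M, genomes.shape[2]), dtype=np.int8)
    chroms = loci["chrom"].to_numpy()
    pos_cm = loci["pos_cm"].to_numpy(dtype=float)
    start_col = 0
    for c in pd.unique(chroms):
        m = int((chroms == c).sum())
        sl = slice(start_col, start_col + m)
        start_col += m
        pos = pos_cm[sl]
        pos = pos - pos[0]  # map length relative to the first locus
        length_cm = pos[-1]
        start = rng.integers(0, 2, size=M).astype(np.int16)
        if length_cm <= 0:
            parity = np.broadcast_to(start[:, None], (M, m))
        else:
            counts = rng.poisson(length_cm / 100.0, size=M)
            cmax = int(counts.max())
            parity = np.zeros((M, m), dtype=np.int16)
            if cmax > 0:
                xo = rng.uniform(0.0, length_cm, size=(M, cmax))
                xo[np.arange(cmax)[None, :] >= counts[:, None]] = np.inf
                for j in range(cmax):
                    parity += xo[:, j, None] <= pos[None, :]
            parity = (parity + start[:, None]) % 2
        sub = genomes[:, :, sl]
        gametes[:, sl] = np.where(parity == 0, sub[:, 0, :], sub[:, 1, :])
    return gametes


def meiosis(
    genome: np.ndarray, loci: pd.DataFrame, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Single meiosis: one gamete from one diploid genome (2 x n_loci)."""
    rng = np.random.default_rng(rng)
    return batch_meiosis(np.asarray(genome)[None, :, :], loci, rng)[0]


def advance_generation(
    pop: HaplotypePopulation,
    n_crosses: int,
    progeny_per_cross: int,
    rng: np.random.Generator | int | None = None,
    generation: str | None = None,
) -> HaplotypePopulation:
    """One round of panmictic random mating without selection or selfing.

    Each cross pairs two distinct parents drawn uniformly with replacement
    across crosses; each progeny is the union of two independent meioses.
    The next generation has exactly ``n_crosses * progeny_per_cross``
    individuals.
    """
    if pop.n_individuals < 2:
        raise ValueError("need at least 2 parents (selfing is excluded)")
    rng = np.random.default_rng(rng)
    n = pop.n_individuals
    mothers = rng.integers(0, n, size=n_crosses)
    fathers = rng.integers(0, n - 1, size=n_crosses)
    fathers[fathers >= mothers] += 1  # distinct from the mother
    mom_per_prog = np.repeat(mothers, progeny_per_cross)
    dad_per_prog = np.repeat(fathers, progeny_per_cross)
    gam_m = batch_meiosis(pop.haplotypes[mom_per_prog], pop.loci, rng)
    gam_f = batch_meiosis(pop.haplotypes[dad_per_prog], pop.loci, rng)
    return HaplotypePopulation(
        haplotypes=np.stack([gam_m, gam_f], axis=1),
        loci=pop.loci,
        generation=generation or "SYN",
    )


def hwe_additive_variance(pop: HaplotypePopulation, trait: TraitArchitecture) -> float:
    """Additive variance of a hypothetical Hardy-Weinberg population at the
    population's current QTL allele frequencies: ``2 sum_q a_q^2 p_q (1-p_q)``.

    This gene-diversity form obeys the classical neutral-drift law
    ``E[v(t+1)] = v(t) (1 - 1/(2N))`` exactly under random mating from N
    parents.  The realized genotypic variance differs from it transiently:
    excluding selfing creates excess heterozygosity (negative F), and the
    one-generation expectation of the genotypic variance is
    ``v(t) (1 - 1/N)`` instead; the deviation dissipates the following
    generation.
    """
    p = pop.allele_frequencies()[trait.qtl_indices]
    return float(2.0 * np.sum(trait.effects**2 * p * (1.0 - p)))


class VarianceEstimate(NamedTuple):
    sigma2_a: float
    sigma2_p: float
    h2_realized: float


def estimate_variances(
    pop: HaplotypePopulation,
    trait: TraitArchitecture,
    rng: np.random.Generator | int | None = None,
) -> VarianceEstimate:
    """Additive and phenotypic variance and realized heritability.

    The additive variance is the sample variance of true genetic values
    (equal to the total genetic variance for this purely additive trait);
    phenotypes add independent Normal(0, varE) noise.
    """
    if pop.n_individuals < 2:
        raise ValueError("need at least 2 individuals to estimate variances")
    rng = np.random.default_rng(rng)
    gv = trait.genetic_values(pop)
    s2a = float(gv.var(ddof=1))
    phe = gv + rng.normal(0.0, np.sqrt(trait.var_e), size=gv.size)
    s2p = float(phe.var(ddof=1))
    return VarianceEstimate(s2a, s2p, s2a / s2p)


# ---------------------------------------------------------------------------
# The factorial experiment
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Factorial design: parent counts x heritability levels x iterations.

    Defaults follow the full-scale experiment (1,000 crosses x 100 progeny,
    100 iterations); :meth:`desk` gives the scaled-down configuration used
    for testing (100 x 20, 25 iterations).
    """

    parent_counts: tuple[int, ...] = (7, 10, 15, 20, 25)
    n_crosses: int = 1000
    progeny_per_cross: int = 100
    n_generations: int = 4
    iterations: int = 100
    h2_levels: tuple[float, ...] = (0.4, 0.6, 0.8)
    n_qtl: int = 1000
    trait_mean: float = 1.0
    v0: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_crosses, self.progeny_per_cross, self.n_generations,
                  self.iterations, self.n_qtl, *self.parent_counts)
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be positive")
        if any(not 0 < h <= 1 for h in self.h2_levels):
            raise ValueError("heritability levels must be in (0, 1]")

    @classmethod
    def desk(cls, **overrides) -> "SimulationDesign":
        defaults = dict(n_crosses=100, progeny_per_cross=20, iterations=25)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class VarianceTable:
    """Per (parent count, generation, heritability, iteration) variance
    records; the machine twin of the published variance table."""

    records: pd.DataFrame

    COLUMNS = ("parent_count", "generation", "h2_input", "iteration",
               "sigma2_a", "sigma2_p", "h2_realized", "variance_anomaly")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD per (parent count, generation, heritability) cell."""
        g = self.records.groupby(["h2_input", "generation", "parent_count"])
        out = g[["sigma2_a", "sigma2_p", "h2_realized"]].agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()

    def mean_realized_h2(self, h2_input: float | None = None) -> float:
        """Mean realized heritability over cells, optionally restricted to
        one input heritability level (cell = parent count x generation)."""
        df = self.records
        if h2_input is not None:
            df = df[np.isclose(df["h2_input"], h2_input)]
        cells = df.groupby(["parent_count", "generation"])["h2_realized"].mean()
        return float(cells.mean())

    def tukey_by_parent_count(self, h2_input: float, alpha: float = 0.001,
                              value: str = "sigma2_a") -> TukeyResult:
        """Tukey HSD comparison of per-iteration values across parent counts,
        pooling generations, at one input heritability."""
        df = self.records[np.isclose(self.records["h2_input"], h2_input)]
        groups = {str(pc): sub[value].to_numpy()
                  for pc, sub in df.groupby("parent_count")}
        return tukey_hsd(groups, alpha=alpha)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_synthetic_experiment(
    design: SimulationDesign,
    founder_pool: HaplotypePopulation,
    progress: bool = False,
) -> VarianceTable:
    """Run the full factorial SYN-advancement experiment.

    Per iteration and parent count: draw that many parents (without
    replacement) from the founder pool, sample a fresh QTL architecture
    calibrated on the full pool, intermate the parents to produce SYN1, and
    advance to SYN4 by random mating without selection.  The same genome
    lineage is scored under every heritability level (only the residual
    variance differs).  Per-iteration seeds derive deterministically from
    ``design.seed``.
    """
    if founder_pool.n_individuals <= max(design.parent_counts):
        raise ValueError("founder pool must be larger than the largest parent count")
    est_progeny = design.n_crosses * design.progeny_per_cross
    if est_progeny * founder_pool.n_loci > 5e9:
        raise MemoryError(
            "requested population exceeds a workable in-memory size; "
            "reduce n_crosses/progeny_per_cross or the number of loci"
        )
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.iterations * len(design.parent_counts))
    rows = []
    idx = 0
    for it in range(design.iterations):
        for pc in design.parent_counts:
            rng = np.random.default_rng(children[idx])
            idx += 1
            parents = rng.choice(founder_pool.n_individuals, size=pc, replace=False)
            base_trait = sample_qtl_effects(
                founder_pool,
                n_qtl=design.n_qtl,
                target_mean=design.trait_mean,
                v0=design.v0,
                rng=rng,
            )
            traits = [base_trait.with_h2(h) for h in design.h2_levels]
            pop = founder_pool.subset(parents)
            for gen in range(1, design.n_generations + 1):
                pop = advance_generation(
                    pop, design.n_crosses, design.progeny_per_cross,
                    rng=rng, generation=f"SYN{gen}",
                )
                for trait in traits:
                    s2a, s2p, h2r = estimate_variances(pop, trait, rng=rng)
                    rows.append(
                        (pc, f"SYN{gen}", trait.target_h2, it, s2a, s2p, h2r,
                         s2p < s2a)
                    )
        if progress:  # pragma: no cover - cosmetic
            print(f"iteration {it + 1}/{design.iterations} done")
    df = pd.DataFrame(rows, columns=list(VarianceTable.COLUMNS))
    return VarianceTable(df)
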