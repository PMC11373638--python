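"""Forward-simulator tests: trait calibration, meiosis, generation
advancement, variance estimation, the factorial experiment, and Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from synpop import (
    SimulationDesign,
    TraitArchitecture,
    advance_generation,
    estimate_variances,
    hwe_additive_variance,
    meiosis,
    run_synthetic_experiment,
    sample_qtl_effects,
    tukey_hsd,
)
from synpop.population import HaplotypePopulation
from synpop.synsim import batch_meiosis


class TestTraitCalibration:
    def test_founder_variance_equals_v0_exactly(self, small_pool):
        trait = sample_qtl_effects(small_pool, n_qtl=100, v0=0.3, rng=1)
        gv = trait.genetic_values(small_pool)
        assert gv.var(ddof=1) == pytest.approx(0.3, rel=1e-12)

    def test_founder_mean_equals_target(self, small_pool):
        trait = sample_qtl_effects(small_pool, n_qtl=100, target_mean=1.0, rng=2)
        assert trait.genetic_values(small_pool).mean() == pytest.approx(1.0, abs=1e-12)

    def test_single_qtl_closed_form(self, small_pool):
        """With one QTL the scaled effect satisfies the observed-dosage
        variance identity var(g) = a^2 var(dosage) = v0."""
        trait = sample_qtl_effects(small_pool, n_qtl=1, v0=0.1, rng=3)
        dos = small_pool.dosage()[:, trait.qtl_indices[0]]
        assert trait.effects[0] ** 2 * dos.var(ddof=1) == pytest.approx(0.1, rel=1e-10)

    def test_var_e_tied_to_h2(self, small_pool):
        trait = sample_qtl_effects(small_pool, n_qtl=50, v0=0.3,
                                   target_h2=0.6, rng=4)
        assert trait.var_e == pytest.approx(0.3 * 0.4 / 0.6)
        assert trait.with_h2(0.8).var_e == pytest.approx(0.3 * 0.25)

    def test_too_many_qtl_rejected(self, small_pool):
        with pytest.raises(ValueError, match="segregates"):
            sample_qtl_effects(small_pool, n_qtl=10**6, rng=5)


class TestMeiosis:
    def test_zero_length_chromosome_returns_whole_haplotype(self):
        loci = pd.DataFrame({"snp_id": list("abc"), "chrom": "1",
                             "pos_bp": [1, 2, 3], "pos_cm": [0.0, 0.0, 0.0]})
        genome = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        for seed in range(10):
            gam = meiosis(genome, loci, rng=seed)
            assert gam.tolist() in ([0, 0, 0], [1, 1, 1])

    def test_haldane_recombination_fraction(self):
        """Two loci 50 cM apart recombine at 0.5(1 - e^-1) = 0.316."""
        loci = pd.DataFrame({"snp_id": ["a", "b"], "chrom": "1",
                             "pos_bp": [1, 2], "pos_cm": [0.0, 50.0]})
        genomes = np.tile(np.array([[0, 0], [1, 1]], dtype=np.int8)[None],
                          (100_000, 1, 1))
        gam = batch_meiosis(genomes, loci, np.random.default_rng(0))
        rec = (gam[:, 0] != gam[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-1))
        assert abs(rec - expected) < 0.005

    def test_homozygous_parent_gives_constant_gamete(self):
        loci = pd.DataFrame({"snp_id": [f"s{i}" for i in range(20)],
                             "chrom": "1", "pos_bp": np.arange(1, 21),
                             "pos_cm": np.linspace(0, 100, 20)})
        genome = np.tile(np.array([0, 1] * 10, dtype=np.int8), (2, 1))
        for seed in range(5):
            assert np.array_equal(meiosis(genome, loci, rng=seed), genome[0])

    def test_independent_assortment_across_chromosomes(self):
        loci = pd.DataFrame({"snp_id": ["a", "b"], "chrom": ["1", "2"],
                             "pos_bp": [1, 1], "pos_cm": [0.0, 0.0]})
        genomes = np.tile(np.array([[0, 0], [1, 1]], dtype=np.int8)[None],
                          (50_000, 1, 1))
        gam = batch_meiosis(genomes, loci, np.random.default_rng(1))
        rec = (gam[:, 0] != gam[:, 1]).mean()
        assert abs(rec - 0.5) < 0.01


class TestAdvanceGeneration:
    def test_size_is_crosses_times_progeny(self, small_pool):
        off = advance_generation(small_pool, 30, 4, rng=1)
        assert off.n_individuals == 120

    def test_identical_homozygous_parents_give_identical_progeny(self, small_pool):
        haps = np.ones((5, 2, small_pool.n_loci), dtype=np.int8)
        pop = HaplotypePopulation(haps, small_pool.loci, "X")
        off = advance_generation(pop, 10, 5, rng=2)
        assert (off.haplotypes == 1).all()
        trait = sample_qtl_effects(small_pool, n_qtl=50, rng=3)
        assert trait.genetic_values(off).var(ddof=1) == pytest.approx(0.0, abs=1e-12)

    def test_allele_frequencies_preserved_in_expectation(self, small_pool):
        """Per-locus frequency change is bounded by the binomial drift SE
        across replicates."""
        diffs = []
        for seed in range(30):
            off = advance_generation(small_pool, 100, 5, rng=seed)
            diffs.append(off.allele_frequencies() - small_pool.allele_frequencies())
        mean_diff = np.mean(diffs, axis=0)
        p = small_pool.allele_frequencies()
        se = np.sqrt(p * (1 - p) / (2 * 60) / 30) + 1e-9
        assert np.mean(np.abs(mean_diff) < 4 * se) > 0.95

    def test_single_parent_rejected(self, small_pool):
        pop = small_pool.subset([0])
        with pytest.raises(ValueError, match="selfing"):
            advance_generation(pop, 5, 2, rng=0)

    def test_no_selfing_parent_pairs_distinct(self, small_pool):
        # progeny of 2 parents: every individual gets one gamete from each
        pop = small_pool.subset([0, 1])
        pop.haplotypes[0] = 0
        pop.haplotypes[1] = 1
        off = advance_generation(pop, 20, 5, rng=4)
        dos = off.dosage()
        # each progeny has exactly one all-0 and one all-1 gamete: dosage
        # sums to n_loci
        assert np.all(dos.sum(axis=1) == off.n_loci)


class TestVarianceEstimation:
    def test_zero_error_variance_gives_h2_one(self, small_pool):
        trait = sample_qtl_effects(small_pool, n_qtl=50, rng=1).with_h2(1.0)
        est = estimate_variances(small_pool, trait, rng=2)
        assert est.h2_realized == 1.0
        assert est.sigma2_p == est.sigma2_a

    def test_h2_construction_at_06(self):
        """In a large founder pool, varE = (2/3) v0 realizes H2 ~ 0.6."""
        from synpop import FounderPoolSpec, generate_founder_pool

        pool = generate_founder_pool(FounderPoolSpec(
            n_individuals=4000, n_chromosomes=2, n_snp_per_chromosome=100,
            seed=6))
        trait = sample_qtl_effects(pool, n_qtl=100, target_h2=0.6, rng=7)
        est = estimate_variances(pool, trait, rng=8)
        assert abs(est.h2_realized - 0.6) < 0.03

    def test_neutral_drift_of_gene_diversity(self, small_pool):
        """One generation of random mating from N parents shrinks the
        HWE-expected additive variance by 1 - 1/(2N) on average."""
        rng = np.random.default_rng(9)
        N = 10
        ratios = []
        for _ in range(200):
            trait = sample_qtl_effects(small_pool, n_qtl=100, rng=rng)
            parents = small_pool.subset(rng.choice(60, N, replace=False))
            off = advance_generation(parents, 100, 5, rng=rng)
            ratios.append(hwe_additive_variance(off, trait)
                          / hwe_additive_variance(small_pool, trait))
        assert abs(np.mean(ratios) - (1 - 1 / (2 * N))) < 0.015

    def test_tiny_population_rejected(self, small_pool):
        trait = sample_qtl_effects(small_pool, n_qtl=20, rng=1)
        with pytest.raises(ValueError):
            estimate_variances(small_pool.subset([0]), trait, rng=0)


class TestExperiment:
    def test_bookkeeping_one_record_per_cell(self, small_pool):
        design = SimulationDesign(
            parent_counts=(5, 8), n_crosses=20, progeny_per_cross=5,
            n_generations=2, iterations=1, h2_levels=(0.6,), n_qtl=50, seed=1)
        table = run_synthetic_experiment(design, small_pool)
        assert len(table.records) == 2 * 2 * 1 * 1
        cells = table.records.groupby(
            ["parent_count", "generation", "h2_input"]).size()
        assert (cells == 1).all()

    def test_determinism_under_fixed_seed(self, small_pool):
        design = SimulationDesign(
            parent_counts=(5,), n_crosses=10, progeny_per_cross=5,
            n_generations=2, iterations=2, h2_levels=(0.6,), n_qtl=30, seed=7)
        a = run_synthetic_experiment(design, small_pool)
        b = run_synthetic_experiment(design, small_pool)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_founder_pool_must_exceed_parent_count(self, small_pool):
        design = SimulationDesign(parent_counts=(100,), n_qtl=30)
        with pytest.raises(ValueError, match="founder pool"):
            run_synthetic_experiment(design, small_pool)

    def test_variance_anomalies_flagged_not_clipped(self, small_pool):
        design = SimulationDesign(
            parent_counts=(5,), n_crosses=10, progeny_per_cross=3,
            n_generations=2, iterations=10, h2_levels=(0.9,), n_qtl=30, seed=3)
        table = run_synthetic_experiment(design, small_pool)
        anomalous = table.records[table.records["variance_anomaly"]]
        # records where sigma2_p < sigma2_a are kept with their raw values
        assert (anomalous["sigma2_p"] < anomalous["sigma2_a"]).all()


class TestTukey:
    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 50)
        res = tukey_hsd({"a": base, "b": base.copy(), "c": base.copy()},
                        alpha=0.001)
        assert len(set(res.letters.values())) == 1

    def test_ten_sd_separation_distinct_letters(self):
        rng = np.random.default_rng(2)
        res = tukey_hsd({"lo": rng.normal(0, 1, 50),
                         "hi": rng.normal(10, 1, 50)}, alpha=0.001)
        assert set(res.letters["lo"]) & set(res.letters["hi"]) == set()

    def test_hsd_matches_studentized_range_oracle(self):
        """3-group fixture: HSD equals the brute-force q-quantile times
        sqrt(MSE/n) computed from scratch."""
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(mu, 1.3, 40) for g, mu in
                  [("a", 0.0), ("b", 0.7), ("c", 2.5)]}
        res = tukey_hsd(groups, alpha=0.01)
        vals = list(groups.values())
        k, n = 3, 40
        mse = np.sum([(v - v.mean()) ** 2 for v in vals]) / (3 * n - 3)
        q = sps.studentized_range.ppf(0.99, k, 3 * n - 3)
        assert res.hsd == pytest.approx(q * np.sqrt(mse / n), rel=1e-10)

    def test_against_statsmodels_pairwise(self):
        """Significance decisions agree with statsmodels' Tukey HSD."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(4)
        groups = {g: rng.normal(mu, 1.0, 30) for g, mu in
                  [("a", 0.0), ("b", 0.4), ("c", 1.5)]}
        res = tukey_hsd(groups, alpha=0.05)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 30)
        sm = pairwise_tukeyhsd(data, labels, alpha=0.05)
        rejects = dict(zip([tuple(r[:2]) for r in sm.summary().data[1:]],
                           [r[-1] for r in sm.summary().data[1:]]))
        for (g1, g2), reject in rejects.items():
            share = bool(set(res.letters[g1]) & set(res.letters[g2]))
            assert share == (not reject)

    def test_degenerate_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            res = tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.degenerate
        assert res.letters["a"] != res.letters["b"]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1, 2, 3]})
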