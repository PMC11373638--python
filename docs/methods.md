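# Methods

This note documents the models implemented in `synpop`, their calibration,
the numerical choices, and what the synthetic-data generators do and do not
emulate.

## The forward simulator (`synsim`)

**State.** A population is a set of phased diploid individuals over mapped
biallelic loci (`HaplotypePopulation`: an `(n, 2, L)` allele array plus a
locus map with chromosome, bp and cM positions). The hexaploid crop the
package targets is genotyped and modeled throughout as diploid dosages — the
convention of the SNP-calling pipeline that produces the data.

**Trait model.** A purely additive polygenic trait: `n_qtl` causative loci
drawn uniformly from the segregating loci of the founder pool, raw effects
standard normal, then rescaled so that the *sample variance of genetic values
in the full founder pool equals `v0` exactly*; an intercept shifts the
founder-pool mean genetic value to `target_mean` (default 1). Dominance,
epistasis, G×E and mutation are absent by design, so additive variance equals
total genetic variance. The residual variance is fixed **once**, at founder
calibration:

    var_e = v0 * (1 - H2) / H2

and is *not* re-tuned per generation. Realized heritability in later
generations therefore drifts with the genetic variance — this is the reading
under which H² is an input property of the trait, not a per-generation
constraint.

Defaults: `n_qtl = 1000`, `v0 = 0.3` (chosen to put simulated σ²ₐ in the
0.2–0.3 range typical of published synthetic-population variance tables;
fully configurable — all scale-free outputs such as realized H², ratios and
orderings are independent of it), `H2 ∈ {0.4, 0.6, 0.8}`.

**Meiosis.** Per chromosome, crossover count ~ Poisson(map length/100),
crossover positions uniform on the genetic map, no interference (Haldane
model), starting haplotype a fair coin. The map length is taken as the cM
span of the mapped loci; crossovers outside that span cannot affect a gamete,
so restricting to it is distributionally exact. Meiosis is vectorized over
batches of gametes (crossover-parity accumulation), which is what makes the
factorial experiment tractable at desk scale.

**Mating.** `advance_generation` pairs two *distinct* parents per cross
(uniform with replacement across crosses, selfing excluded) and produces each
progeny from two independent meioses; a generation has exactly
`n_crosses × progeny_per_cross` individuals. Founder-to-SYN1 crossing uses
the same operator as later advancements (the crossing block is panmictic).

**Drift expectations (the module's strongest oracle).** With parents drawn
from a Hardy–Weinberg pool:

* the *gene-diversity* (HWE-expected) additive variance
  `2 Σ a² p(1-p)` obeys the classical neutral-drift law exactly:
  `E[v(t+1)] = v(t) (1 - 1/(2N))` for `N` parents;
* the *realized genotypic* variance obeys `E[v(t+1)] = v(t) (1 - 1/N)`
  instead. Excluding selfing makes the two gametes of an individual
  negatively correlated across the parent pool (covariance `-Var(p_i)/(N-1)`),
  i.e. transient excess heterozygosity, which costs exactly another `1/(2N)`
  in the first generation. The deficit dissipates the next generation (the
  population returns to HW proportions at its new frequencies), which is why
  7-parent synthetics show a small σ²ₐ *rise* from SYN1 to SYN2 before
  flattening.

Both laws are verified by simulation in the test suite (500 replicates,
`N ∈ {7, 20}`). `synsim.hwe_additive_variance` exposes the gene-diversity
form.

**The factorial experiment.** Per iteration and parent count: draw parents
without replacement from the founder pool, sample a *fresh* QTL architecture
(effects resampled each iteration — the between-iteration spread of the
variance table comes from architecture and parent resampling, not from the
negligible sampling error of large progeny sets), intermate to SYN1, advance
to SYN4 with no selection, and record σ²ₐ, σ²ₚ and realized H² per
generation. The same genome lineage is scored under every heritability level
(only `var_e` differs). Per-iteration seeds derive from a single
`SeedSequence`, so the whole experiment is bit-reproducible.

**Problem sizes.** The full-scale design (1,000 crosses × 100 progeny,
100 iterations) is available but the package's working configuration is the
desk scale: **100 crosses × 20 progeny, 25 iterations**, a founder pool of
80 individuals on a 21-chromosome genome with 60 SNPs per chromosome
(1,260 loci — enough to place 1,000 QTL). At 2,000 progeny per generation the
Monte-Carlo error of a variance estimate is ~3 %, so cell means over 25
iterations are stable; the founder-number ordering and the Tukey separations
are identical at both scales.

**Tukey HSD.** One-way ANOVA MSE, studentized-range quantile
`q(1-α, k, df)` from `scipy.stats.studentized_range`,
`HSD = q · sqrt(MSE/n_h)` with the harmonic mean group size (Tukey–Kramer),
and a compact letter display in which groups sharing a letter differ by less
than HSD. The letter assignment uses maximal intervals on the sorted means,
which is exact for a single common threshold. Cross-checked against
`statsmodels`' pairwise Tukey HSD in the tests. Zero within-group variance
everywhere is flagged as degenerate (HSD = 0; only exactly equal means
share a letter).

### Why realized H² sits slightly below the input level

With `var_e` fixed at founder calibration, the expected realized H² in SYN
generations is

    E[H2_realized] ≈ (v0 · d) / (v0 · d + var_e),   d ≈ 1 - 1/N … 1

i.e. slightly **below** the input H² (≈ 0.58 across the grid for input 0.6 at
desk scale, because the founding bottleneck removes a 1/N share of variance).
A grid-average realized H² *above* the input level — as sometimes reported
from small-sample variance estimates — can only arise from Jensen-type
inflation of a mean of ratios with noisy denominators, or from a founder pool
with excess homozygosity whose intermating releases additive variance.
Neither applies to this package's HWE founder pools, so the package reports
the unbiased quantity and documents the difference rather than recalibrating
`var_e` per generation.

## Synthetic data (`synthdata`)

The generator emulates a GBS-genotyped breeding population of an outcrossing
grass:

* 21 chromosomes, default 150 cM and 10⁸ bp each (typical grass-genome
  scale), SNP physical positions uniform, genetic positions proportional to
  physical ones;
* minor allele frequencies from a Beta distribution rescaled to (0, 0.5]
  with mean 0.22 (the genome-wide mean MAF of a filtered GBS panel) and
  concentration 3; haplotype alleles are independent Bernoulli draws, so
  founders are in exact Hardy–Weinberg proportions;
* **LD**: by default sites are independent (no ancestral LD). The optional
  block-mosaic mode copies blocks of consecutive SNPs from a small pool of
  ancestral haplotypes per chromosome; with 8 ancestors and 8-SNP blocks the
  mean pairwise r² within a 10 Mbp window is ≈ 0.09, matching the LD level
  of real GBS panels of such populations. The block mode produces a
  step-like, not distance-smooth, decay profile — adequate for testing
  LD-aware methods, not a coalescent model;
* GBS missingness: per-SNP missing rates drawn from a Beta around the target
  mean (so some SNPs exceed a 10 % filter threshold and the filters have
  work to do), plus an optional fraction of low-call-rate individuals pushed
  below the call-rate floor. Masked-cell positions are returned so
  imputation can be scored against truth;
* phenotypes: `value = genetic value + year effect + N(0, var_e·scale)`, one
  record per individual × year.

What passing tests on these data do **not** show about real data: real
founder pools carry relatedness, inbreeding and distance-decaying LD that the
generator does not model; absolute imputation accuracies and predictive
abilities on real panels will differ even when the orderings tested here
hold.

## Genotype I/O, filtering, imputation (`genio`)

Dosage matrices (0/1/2, `nan` missing) with per-SNP chromosome/position
metadata. VCF v4.2 is read via cyvcf2 (multi-allelic records skipped and
counted) and written with GT fields (`./.` for missing, placeholder alleles —
dosage data carry no nucleotides).

**Filtering order** (single pass): individuals by call rate ≥ 0.80, then
SNPs by missingness ≤ 0.10 on retained individuals, then SNPs by MAF ≥ 0.03
on retained individuals. One subtlety, found by property testing: removing a
high-missingness SNP can lower an individual's call rate *on the surviving
panel* below the floor, so a second pass is not a strict no-op on adversarial
tiny matrices; at realistic panel sizes (hundreds of SNPs and more) the
interaction vanishes and filtering is idempotent.

**LD-kNN imputation.** For each SNP `s` with missing calls: select the `l`
markers with highest composite-LD r² to `s` (dosage correlation over
pairwise-complete individuals — appropriate for unphased GBS data); the
distance from the target individual to each candidate donor is the mean
absolute dosage difference over those markers (mutually missing sites
ignored); the imputed dosage is the 1/distance-weighted mean of the `k`
nearest donors' dosages at `s`, rounded to an integer call in {0, 1, 2}
(downstream population-genetic statistics assume calls). Defaults
`l = 30, k = 10`; a zero distance is replaced by ε = 10⁻⁶ for weighting, and
ranking ties break on individual index for determinism. A SNP with no
observed calls at all is left missing and reported.

## Diversity statistics (`popdiv`)

* **Weir–Cockerham F<sub>ST</sub>**: per-SNP θ = a/(a+b+c) from the
  two-population variance components (focal generation vs the pooled
  remainder — the summary convention for per-generation tables), negative
  estimates retained; SNPs with < 2 called individuals in either group, or a
  zero denominator (monomorphic everywhere), are skipped and counted. Note
  the moments estimator is deterministically slightly *negative* for
  identical samples (it subtracts the expected sampling variance).
* **Nei's D** (1972 standard distance): `D = -ln(Jxy / sqrt(Jx·Jy))` with
  gene identities averaged over loci computable in both groups; symmetric,
  zero diagonal; opposite fixation at every locus (infinite D) is reported
  as the cap `-ln(1e-12) ≈ 27.6` with a warning.
* **Shannon's H**, per individual over its dosage proportions
  (`q_s = d_s / Σd`, `H = -Σ q ln q`): the only reading under which a
  diversity table's per-group min/max/mean over individuals approaches
  `ln(m)` for an m-SNP panel (ln 13633 = 9.52). All-zero-dosage individuals
  get H = 0 with a warning.
* **PCA**: per-SNP mean imputation of missing cells, column centering, no
  variance scaling (the `prcomp` default), SVD; variance proportions sum to
  one over all axes; a matrix of identical rows returns an explicit
  degenerate result.
* **LD decay**: composite r² for all intra-chromosomal pairs within a
  window (default 10 Mbp), pairwise-complete individuals; locally weighted
  (lowess) smoothing with span 0.3; the decay distance is the smallest
  distance at which the fitted curve falls below the threshold (default
  r² = 0.2), interpolated at the crossing, `NaN` if the curve never drops
  below, and the first pair distance if the curve starts below. Fewer than
  five pairs skip smoothing (raw sorted points are used).

## RR-BLUP (`gpred`)

Model `y = Xβ + Zu + ε` with one fixed-effect column per evaluation year
(cell-means coding) and `Z` the column-centered marker dosages of each
record's individual (centering vector estimated on the training records and
stored for application to prediction targets — the standard RR-BLUP marker
coding). REML estimates the variance ratio λ = σ²ₑ/σ²ᵤ by a 1-D bounded
search on log λ (tolerance 10⁻¹⁰, bounds e±25) over the profiled restricted
likelihood after one eigendecomposition of the fixed-effect-projected
`ZZᵀ + I`; β and u then solve the mixed-model equations through the
n-dimensional system `H = ZZᵀ + λI`. Correctness is pinned to a dense MME
solve (10⁻⁶ relative) and to the two ridge limits (λ→∞: u→0, β→year means;
λ→0: interpolation of a noiseless trait).

**Cross-validation**: individuals (not records) are partitioned into 4 folds
per replication (the 75/25 split); ability is the Pearson correlation in the
validation fold between GEBV and the *year-adjusted* observed mean (records
minus fitted year effects, averaged per individual). Note the null
distribution of ability on a single finite dataset is not centered exactly at
zero — the one realized noise vector carries an O(1/√n) chance correlation
with the genotype structure that refolding cannot remove; averaging over
independent datasets recovers zero.

**Population prediction**: predictions for unphenotyped target generations
use the average year effect plus GEBV (no year is observed for them), are
averaged over replications that refit the model on random 75 % subsets of
the training individuals, and generation means are compared by Tukey HSD at
α = 0.001. Target SNP sets are reconciled with the training set by
intersection (mismatches logged; missing target calls mean-imputed with the
training centering vector).

## Pipeline and reproducibility (`cli` / `pipeline`)

A single master seed is split into named per-stage substreams
(SHA-256 of `"{seed}:{stage}"`, reduced below 2³¹), recorded in a manifest
together with package/library versions, all stage parameters, input-file
checksums and the output list — sufficient to reproduce any run bit-for-bit.
Stage failure aborts with the stage name; partial outputs and the manifest
are retained.

## Known limitations

* Founder pools are unrelated and non-inbred; no pedigree, selection history
  or realistic coalescent LD.
* Block-mosaic LD is step-like in physical distance; decay-distance
  estimates on synthetic data are not comparable to real panels.
* The simulator models no dominance, epistasis, G×E, mutation or migration
  (deliberately, matching the additive no-selection setting it studies).
* Phasing, reference-panel imputation, indels and multi-allelic variants are
  out of scope; polyploid dosage models are not implemented.
* Tukey letters use a single common HSD threshold (harmonic-mean group
  size); strongly unbalanced designs would need per-pair thresholds.
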