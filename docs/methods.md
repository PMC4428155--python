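# Methods

## Scope and model

`wgrbench` implements a complete simulation study of Bayesian whole-genome
regression (WGR) for distantly related individuals: synthetic genotypes with
controllable LD and allele-frequency spectra, additive trait simulation
under configurable genetic architectures, three WGR samplers (GBLUP,
Bayes A, Spike-Slab), per-model genomic-heritability estimators, and a
replicated training–testing validation design with kinship filtering.

The phenotype model is strictly additive: `y_i = Σ_j Z_ij β_j + ε_i` with
raw dosages `Z_ij ∈ {0,1,2}`, normal effects and normal residuals.
Dominance, epistasis, covariates and non-Gaussian traits are out of scope.

## Synthetic genotypes

Genotypes come from a founder-mosaic model. Per LD block, a pool of
`F` founder haplotypes (default 200) is built by a frequency-threshold rule:
founder `f` carries the minor allele at marker `m` iff its per-block shuffled
quantile lies below the marker's target frequency `p_m`, drawn from a
configurable MAF law. Each sampled haplotype is a mosaic of founders; the
founder is re-drawn between adjacent markers with probability
`min(2·switch_prob, 1)`, so `switch_prob` behaves like a recombination
fraction: 0 puts a whole block on one founder (r² = 1 between
equal-frequency markers) and 0.5 is exactly free recombination (mean pair r²
at the 1/(n−1) independence floor). Blocks are independent by construction.

Two consequences of the threshold rule are deliberate:

* markers with similar target frequency are strongly correlated in the
  founder pool, so low switch probabilities give the strong flanking-LD
  regime (mean r² ≈ 0.6) seen on dense common-SNP arrays;
* a rare variant can never be in high r² with a common neighbour, which is
  precisely why the LOW-MAF scenario produces weak marker–QTL LD and
  missing heritability.

`freq_autocorr` (default 0) is the probability that an adjacent marker
reuses the previous marker's target frequency; raising it pushes flanking
r² toward 1 and is how the strongest-LD diagnostics are produced. The exact
LD decay of the real panel being emulated is not identifiable from summary
tables, so this calibration is best-effort by design.

MAF laws: a common-variant spectrum (Beta(1, 1.2) rescaled to
(0.005, 0.5), median ≈ 0.22), a low-frequency-enriched law
(Beta(0.5, 3.5) on the same support) for QTL pools, and a 0.7/0.3 mixture
of the two for whole panels from which a pool will be partitioned. The
mixture exists because, at desk scale, a purely common-variant pool does not
contain enough loci below MAF 0.05 to fill the LOW-MAF strata; at full
scale (hundreds of thousands of array SNPs) the common-variant spectrum
itself supplies them. Monomorphic columns are regenerated (fresh target
frequency on the same mosaic paths, falling back to Bernoulli founder
alleles if the threshold carrier set is unreachable); a law that keeps
producing monomorphic loci raises an error rather than emitting a broken
panel.

## Trait simulation

Loci are randomly partitioned into a marker set and a QTL pool. QTL are
drawn from the pool uniformly (RAND) or by stratified sampling (LOW-MAF:
75% below MAF 0.05, 25% in [0.05, 0.15), none above; quotas are
proportions times `n_qtl`, rounded, with the last stratum absorbing the
remainder; an under-filled stratum raises an error naming the stratum).

Architectures are parameterized by the number of large-effect QTL
(`n_large`) and the fraction of genetic variance they carry (`pve_large`),
with standard settings h² = 0.5 and V(ε) = 0.5, giving target genetic
variance `V_g = V(ε)·h²/(1−h²) = 0.5`. Effect variances are solved in
closed form from the **realized** allele frequencies of the drawn QTL
(`Σ 2p(1−p)·σ² = share·V_g` per stratum): targeting is only achievable
conditionally on the drawn frequencies, and LD among QTL still makes
realized h² vary across replicates — that variation is part of the design
and is left uncorrected (an `exact_h2` rescale flag exists for unit tests
only). The large-effect set is drawn uniformly among QTL, independent of
MAF. Realized pve is reported as `var(g_large)/(var(g_large)+var(g_small))`.

## Samplers

All three models are Gibbs samplers over `{μ, effects, variance
components}` with scaled-inverse-χ² priors on variances (a degrees-of-
freedom of `inf` pins a variance at its scale, used by the fixed-variance
oracle tests). The intercept has a flat prior; phenotypes are not
pre-standardized. Dosage columns are centered by their mean (equal to twice
the sample allele frequency). Single-site effect sweeps are numba-compiled;
every random number is pre-drawn per iteration from a seeded numpy
Generator and passed into the kernels, so chains are bit-reproducible given
the seed.

* **GBLUP** is available in marker form (common σ²_β) and in GRM form:
  the random effect u ~ N(0, σ²_u G) sampled in the eigenbasis of G, which
  makes every iteration O(n) after one eigendecomposition. The two forms
  are the same model; tests verify their training predictions agree within
  Monte Carlo error.
* **Bayes A** uses the normal/inverse-χ² augmentation of the scaled-t. S0
  follows the sum-of-squares parametrization (prior mean of a marker
  variance is S0/(df−2)), with df fixed at 5. By default S0 carries a
  Gamma(1.1, rate) hyperprior with the rate solved so E(S0) matches the
  proportion-of-variance rule below; this matches how the reference
  software for this model family actually behaves and is what lets the
  scaled-t adapt its global scale to sparse architectures. `S0=...,
  s0_shape=None` fixes it instead.
* **Spike-Slab** defaults to the BSLMM decomposition: every marker has a
  dense background effect α_j ~ N(0, σ²_α) (so u = X_c α is the polygenic
  term — mathematically identical to a GRM random effect, kept in marker
  form so updates stay O(n) per marker) plus, with probability π, a sparse
  effect γ_j ~ N(0, σ²_γ) against a point mass at zero. Indicators are
  sampled with γ_j integrated out. π has a log-uniform prior on [1/p, 1]
  sampled by a Metropolis step on log π. The pure George–McCulloch
  two-normal mixture is available via `variant="george_mcculloch"`.

Default prior scales follow a proportion-of-variance rule: the prior mode
of the genetic (residual) variance equals R²·var(y) ((1−R²)·var(y)) with
R² = 0.5. Default chains are 12,000 iterations, 2,000 burn-in, thinning 5 —
sized for desk-scale instances; effective sample sizes (Geyer initial
positive sequence) are reported per fit. Missing genotypes on the real-data
path are mean-imputed per locus after quality control.

Correctness is anchored to independent oracles: closed-form ridge/BLUP
solutions under pinned variances, and brute-force quadrature posteriors
(2-D grids; configuration enumeration for the point-mass mixture) on
5-individual, 2-marker instances, one per prior family.

## Heritability estimators

Each model's genomic heritability is computed draw-wise, the way that model
defines it: σ²_g/(σ²_g+σ²_ε) for GBLUP; `Σ_j 2p_j(1−p_j)·S0/(df−2)`
plugged into the same ratio for Bayes A (per-draw S0 when sampled; sample
frequencies of the fitted loci); and the PVE form
`V(Xβ+u)/(V(Xβ+u)+τ⁻¹)` for Spike-Slab, with V(·) the empirical variance
of that draw's genetic values over training individuals (an analytic
expectation would be an alternative; the empirical form matches how PVE is
reported in practice). All draws lie in [0, 1] by construction.

## Validation design

Repeated random holdout: per replicate, a candidate validation group is set
aside and only candidates whose **maximum** genomic relationship to any
training individual is ≤ 1/8 are retained (the bound is read as uniform
over training pairs). The same split and the same simulated trait are
reused across methods and data-used variants within a replicate (paired
design), which is what makes per-replicate method differences and the
Wilcoxon signed-rank comparison meaningful. A fresh trait is simulated per
replicate. Wilcoxon tests use scipy (exact small-sample distribution,
normal approximation with tie handling otherwise); tests verify agreement
with brute-force enumeration over sign assignments for n ≤ 10.

A practical caveat at reduced scale: the GRM's off-diagonal noise has
standard deviation ~1/√M_eff over effectively independent loci. Individuals
here are unrelated by construction, so with only a few hundred loci the
noise alone exceeds 1/8 and would empty every validation set. Experiments
that exercise the 1/8 filter therefore estimate relatedness genome-wide —
causal panel plus independent background marker blocks (≥ ~2,000 effective
loci) — exactly as kinship is estimated in practice; toy configurations
instead widen the threshold and say so in their config.

## Scaled experiment designs

The stock experiments (`wgrbench.experiments`) preserve the structural
ratios of the full-size study while keeping single-CPU runtimes in minutes:

* sampler stratification: 500 QTL from a 20,000-locus low-MAF-enriched
  pool, 20 seeds;
* simulator calibration: 30 replicate traits at n = 2,000, 500 QTL;
* heritability recovery: GBLUP on causal genotypes, n = 1,500, 500 loci,
  10 replicates (no missing heritability, so the mean estimate should sit
  on the simulated 0.5);
* perfect-LD accuracy: Spike-Slab, train 2,000 / 200 filtered holdouts,
  400 QTL with 40 large (pve 0.75), preserving n·h²/M_e of the full
  design, 10 replicates;
* overfitting: GBLUP training R² at marker:record ratio ≈ 0.95;
* method ordering: markers-only fits with p ≫ n (3,000 markers, 600
  records) and an extremely sparse signal (5 of 50 QTL carrying 75% of
  V_g) — the regime where selection and differential shrinkage beat
  homogeneous shrinkage; smaller marker:record ratios wash the ordering
  out, which is itself consistent with how the phenomenon scales;
* LD degradation: QTL-only vs markers+QTL vs markers-only under moderate
  switch probability.

## What the synthetic data does and does not show

The generator reproduces block LD with tunable decay, realistic folded MAF
spectra, frequency-dependent marker–QTL r², and exact stratified QTL
sampling. It does **not** emulate human demographic history, cryptic
relatedness, assortative mating, genotyping error, sex chromosomes or
phasing ambiguity. Passing tests therefore demonstrate correctness of the
methods and the direction/magnitude of LD- and architecture-driven effects
under the stated generative model — not calibrated predictions for any
particular human cohort.

## Numerical choices

* GRM: VanRaden centering by 2p before the cross-product, denominator
  Σ 2p(1−p). The raw (uncentered) cross-product form that is sometimes
  displayed alongside this construction gives mean relationships without
  the interpretable 0/0.125/0.5 scale; the centered form is what makes the
  1/8 filter and the variance-component heritability meaningful, so it is
  used throughout.
* GRM-form GBLUP: eigenvalues clipped at 0; components with eigenvalue
  below 1e-8·max are fixed at zero; a GRM with eigenvalues below
  −1e-6·max is rejected as non-PSD.
* Flanking-LD summaries: edge QTL contribute only their existing flank;
  a marker sharing the QTL's position counts as the left flank (lower
  index wins); monomorphic columns are skipped.
* QC order: SNP missingness (≥ threshold removes, closed bound) →
  individual missingness → MAF floor (strict <) computed on the surviving
  panel; the order is observable (a fixture in the tests demonstrates it).
* All pipeline randomness derives from one master seed through
  `np.random.SeedSequence` keyed on stage name and grid coordinates; the
  run manifest echoes every derived seed.

## Known limitations

* GBLUP with externally LD-adjusted marker weights is supported only
  through the `weights` hook of `compute_grm`; no weighting algorithm is
  implemented here.
* The Bayes A degrees of freedom is fixed (default 5); estimating it would
  likely soften that model's biases under sparse architectures.
* Heritability standard errors ignore relatedness structure among training
  individuals.
* The Spike-Slab sampler mixes π by a random-walk Metropolis step; for
  very large p, mixing of π (not of the predictions) can be slow.
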