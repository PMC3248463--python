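# Methods

## The generative model

The package models a standardized quantitative phenotype as the sum of a
polygenic score and independent residual noise:

    Z = WAS + R,   R ~ N(0, σ²_remaining),   σ²_remaining = 1 − var(WAS)

with effect-allele dosages at `N` independent biallelic SNPs drawn
`Binomial(2, p_j)` (Hardy-Weinberg, no LD) and

    WAS = Σ β_j·dosage_j − α,   α = Σ β_j·2p_j,
    var(WAS) = Σ β_j²·2p_j(1−p_j).

Rare-variant scenarios add a second centered score from `n` variants of
frequency `F` and per-allele effect `B` (SD units):

    Z = WAS + [Σ B·dosage_rv − α_rv] + R,   α_rv = Σ 2BF,
    σ²_remaining = 1 − var(WAS) − Σ B²·2F(1−F),

so `var(Z) = 1` in every scenario and the score definition — hence the
observable being tested — never changes. Scenario parameters with
`var(WAS) + var(rare) ≥ 1` are rejected.

Assumptions worth keeping in mind: SNPs are unlinked and effects purely
additive; the phenotype is already age/gender standardized upstream;
allele frequencies used for centering are the same ones used for
simulation (a frequency source mismatch between discovery and target
cohorts shifts α and is the caller's responsibility — `SnpPanel.with_frequencies`
re-keys a panel to cohort-specific frequencies).

## Per-allele tail model and expected odds ratios

Conditioning on a single allele drawn at one SNP, the phenotype is
normal with

    M_i = β(1−p)   (trait-increasing allele),
    M_d = −βp      (trait-decreasing allele),
    V   = 1 − β²p(1−p),

a two-component mixture with mean exactly zero. These conditional means
follow directly from the binomial generative model (the companion allele
contributes `βp` on average, the centering removes `2βp`); the mixture
property `p·M_i + (1−p)·M_d = 0` and agreement with genotype-level
simulation are both asserted in the test suite. The expected
tall-vs-short allelic odds ratio evaluates per-allele normal tail masses
at the design cutoffs (survival/CDF routines, never `1 − Φ`, to avoid
cancellation); its approximate log-scale SE propagates the discovery
effect-size uncertainty by evaluating the OR at `β ± 1.96·se` and
dividing the log-range by `2·1.96`. Observed and expected log-OR SEs
combine in quadrature for the Z-test.

The power-equivalence calculation matches noncentrality parameters: for
groups drawn from symmetric Z bands, each tail's allele-frequency shift
is `β·p(1−p)·m` with `m` the truncated-normal band mean, the contrast
variance is `p(1−p)(1/(2n_short)+1/(2n_tall))`, and the equivalent
random-population `N` is the band-design NCP divided by the variance
explained (a quantitative-trait test on `N` random samples has
NCP = N·R²). The reference allele frequency defaults to 0.3, typical of
a common-variant panel; the result is invariant to the `β ↔ R²`
parametrization.

## Ascertainment schemes

Two schemes mirror how real extreme cohorts are collected:

- **Quota** (`QuotaScheme`): the population is partitioned into
  subpopulations (default sizes 4271/6582/5025/7610, kept as strata);
  from each, the most extreme individuals per tail are taken up to a
  quota (default 50), pooled, and randomly dropped to exact final group
  sizes (defaults 181 short / 192 tall). Ties at quota boundaries are
  broken by a seeded uniform jitter on rank.
- **Threshold** (`ThresholdScheme`): all individuals beyond Z cutoffs
  (defaults ±2.14) are eligible and random subsets of the target sizes
  (defaults 385 short / 456 tall from a 50,000-strong pool) are kept;
  optionally a middle group (|Z| < 2, default 1,224) is drawn from the
  remainder.

The simulator draws exactly the analysis pool rather than a larger
super-population that is then subsampled — the two are distributionally
identical for exchangeable individuals. Per-SNP missingness is applied
to ascertained cohorts as independent Bernoulli masking; scores are then
centered per individual over that individual's non-missing SNPs, which
keeps E[WAS] = 0 under any genotype-independent missingness pattern.

Stratified analyses re-select within an ascertained cohort either by Z
bands (threshold cohorts; including the "doughnut" — extremes minus the
most extreme band) or by per-subpopulation counts of the most extreme
individuals (quota cohorts, counts supplied by the caller using the
floor-of-expected-count rule). The identical rule runs inside every null
replicate: the symmetry between observed and simulated pipelines is what
makes the p-value exact with respect to the ascertainment process.

## Null inference

For each group (short/tall/middle), `null_mean_was_distribution`
replays simulate → ascertain → (missingness) → score over `n_replicates`
cohorts and summarizes the replicate mean scores by their mean and
variance; an observed group mean is then evaluated two-sided against
`Normal(μ_simulation, σ²_simulation)` as `2·min(Φ(t), 1−Φ(t))`, capped
at 1. The default replicate count is 10,000; the test suite and the
bundled demo run 400–500 replicates, at which the Monte-Carlo error in
(μ, σ) contributes relative p-value error below ~10% for p > 0.01, and
the replicate-mean distribution is comfortably normal for group sizes in
the hundreds (checked by the calibration test: under the generating
null, p-values are uniform and reject at the nominal 5%).

Scenario comparison rebuilds the null under each candidate rare-variant
model and flags a scenario consistent when every evaluated group's p
exceeds 0.05; the sign of (observed − scenario mean) distinguishes
"not enough shift" from "over-corrected" scenarios. When only the short
tail carries the scientific question, callers may evaluate that group
alone by passing a `{"short": mean}` mapping.

## Exact score sampling in replicate loops

Replicate-heavy loops do not need per-SNP genotypes when no missingness
is mirrored: selection acts on Z and the recorded statistic is the group
mean score. `ScoreSampler` therefore tabulates the exact population
distribution of the centered score — an iterated convolution of each
SNP's three-point dosage contribution on a uniform grid (~1e-4 SD
spacing; the linear splitting of off-grid atoms is equivalent to adding
noise of variance ≲1e-9 SD², and within-cell jitter at draw time keeps
the output continuous) — and inverts its CDF. This is distributionally
interchangeable with genotype-level simulation for these statistics; the
genotype path remains the reference implementation, the two are compared
by a KS test and by parallel null distributions in the suite, and the
genotype path runs whenever per-SNP data (e.g. missingness mirroring)
is required.

## Synthetic effect panel

The bundled 160-SNP panel emulates a large-consortium height GWAS hit
list: frequencies uniform on (0.05, 0.95), signed normal effects
rescaled so the score explains exactly 10% of trait variance (rms
|β| ≈ 0.044 SD), and SEs of `1/sqrt(2p(1−p)·130,000)` as from a ~130k
discovery sample. What it deliberately does not emulate: LD between
SNPs, winner's-curse inflation of discovery effects, allele-frequency
differences between discovery and target populations, and genotyping
artifacts beyond missing-at-random calls. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

## Experiment sizing in the test suite

Two experiment designs in the acceptance-level tests were set by
up-front power/feasibility calculations:

- **Calibration** runs at a reduced scale (pool 20,000, 120 per tail,
  500 inner replicates, 200 outer cohorts, one shared null): calibration
  of a p-value is scale-free, and the shared-null approximation
  perturbs the uniform distribution by far less than the KS test's
  resolution at 200 samples.
- **Scenario recovery** uses pool 200,000 with 1,000 individuals per
  ±2.326 tail. The pool size guarantees tail feasibility under every
  scenario (a B = −4 variant thins the tall tail by ~35%), and the
  group size gives ~94% power to reject the purely polygenic null for
  cohorts generated with (n = 10, B = −1, F = 0.005) — whose short-tail
  mean-score shift is ≈ +0.033 against a null SD of ≈0.010 — so that
  joint recovery (reject the wrong model, retain the right one) is the
  expected outcome rather than a coin flip. At a 385-per-tail scale the
  same shift is only ≈2.9 null SDs and single-cohort decisions become
  marginal, as the README example illustrates.
- **Expected-OR validation** simulates 5×10⁶ genotypes per (β, p)
  combination and integrates the Gaussian residual stage analytically
  per genotype class (conditional Monte Carlo). The comparison's target
  is the structural equivalence of the allele-level mixture formula and
  the genotype-level model; conditioning removes the residual-stage
  counting noise (which alone is ~1.5% at p = 0.1, comparable to the 2%
  agreement band) while leaving that structure fully tested. A plain
  realized-count check at one combination, with a count-based error
  band, runs alongside.

## Numerical choices and edge cases

- Normal tails via `scipy` `sf`/`cdf`; underflowing tail probabilities
  raise rather than return 0-odds.
- Mantel-Haenszel: statsmodels' pooled OR, Robins-Breslow-Greenland
  log-OR SE and 1-df chi-square without continuity correction, on
  allele-level tables; strata with a zero cell get Haldane-Anscombe 0.5
  on all cells and are flagged in the result. Logistic association uses
  a GLM/Binomial fit; complete separation raises instead of returning a
  divergent estimate.
- Inverse-normal transform: Blom offsets (r − 3/8)/(n + 1/4), average
  ranks for ties, constant input rejected.
- Sibling analysis: families with several siblings should be averaged to
  one pair before analysis (the CLI does this) to avoid
  pseudo-replication; CIs are normal approximations. The additive-model
  benchmark `r·φ(c)/Φ(−c)` makes differential tail regression a
  detectable model violation, not an artifact of tail selection.
- RNG: every stochastic function takes an explicit
  `numpy.random.Generator`; pipelines advance a single seeded stream, so
  a fixed seed reproduces outputs byte-for-byte.

## Known limitations

Independent SNPs only (no LD-aware simulation); fixed-effect
meta-analysis only; no covariate adjustment in association tests; no
liability-threshold disease model; empirical-quantile (rather than
normal-approximation) p-values for the mean score are not implemented.
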