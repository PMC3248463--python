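# polytail

Do common variants explain phenotype extremes? `polytail` implements the
analysis toolkit for asking that question with tail-ascertained cohorts:
polygenic weighted allele scores, closed-form expected odds ratios for
extreme-vs-extreme allelic association under a truncated-normal model,
an ascertainment-mimicking cohort simulator with rare-variant scenarios,
replicate-based null inference on group mean scores, and a sibling
regression-to-the-mean benchmark.

It is aimed at statistical geneticists studying highly polygenic
quantitative traits (height being the canonical case) who have GWAS
summary statistics for a panel of trait-associated SNPs and genotypes for
individuals drawn from the tails of the trait distribution, and who want
to know whether those extremes are "more of the same polygenic story" or
whether something else — rare variants of larger effect, non-additive or
non-genetic factors — takes over in the far tail.

## The model

For a panel of `N` independent SNPs with per-allele effects `β_j`
(phenotype-SD units) and effect-allele frequencies `p_j`, each
individual's **weighted allele score** is

```
WAS_i = Σ_j β_j · dosage_ij − α,        α = Σ_j β_j · 2 p_j
```

so E[WAS] = 0 and, under binomial dosage sampling,
`var(WAS) = Σ_j β_j² · 2 p_j (1 − p_j)`. The purely polygenic null model
for the standardized phenotype is `Z = WAS + N(0, 1 − var(WAS))`.

**Expected tail odds ratios.** Conditioning on one allele at a SNP, the
phenotype is normal with mean `M_i = β(1 − p)` (trait-increasing allele)
or `M_d = −β p` (decreasing allele) and variance `V = 1 − β² p (1 − p)`.
The odds of seeing the increasing allele beyond an upper cutoff `c` are
`p·Φ̄((c − M_i)/√V) / [(1−p)·Φ̄((c − M_d)/√V)]`, and the expected
case/control odds ratio for a tall-vs-short design is the ratio of the
upper-tail odds to the lower-tail odds.

**Null inference on the mean score.** The null distribution of a group's
mean WAS is obtained by replaying the full ascertainment pipeline on
simulated cohorts — per-subpopulation quotas of the most extreme
individuals, or Z-score thresholds with random subsampling — and the
observed mean is evaluated two-sided against
`Normal(μ_simulation, σ²_simulation)` of the replicate means.
Rare-variant scenarios `(n, B, F)` add `n` variants of frequency `F` and
effect `B` to the generative model (with the residual variance shrunk so
`var(Z) = 1`) without changing the score definition, which is how a
deficit of polygenic signal in one tail is attributed to unmodeled
factors.

## Worked example

A synthetic cohort whose short tail secretly harbours ten rare
height-decreasing variants (B = −1 SD, F = 0.005), ascertained at
Z = ±2.14 with 385 short and 456 tall individuals from a 50,000-strong
population, tested against three candidate generative scenarios:

```python
import numpy as np
import polytail as pt

panel = pt.bundled_panel()                    # 160 SNPs, var(WAS) = 0.10
scheme = pt.default_threshold_scheme()
rng = np.random.default_rng(7)

truth = pt.RareVariantModel.uniform(10, -1.0, 0.005)
g = pt.simulate_genotypes(panel, scheme.pool_size, rng)
z = pt.simulate_zscores(g, panel, truth, rng)
cohort = pt.ascertain_threshold(g, z, scheme, rng)

table = pt.scenario_comparison(
    cohort,
    [("polygenic-only", None),
     ("10 x B=-1, F=0.005", truth),
     ("1 x B=-4, F=0.005", pt.RareVariantModel.uniform(1, -4.0, 0.005))],
    panel, scheme, n_replicates=500, rng=rng,
)
print(table[table.group == "short"])
```

which prints (formatting aside):

```
          scenario group  observed_mean_was  mu_simulation  sigma2_simulation   p_value  direction  consistent
    polygenic-only short            -0.2211        -0.2487          0.0002325   0.07011          1        True
10 x B=-1, F=0.005 short            -0.2211        -0.2205          0.0002542    0.9701         -1        True
 1 x B=-4, F=0.005 short            -0.2211        -0.1421          0.0003172 9.127e-06       -1       False
```

Reading the rows: the short group's observed mean score sits 0.028 above
the purely polygenic expectation (p = 0.07 — at this single-cohort scale
the shift is near the detection limit, which is why stratified and
larger designs matter), is squarely consistent with its true generating
scenario (p = 0.97), and firmly excludes a single 0.5%-frequency variant
of −4 SD effect, which would over-correct the short tail (p ≈ 9×10⁻⁶
in the opposite direction). The same decisions at higher power are
exercised in `tests/test_acceptance.py` with 1,000-per-tail designs.

The analytic side: a SNP with β = 0.05, p = 0.3 has an expected
tall-vs-short odds ratio of 1.306 in ±2.326 (1%) tails, and 923
individuals ascertained from the ~1%–0.25% tail bands give a variant
explaining 0.1% of trait variance the same test noncentrality as ≈5,859
randomly sampled individuals (`pt.equivalent_population_n`).

A command-line interface mirrors the library
(`polytail simulate | was | assoc | expected-or | tail-test | scenario |
sibs | demo`); every output carries the seed in its header and fixed
seeds reproduce byte-identical files.

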