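"""Synthetic polygenic cohorts with extreme-tail ascertainment.

The generative null model for a standardized phenotype is

    Z = WAS + N(0, sigma2_remaining),      sigma2_remaining = 1 - var(WAS)

with effect-allele dosages drawn independently as Binomial(2, p_j) (no LD)
and WAS the centered weighted allele score, so Z is marginally standard
normal. Rare-variant scenarios add a centered score ``sum B V - alpha_rv``
from ``n`` extra variants of frequency F and per-allele effect B, with the
residual variance shrunk so var(Z) stays 1.

Two ascertainment schemes mirror how real extreme-height cohorts were
collected: per-subpopulation quotas of the most extreme individuals
(:class:`QuotaScheme`) and Z-score thresholds followed by random
subsampling to target group sizes (:class:`ThresholdScheme`).

:class:`ScoreSampler` draws a score directly from its exact population
distribution (tabulated by convolving the per-variant three-point dosage
contributions on a fine grid). Because selection acts only on Z and the
tail statistics of interest are score means, sampling scores this way is
distributionally interchangeable with per-SNP genotype simulation and is
used by the replicate-heavy inference loops; the genotype-level simulator
below remains the reference path and the two are cross-checked in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .panel import GenotypeMatrix, SnpEffect, SnpPanel, compute_was

__all__ = [
    "NullModel",
    "RareVariantModel",
    "QuotaScheme",
    "ThresholdScheme",
    "SimulatedCohort",
    "ScoreSampler",
    "synthetic_panel",
    "default_quota_scheme",
    "default_threshold_scheme",
    "simulate_genotypes",
    "simulate_zscores",
    "ascertain_quota",
    "ascertain_threshold",
    "apply_missingness",
    "simulate_sibling_pairs",
]

SHORT, TALL, MIDDLE = "short", "tall", "middle"


# --------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class RareVariantModel:
    """Additional variants of frequency F and per-allele effect B (SD units).

    ``alpha_rv = sum 2 B F`` centers the rare score so the expected
    phenotype stays zero; the score variance ``sum B^2 2F(1-F)`` is charged
    against the residual variance.
    """

    effects: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", np.atleast_1d(np.asarray(self.effects, float)))
        object.__setattr__(self, "freqs", np.atleast_1d(np.asarray(self.freqs, float)))
        if self.effects.shape != self.freqs.shape:
            raise ValueError("effects and freqs must have equal length")
        if ((self.freqs <= 0) | (self.freqs >= 1)).any():
            raise ValueError("rare-variant frequencies must lie in (0, 1)")

    @classmethod
    def uniform(cls, n_variants: int, effect: float, freq: float) -> "RareVariantModel":
        """``n`` identical variants, e.g. ``uniform(10, -1.0, 0.005)``."""
        return cls(np.full(n_variants, effect), np.full(n_variants, freq))

    @property
    def n_variants(self) -> int:
        return self.effects.size

    @property
    def alpha_rv(self) -> float:
        return float(np.sum(2.0 * self.effects * self.freqs))

    @property
    def variance(self) -> float:
        return float(np.sum(self.effects**2 * 2.0 * self.freqs * (1.0 - self.freqs)))


@dataclass(frozen=True)
class NullModel:
    """Variance budget of the generative model: panel + optional rare term."""

    panel: SnpPanel
    rare_model: RareVariantModel | None = None

    @property
    def sigma2_remaining(self) -> float:
        rare = self.rare_model.variance if self.rare_model is not None else 0.0
        s2 = 1.0 - self.panel.was_variance - rare
        if s2 <= 0.0:
            raise ValueError(
                f"variance budget exceeded: var(WAS)={self.panel.was_variance:.4f}"
                + (f" + var(rare)={rare:.4f}" if rare else "")
                + " leaves no residual variance"
            )
        return s2


# --------------------------------------------------------------------------
# ascertainment schemes


@dataclass(frozen=True)
class QuotaScheme:
    """Per-subpopulation quotas of the most extreme individuals per tail.

    The pool is partitioned into subpopulations of the given sizes; from
    each, the ``quota_short`` lowest-Z and ``quota_tall`` highest-Z
    individuals are taken, pooled, and (optionally) randomly dropped to
    exact final group sizes. Subpopulation labels are kept as strata.
    """

    subpop_sizes: tuple[int, ...]
    quota_short: tuple[int, ...]
    quota_tall: tuple[int, ...]
    n_short_final: int | None = None
    n_tall_final: int | None = None

    def __post_init__(self) -> None:
        k = len(self.subpop_sizes)
        if len(self.quota_short) != k or len(self.quota_tall) != k:
            raise ValueError("quotas must match the number of subpopulations")
        for size, qs, qt in zip(self.subpop_sizes, self.quota_short, self.quota_tall):
            if qs + qt > size:
                raise ValueError("tail quotas exceed subpopulation size")
        if self.n_short_final is not None and self.n_short_final > sum(self.quota_short):
            raise ValueError("final short size exceeds pooled quota")
        if self.n_tall_final is not None and self.n_tall_final > sum(self.quota_tall):
            raise ValueError("final tall size exceeds pooled quota")

    @property
    def n_total(self) -> int:
        return sum(self.subpop_sizes)

    def stratum_labels(self) -> np.ndarray:
        labels = np.empty(self.n_total, dtype=object)
        start = 0
        for k, size in enumerate(self.subpop_sizes):
            labels[start : start + size] = f"subpop{k + 1}"
            start += size
        return labels

    def select(self, z: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
        if z.size != self.n_total:
            raise ValueError(f"expected {self.n_total} phenotypes, got {z.size}")
        short_idx, tall_idx = [], []
        start = 0
        for size, qs, qt in zip(self.subpop_sizes, self.quota_short, self.quota_tall):
            block = np.arange(start, start + size)
            # random jitter as secondary key = seeded random tie-break
            order = block[np.lexsort((rng.random(size), z[block]))]
            short_idx.append(order[:qs])
            tall_idx.append(order[size - qt :])
            start += size
        short = np.concatenate(short_idx)
        tall = np.concatenate(tall_idx)
        if self.n_short_final is not None:
            short = rng.choice(short, self.n_short_final, replace=False)
        if self.n_tall_final is not None:
            tall = rng.choice(tall, self.n_tall_final, replace=False)
        return {SHORT: np.sort(short), TALL: np.sort(tall)}


@dataclass(frozen=True)
class ThresholdScheme:
    """Z cutoffs per tail, then random subsampling to target group sizes.

    Optionally draws a non-extreme middle group from ``middle_band``.
    """

    pool_size: int = 50_000
    cutoff_short: float = -2.14
    cutoff_tall: float = 2.14
    n_short: int = 385
    n_tall: int = 456
    middle_band: tuple[float, float] | None = None
    n_middle: int | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cutoff_short) and np.isfinite(self.cutoff_tall)):
            raise ValueError("thresholds must be finite")
        if self.cutoff_short >= self.cutoff_tall:
            raise ValueError("cutoff_short must lie below cutoff_tall")
        if (self.n_middle is None) != (self.middle_band is None):
            raise ValueError("middle_band and n_middle must be given together")

    @property
    def n_total(self) -> int:
        return self.pool_size

    def stratum_labels(self) -> np.ndarray:
        return np.full(self.pool_size, "all", dtype=object)

    def select(self, z: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
        if z.size != self.pool_size:
            raise ValueError(f"expected {self.pool_size} phenotypes, got {z.size}")
        out: dict[str, np.ndarray] = {}
        for group, mask, target in (
            (SHORT, z < self.cutoff_short, self.n_short),
            (TALL, z > self.cutoff_tall, self.n_tall),
        ):
            avail = np.flatnonzero(mask)
            if avail.size < target:
                raise ValueError(
                    f"only {avail.size} {group} extremes beyond the cutoff, "
                    f"need {target}; increase the pool size"
                )
            out[group] = np.sort(rng.choice(avail, target, replace=False))
        if self.middle_band is not None:
            lo, hi = self.middle_band
            avail = np.flatnonzero((z > lo) & (z < hi))
            if avail.size < self.n_middle:
                raise ValueError("middle band smaller than requested middle group")
            out[MIDDLE] = np.sort(rng.choice(avail, self.n_middle, replace=False))
        return out


def default_quota_scheme() -> QuotaScheme:
    """Reference quota ascertainment: 4 subpopulations of sizes
    4271/6582/5025/7610, ~50 extremes per tail each, dropped to 181 short
    and 192 tall."""
    return QuotaScheme(
        subpop_sizes=(4271, 6582, 5025, 7610),
        quota_short=(50, 50, 50, 50),
        quota_tall=(50, 50, 50, 50),
        n_short_final=181,
        n_tall_final=192,
    )


def default_threshold_scheme(middle: bool = False) -> ThresholdScheme:
    """Reference threshold ascertainment: 50,000 individuals,
    cutoffs -2.14/+2.14, 385 short and 456 tall; optionally a 1,224-strong
    middle group with |Z| < 2."""
    return ThresholdScheme(
        pool_size=50_000,
        cutoff_short=-2.14,
        cutoff_tall=2.14,
        n_short=385,
        n_tall=456,
        middle_band=(-2.0, 2.0) if middle else None,
        n_middle=1224 if middle else None,
    )


# --------------------------------------------------------------------------
# cohort container


@dataclass
class SimulatedCohort:
    """Ascertained individuals with phenotypes and group/stratum labels.

    Either per-SNP ``dosages`` or precomputed ``was`` scores are carried;
    the replicate-heavy inference loops use score-only cohorts.
    """

    z: np.ndarray
    group: np.ndarray
    stratum: np.ndarray
    dosages: GenotypeMatrix | None = None
    was: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.z.size
        if self.group.size != n or self.stratum.size != n:
            raise ValueError("z, group and stratum must have equal length")
        if self.dosages is None and self.was is None:
            raise ValueError("cohort needs dosages or precomputed scores")

    @property
    def n_individuals(self) -> int:
        return self.z.size

    def was_scores(self, panel: SnpPanel) -> np.ndarray:
        if self.was is not None:
            return self.was
        return compute_was(self.dosages, panel).score

    def group_mean_was(self, panel: SnpPanel) -> dict[str, float]:
        scores = self.was_scores(panel)
        return {
            g: float(np.nanmean(scores[self.group == g]))
            for g in dict.fromkeys(self.group)
        }


# --------------------------------------------------------------------------
# exact score sampling


class ScoreSampler:
    """Exact sampler for a centered sum of scaled binomial dosages.

    The population distribution of ``sum_j beta_j (d_j - 2 p_j)`` with
    independent ``d_j ~ Binomial(2, p_j)`` is tabulated once by iterated
    convolution of the per-variant three-point contributions on a uniform
    grid (fractional shifts are split linearly between neighbouring cells,
    equivalent to smoothing by less than one grid step; with the default
    resolution the added variance is ~1e-9 SD^2). Draws then invert the
    tabulated CDF with within-cell jitter.
    """

    def __init__(
        self,
        effects: Sequence[float],
        freqs: Sequence[float],
        max_grid: int = 1 << 17,
        target_step: float = 1e-4,
    ):
        b = np.atleast_1d(np.asarray(effects, float))
        p = np.atleast_1d(np.asarray(freqs, float))
        if b.shape != p.shape:
            raise ValueError("effects and freqs must have equal length")
        # centered atoms per variant: beta*d - 2 beta p, d = 0,1,2
        atoms = b[:, None] * np.array([0.0, 1.0, 2.0]) - (2.0 * b * p)[:, None]
        probs = np.stack(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1
        )
        lo = atoms.min(axis=1)
        width = float((atoms.max(axis=1) - lo).sum())
        self._degenerate = width == 0.0  # all effects zero: point mass at 0
        if self._degenerate:
            width = 1.0
        size = min(max_grid, int(2 ** np.ceil(np.log2(width / target_step + 2))))
        self._step = width / (size - 2)
        pmf = np.zeros(size)
        pmf[0] = 1.0
        shifts = (atoms - lo[:, None]) / self._step  # nonnegative
        for j in range(b.size):
            nxt = np.zeros(size)
            for d in range(3):
                q = probs[j, d]
                if q == 0.0:
                    continue
                t = shifts[j, d]
                k = int(t)
                f = t - k
                nxt[k : size] += q * (1.0 - f) * pmf[: size - k]
                if f > 0.0 and k + 1 < size:
                    nxt[k + 1 :] += q * f * pmf[: size - k - 1]
            pmf = nxt
        self._origin = float(lo.sum())
        self._cdf = np.cumsum(pmf)
        self._cdf /= self._cdf[-1]
        self.mean = 0.0
        self.variance = float(np.sum(b**2 * 2.0 * p * (1.0 - p)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self._degenerate:
            return np.zeros(n)
        idx = np.searchsorted(self._cdf, rng.random(n))
        return self._origin + (idx + rng.random(n)) * self._step

    def grid_moments(self) -> tuple[float, float]:
        """Mean and variance of the tabulated distribution (diagnostics)."""
        pmf = np.diff(self._cdf, prepend=0.0)
        x = self._origin + np.arange(pmf.size) * self._step
        m = float(np.sum(pmf * x))
        v = float(np.sum(pmf * (x - m) ** 2))
        return m, v


# --------------------------------------------------------------------------
# generative operations


def simulate_genotypes(
    panel: SnpPanel, n_individuals: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Independent Binomial(2, p_j) effect-allele dosages (no LD)."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    d = rng.binomial(2, panel.freqs, size=(n_individuals, len(panel))).astype(float)
    return GenotypeMatrix(dosages=d, snp_ids=list(panel.snp_ids))


def simulate_zscores(
    dosages: GenotypeMatrix,
    panel: SnpPanel,
    rare_model: RareVariantModel | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Standardized phenotypes: WAS (+ centered rare score) + residual noise."""
    if rng is None:
        raise ValueError("an explicit rng is required")
    sigma2 = NullModel(panel, rare_model).sigma2_remaining
    n = dosages.n_individuals
    z = compute_was(dosages, panel).score.copy()
    if np.isnan(z).any():
        raise ValueError("cannot simulate phenotypes from missing dosages")
    if rare_model is not None:
        d_rv = rng.binomial(2, rare_model.freqs, size=(n, rare_model.n_variants))
        z += d_rv @ rare_model.effects - rare_model.alpha_rv
    z += rng.normal(0.0, np.sqrt(sigma2), n)
    return z


def _build_cohort(
    genotypes: GenotypeMatrix | None,
    z: np.ndarray,
    selected: dict[str, np.ndarray],
    pool_strata: np.ndarray,
    was: np.ndarray | None = None,
) -> SimulatedCohort:
    idx = np.concatenate([selected[g] for g in selected])
    group = np.concatenate(
        [np.full(selected[g].size, g, dtype=object) for g in selected]
    )
    sub = None
    if genotypes is not None:
        sub = GenotypeMatrix(
            dosages=genotypes.dosages[idx],
            snp_ids=list(genotypes.snp_ids),
            sample_ids=[f"sim{i}" for i in idx],
        )
    return SimulatedCohort(
        z=z[idx],
        group=group,
        stratum=pool_strata[idx],
        dosages=sub,
        was=None if was is None else was[idx],
    )


def ascertain_quota(
    genotypes: GenotypeMatrix,
    z: np.ndarray,
    scheme: QuotaScheme,
    rng: np.random.Generator,
) -> SimulatedCohort:
    """Per-subpopulation most-extreme selection with random drop to exact sizes."""
    selected = scheme.select(np.asarray(z, float), rng)
    return _build_cohort(genotypes, np.asarray(z, float), selected, scheme.stratum_labels())


def ascertain_threshold(
    genotypes: GenotypeMatrix,
    z: np.ndarray,
    scheme: ThresholdScheme,
    rng: np.random.Generator,
) -> SimulatedCohort:
    """Threshold selection per tail followed by random subsampling."""
    selected = scheme.select(np.asarray(z, float), rng)
    return _build_cohort(genotypes, np.asarray(z, float), selected, scheme.stratum_labels())


def apply_missingness(
    genotypes: GenotypeMatrix,
    per_snp_rates: float | Sequence[float],
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Set each dosage missing independently with its SNP's rate."""
    rates = np.broadcast_to(
        np.asarray(per_snp_rates, float), (len(genotypes.snp_ids),)
    )
    if ((rates < 0) | (rates >= 1)).any():
        raise ValueError("missing rates must lie in [0, 1)")
    d = genotypes.dosages.copy()
    d[rng.random(d.shape) < rates] = np.nan
    return GenotypeMatrix(d, list(genotypes.snp_ids), genotypes.sample_ids)


def simulate_sibling_pairs(
    n_pairs: int, sib_correlation: float, rng: np.random.Generator
) -> np.ndarray:
    """Proband/sibling standardized phenotypes from a bivariate normal.

    Returns an ``(n_pairs, 2)`` array with standard-normal marginals and
    the requested pairwise correlation.
    """
    if not -1.0 < sib_correlation < 1.0:
        raise ValueError("sibling correlation must lie in (-1, 1)")
    proband = rng.standard_normal(n_pairs)
    sibling = sib_correlation * proband + np.sqrt(
        1.0 - sib_correlation**2
    ) * rng.standard_normal(n_pairs)
    return np.column_stack([proband, sibling])


# --------------------------------------------------------------------------
# synthetic effect panel


def synthetic_panel(
    n_snps: int = 160,
    was_variance: float = 0.10,
    seed: int = 2011,
    freq_range: tuple[float, float] = (0.05, 0.95),
    discovery_n: int = 130_000,
) -> SnpPanel:
    """A GWAS-summary-style effect panel emulating a large height study.

    Frequencies are uniform on ``freq_range``; signed effects are normal
    and rescaled so the score variance is exactly ``was_variance``
    (default 0.10, i.e. the panel explains 10% of trait variance). SEs
    mimic a quantitative-trait discovery study of ``discovery_n`` samples,
    ``se ~ 1/sqrt(2 p (1-p) N)``.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, n_snps)
    betas = rng.normal(0.0, 1.0, n_snps)
    raw_var = np.sum(betas**2 * 2.0 * freqs * (1.0 - freqs))
    betas *= np.sqrt(was_variance / raw_var)
    ses = 1.0 / np.sqrt(2.0 * freqs * (1.0 - freqs) * discovery_n)
    pairs = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    picks = rng.integers(0, 4, n_snps)
    width = len(str(n_snps))
    return SnpPanel(
        SnpEffect(
            snp_id=f"snp{i + 1:0{width}d}",
            effect_allele=pairs[picks[i]][0],
            other_allele=pairs[picks[i]][1],
            beta=float(betas[i]),
            se_beta=float(ses[i]),
            effect_allele_freq=float(freqs[i]),
        )
        for i in range(n_snps)
    )
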