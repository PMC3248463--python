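"""SNP effect panels and the weighted allele score (WAS).

The weighted allele score is a per-individual genetic prediction of a
standardized phenotype: the sum of effect-allele dosages weighted by
per-SD-unit effect sizes, centered so its population expectation is zero
when dosages are drawn at the panel's allele frequencies:

    WAS_i = sum_j beta_j * dosage_ij - alpha,   alpha = sum_j beta_j * 2 p_j

Under Hardy-Weinberg dosage sampling (Binomial(2, p_j), independent SNPs)
the score has variance sum_j beta_j^2 * 2 p_j (1 - p_j).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpEffect",
    "SnpPanel",
    "GenotypeMatrix",
    "WasResult",
    "compute_alpha",
    "compute_was",
    "compute_was_variance",
    "inverse_normal_transform",
]


@dataclass(frozen=True)
class SnpEffect:
    """One SNP's published association summary.

    Parameters
    ----------
    snp_id : identifier, e.g. an rs number.
    effect_allele : allele whose dosage (0/1/2) multiplies ``beta``.
    other_allele : the non-effect allele.
    beta : effect size in phenotype-SD units per effect allele (signed).
    se_beta : standard error of ``beta``, SD units.
    effect_allele_freq : population frequency of the effect allele, in (0, 1).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se_beta: float
    effect_allele_freq: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be nonempty")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise ValueError(
                f"{self.snp_id}: effect_allele_freq must lie in (0, 1), "
                f"got {self.effect_allele_freq}"
            )
        if self.se_beta < 0:
            raise ValueError(f"{self.snp_id}: se_beta must be >= 0")


class SnpPanel:
    """Ordered collection of :class:`SnpEffect` with vectorized accessors.

    The panel's score variance ``sum beta^2 * 2p(1-p)`` must be < 1 so a
    nonnegative residual variance exists for a standardized phenotype.
    """

    def __init__(self, effects: Iterable[SnpEffect]):
        self.effects: tuple[SnpEffect, ...] = tuple(effects)
        if not self.effects:
            raise ValueError("panel must contain at least one SNP")
        ids = [e.snp_id for e in self.effects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_ids in panel: {dupes}")
        self.snp_ids: list[str] = ids
        self.betas = np.array([e.beta for e in self.effects], dtype=float)
        self.freqs = np.array([e.effect_allele_freq for e in self.effects], dtype=float)
        self.ses = np.array([e.se_beta for e in self.effects], dtype=float)
        if self.was_variance >= 1.0:
            raise ValueError(
                f"panel score variance {self.was_variance:.4f} >= 1: "
                "no admissible residual variance"
            )

    def __len__(self) -> int:
        return len(self.effects)

    def __iter__(self) -> Iterator[SnpEffect]:
        return iter(self.effects)

    @property
    def alpha(self) -> float:
        """Centering constant ``sum_j beta_j * 2 p_j`` (SD units)."""
        return float(np.sum(self.betas * 2.0 * self.freqs))

    @property
    def was_variance(self) -> float:
        """Population score variance ``sum_j beta_j^2 * 2 p_j (1-p_j)``."""
        return float(np.sum(self.betas**2 * 2.0 * self.freqs * (1.0 - self.freqs)))

    def with_frequencies(self, freqs: Sequence[float]) -> "SnpPanel":
        """Same effects re-keyed to another cohort's allele frequencies."""
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (len(self),):
            raise ValueError("frequency vector length does not match panel")
        return SnpPanel(
            SnpEffect(e.snp_id, e.effect_allele, e.other_allele, e.beta, e.se_beta, f)
            for e, f in zip(self.effects, freqs)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "effect_allele": [e.effect_allele for e in self.effects],
                "other_allele": [e.other_allele for e in self.effects],
                "eaf": self.freqs,
                "beta": self.betas,
                "se": self.ses,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpPanel":
        return cls(
            SnpEffect(
                str(r.snp_id),
                str(r.effect_allele),
                str(r.other_allele),
                float(r.beta),
                float(r.se),
                float(r.eaf),
            )
            for r in df.itertuples(index=False)
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosages, NaN marking missing calls.

    Column order must match the panel the matrix is aligned to; dosages are
    restricted to {0, 1, 2, NaN}.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("column count does not match snp_ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def missing_rates(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class WasResult:
    """Per-individual weighted allele scores.

    ``score`` is NaN for individuals with no genotyped panel SNP (also
    listed in ``all_missing``); ``n_snps_used`` counts non-missing SNPs.
    """

    score: np.ndarray
    n_snps_used: np.ndarray

    @property
    def all_missing(self) -> np.ndarray:
        return np.flatnonzero(self.n_snps_used == 0)


def compute_alpha(panel: SnpPanel) -> float:
    """Centering constant making the expected population score zero."""
    return panel.alpha


def compute_was_variance(panel: SnpPanel) -> float:
    """Score variance under binomial dosage sampling at panel frequencies."""
    v = panel.was_variance
    if v >= 1.0:
        raise ValueError("score variance >= 1: no admissible residual variance")
    return v


def compute_was(genotypes: GenotypeMatrix, panel: SnpPanel) -> WasResult:
    """Weighted allele score for each individual.

    Missing dosages are dropped and the centering constant is restricted,
    per individual, to that individual's non-missing SNPs, so the score's
    expectation stays zero under any missingness pattern independent of
    genotype.
    """
    if genotypes.snp_ids != panel.snp_ids:
        raise ValueError("genotype matrix is not aligned to the panel")
    d = genotypes.dosages
    observed = np.isfinite(d)
    weighted = np.where(observed, d, 0.0) @ panel.betas
    center = observed @ (panel.betas * 2.0 * panel.freqs)
    score = weighted - center
    n_used = observed.sum(axis=1)
    score = np.where(n_used > 0, score, np.nan)
    return WasResult(score=score, n_snps_used=n_used)


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offsets, average-rank ties).

    Maps values to standard-normal quantiles at fractional positions
    ``(rank - 3/8) / (n + 1/4)``; monotone in the input, mean ~0, var ~1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D array of at least two values")
    if np.unique(x).size < 2:
        raise ValueError("constant input cannot be rank-transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
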