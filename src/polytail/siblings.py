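"""Regression to the mean in siblings of phenotype-extreme probands.

Under an additive polygenic model, proband and sibling standardized
phenotypes are bivariate normal with correlation r, so siblings of
probands beyond a tail cutoff c have expected phenotype

    E[Z_sib | Z_pro > c] = r * E[Z | Z > c] = r * phi(c) / Phi(-c)

(with the sign flipped for the lower tail). Equal-magnitude regression in
the two tails is therefore the additive-model benchmark; differential
regression signals that something beyond the symmetric additive model
(rare non-additive variants, de novo events, environment) acts in one tail.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SibPairSet",
    "sibling_mean_z",
    "tail_regression_test",
    "expected_sib_mean_additive",
]


class SibPairSet:
    """Proband/sibling standardized phenotype pairs.

    Accepts an ``(n, 2)`` array (proband first column) such as the output
    of :func:`polytail.simulate.simulate_sibling_pairs`. Families
    contributing several siblings should be averaged to one pair upstream
    to keep pairs independent.
    """

    def __init__(self, pairs: np.ndarray):
        pairs = np.asarray(pairs, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        if not np.isfinite(pairs).all():
            raise ValueError("each pair needs both phenotypes")
        self.proband = pairs[:, 0]
        self.sibling = pairs[:, 1]

    def __len__(self) -> int:
        return self.proband.size

    def tail_siblings(self, tail: str, cutoff: float) -> np.ndarray:
        """Sibling phenotypes for probands beyond the tail cutoff."""
        if tail == "short":
            mask = self.proband < -abs(cutoff)
        elif tail == "tall":
            mask = self.proband > abs(cutoff)
        else:
            raise ValueError("tail must be 'short' or 'tall'")
        return self.sibling[mask]


def sibling_mean_z(
    pairs: SibPairSet, tail: str, cutoff: float
) -> tuple[float, tuple[float, float]]:
    """Mean sibling phenotype for tail probands, with a normal 95% CI."""
    sibs = pairs.tail_siblings(tail, cutoff)
    if sibs.size < 2:
        raise ValueError(f"fewer than two probands in the {tail} tail")
    mean = float(sibs.mean())
    half = 1.96 * sibs.std(ddof=1) / np.sqrt(sibs.size)
    return mean, (mean - half, mean + half)


def tail_regression_test(
    short_sib_z: Sequence[float], tall_sib_z: Sequence[float]
) -> tuple[float, float]:
    """Welch t-test for differential regression to the mean between tails.

    Short-tail sibling phenotypes are sign-reversed so that, under a
    symmetric model, both groups share the same positive expectation;
    returns ``(t, two-sided p)`` for tall vs reversed-short.
    """
    short = -np.asarray(short_sib_z, dtype=float)
    tall = np.asarray(tall_sib_z, dtype=float)
    if short.size < 2 or tall.size < 2:
        raise ValueError("both tails need at least two sibling phenotypes")
    res = stats.ttest_ind(tall, short, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def expected_sib_mean_additive(r: float, cutoff: float, tail: str) -> float:
    """Additive-model expected sibling mean for tail probands."""
    if not -1.0 < r < 1.0:
        raise ValueError("sibling correlation must lie in (-1, 1)")
    c = abs(cutoff)
    trunc = stats.norm.pdf(c) / stats.norm.sf(c)  # E[Z | Z > c]
    if tail == "tall":
        return float(r * trunc)
    if tail == "short":
        return float(-r * trunc)
    raise ValueError("tail must be 'short' or 'tall'")
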