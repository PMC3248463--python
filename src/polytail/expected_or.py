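"""Expected allelic odds ratios between phenotype tails under a polygenic
normal model, and related analytic tools.

For a biallelic SNP with trait-increasing effect ``beta`` (SD per allele)
and increasing-allele frequency ``p``, take a standardized phenotype
Z ~ N(0, 1) generated additively from binomial dosages. Conditioning on a
randomly chosen allele being the increasing (resp. decreasing) one gives

    M_i = beta * (1 - p),   M_d = -beta * p,   V = 1 - beta^2 p (1 - p),

a two-component normal mixture with mean zero (``p*M_i + (1-p)*M_d = 0``).
The odds of observing the increasing allele in an upper tail Z > c are
``p * S((c - M_i)/sqrt(V)) / [(1-p) * S((c - M_d)/sqrt(V))]`` with S the
normal survival function, and analogously with the CDF in a lower tail.
The expected case/control odds ratio for a tall-vs-short extreme design is
the ratio of the upper-tail odds to the lower-tail odds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "TailDesign",
    "AlleleHeightModel",
    "ExpectedOrResult",
    "allele_height_moments",
    "tail_allele_odds",
    "expected_odds_ratio",
    "observed_vs_expected_ztest",
    "expected_direction",
    "equivalent_population_n",
]


@dataclass(frozen=True)
class TailDesign:
    """Z-score cutoffs defining the case (upper) and control (lower) tails.

    ``case_outer`` / ``control_outer`` optionally bound the tails away from
    the distribution's end, giving band-limited extremes (e.g. the ~1% to
    0.25% band used in power-equivalence calculations).
    """

    case_cutoff: float = 2.326
    control_cutoff: float = -2.326
    case_outer: float | None = None
    control_outer: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.case_cutoff) and np.isfinite(self.control_cutoff)):
            raise ValueError("tail cutoffs must be finite")
        if self.case_cutoff <= self.control_cutoff:
            raise ValueError("case_cutoff must exceed control_cutoff")
        if self.case_outer is not None and self.case_outer <= self.case_cutoff:
            raise ValueError("case_outer must exceed case_cutoff")
        if self.control_outer is not None and self.control_outer >= self.control_cutoff:
            raise ValueError("control_outer must lie below control_cutoff")


@dataclass(frozen=True)
class AlleleHeightModel:
    """Conditional phenotype moments given the allele drawn at one SNP.

    ``m_increasing`` / ``m_decreasing`` are the mean standardized phenotypes
    of carriers of one trait-increasing / trait-decreasing allele; ``v`` is
    the common conditional variance. Weighted by allele frequency the
    mixture mean is zero.
    """

    m_increasing: float
    m_decreasing: float
    v: float


@dataclass(frozen=True)
class ExpectedOrResult:
    """Model-expected odds ratio with approximate log-scale SE."""

    or_expected: float
    se_log_expected: float
    odds_cases: float
    odds_controls: float


def allele_height_moments(beta: float, freq: float) -> AlleleHeightModel:
    """Per-allele conditional phenotype moments for one SNP.

    ``beta`` must be oriented so positive means trait-increasing, ``freq``
    is the increasing-allele frequency.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError("freq must lie in (0, 1)")
    var_term = beta**2 * freq * (1.0 - freq)
    if var_term >= 1.0:
        raise ValueError("beta^2 p (1-p) >= 1: conditional variance not positive")
    return AlleleHeightModel(
        m_increasing=beta * (1.0 - freq),
        m_decreasing=-beta * freq,
        v=1.0 - var_term,
    )


def tail_allele_odds(
    model: AlleleHeightModel, freq: float, cutoff: float, tail: str
) -> float:
    """Odds of the increasing vs decreasing allele within one phenotype tail.

    ``tail`` is ``"upper"`` (Z > cutoff) or ``"lower"`` (Z < cutoff); tail
    probabilities come from the per-allele conditional normals.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError("freq must lie in (0, 1)")
    s = np.sqrt(model.v)
    if tail == "upper":
        p_inc = norm.sf((cutoff - model.m_increasing) / s)
        p_dec = norm.sf((cutoff - model.m_decreasing) / s)
    elif tail == "lower":
        p_inc = norm.cdf((cutoff - model.m_increasing) / s)
        p_dec = norm.cdf((cutoff - model.m_decreasing) / s)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    if p_inc <= 0.0 or p_dec <= 0.0:
        raise FloatingPointError(
            f"tail probability underflow at cutoff {cutoff} (tail={tail}); "
            "move the cutoff toward the bulk of the distribution"
        )
    return float(freq * p_inc / ((1.0 - freq) * p_dec))


def _or_at(beta: float, freq: float, design: TailDesign) -> float:
    model = allele_height_moments(beta, freq)
    odds_cases = tail_allele_odds(model, freq, design.case_cutoff, "upper")
    odds_controls = tail_allele_odds(model, freq, design.control_cutoff, "lower")
    return odds_cases / odds_controls


def expected_odds_ratio(
    beta: float, se_beta: float, freq: float, design: TailDesign
) -> ExpectedOrResult:
    """Model-expected tall-vs-short allelic odds ratio for one SNP.

    The approximate SE of the log expected OR propagates the discovery
    study's effect-size uncertainty: the ORs at ``beta +/- 1.96 se`` give
    95% limits whose log-range spans ``2 * 1.96`` standard errors.
    """
    if se_beta < 0:
        raise ValueError("se_beta must be >= 0")
    model = allele_height_moments(beta, freq)
    odds_cases = tail_allele_odds(model, freq, design.case_cutoff, "upper")
    odds_controls = tail_allele_odds(model, freq, design.control_cutoff, "lower")
    or_expected = odds_cases / odds_controls
    if se_beta == 0.0:
        se_log = 0.0
    else:
        hi = _or_at(beta + 1.96 * se_beta, freq, design)
        lo = _or_at(beta - 1.96 * se_beta, freq, design)
        se_log = (np.log(hi) - np.log(lo)) / (2.0 * 1.96)
    return ExpectedOrResult(
        or_expected=float(or_expected),
        se_log_expected=float(se_log),
        odds_cases=float(odds_cases),
        odds_controls=float(odds_controls),
    )


def observed_vs_expected_ztest(
    or_obs: float, se_log_obs: float, expected: ExpectedOrResult
) -> tuple[float, float]:
    """Z-test of an observed OR against its model expectation.

    Log-scale SEs of the observed and expected ORs combine in quadrature.
    Returns ``(z, two-sided p)``.
    """
    if or_obs <= 0 or expected.or_expected <= 0:
        raise ValueError("odds ratios must be positive")
    if se_log_obs < 0 or expected.se_log_expected < 0:
        raise ValueError("standard errors must be >= 0")
    denom = np.hypot(se_log_obs, expected.se_log_expected)
    if denom == 0.0:
        raise ValueError("both standard errors are zero")
    z = (np.log(or_obs) - np.log(expected.or_expected)) / denom
    return float(z), float(2.0 * norm.sf(abs(z)))


def expected_direction(beta: float) -> int:
    """Sign of the published effect; zero effects are excluded upstream."""
    if beta == 0:
        raise ValueError("direction undefined for beta = 0")
    return 1 if beta > 0 else -1


def _band_mean(lo: float, hi: float) -> float:
    """Mean of a standard normal truncated to (lo, hi)."""
    mass = norm.cdf(hi) - norm.cdf(lo)
    if mass <= 0:
        raise ValueError("empty tail band")
    return float((norm.pdf(lo) - norm.pdf(hi)) / mass)


def equivalent_population_n(
    design: TailDesign,
    n_short: int,
    n_tall: int,
    variance_explained: float,
    freq: float = 0.3,
) -> float:
    """Random-population sample size matching the power of a tail design.

    For a variant explaining ``variance_explained`` of trait variance
    (``2 p (1-p) beta^2``), the allele-frequency contrast between groups
    drawn from symmetric Z bands has noncentrality

        NCP = [2 beta p (1-p) m]^2 / [p (1-p) (1/(2 n_short) + 1/(2 n_tall))]

    where ``m`` is the truncated-normal mean of the upper band; the
    frequency shift per tail is ``beta p (1-p) m``. A quantitative-trait
    test on N random individuals has NCP = N * variance_explained, so the
    equivalent N is ``NCP / variance_explained``.
    """
    if n_short <= 0 or n_tall <= 0:
        raise ValueError("group sizes must be positive")
    if not 0.0 < variance_explained < 2.0 * freq * (1.0 - freq):
        raise ValueError("variance_explained outside the admissible range")
    if design.case_outer is None or design.control_outer is None:
        raise ValueError("design must specify band limits (case_outer/control_outer)")
    m_upper = _band_mean(design.case_cutoff, design.case_outer)
    m_lower = _band_mean(design.control_outer, design.control_cutoff)
    beta = np.sqrt(variance_explained / (2.0 * freq * (1.0 - freq)))
    pq = freq * (1.0 - freq)
    freq_contrast = beta * pq * (m_upper - m_lower)
    contrast_var = pq * (1.0 / (2.0 * n_short) + 1.0 / (2.0 * n_tall))
    ncp = freq_contrast**2 / contrast_var
    return float(ncp / variance_explained)
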