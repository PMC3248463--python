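"""Observed per-SNP association in extreme-vs-extreme designs.

Tall-tail individuals are treated as cases and short-tail individuals as
controls; association is at the allele level (each individual contributes
two alleles). Stratified designs use the Cochran-Mantel-Haenszel common
odds ratio with the Robins-Breslow-Greenland log-OR variance; unstratified
designs can alternatively use per-allele logistic regression on dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "StratifiedAlleleTables",
    "AssocResult",
    "allele_tables",
    "cmh_test",
    "logistic_assoc",
    "inverse_variance_meta",
    "direction_consistency_test",
    "nominal_enrichment_test",
]

TALL, SHORT = "tall", "short"


@dataclass
class StratifiedAlleleTables:
    """Per-stratum 2x2 allele-count tables.

    ``tables[k]`` is ``[[tall effect, tall other], [short effect, short
    other]]`` for stratum k; counts are allele counts (2 per genotyped
    individual).
    """

    tables: np.ndarray
    strata: list[str]

    def __post_init__(self) -> None:
        self.tables = np.asarray(self.tables, dtype=float)
        if self.tables.ndim != 3 or self.tables.shape[1:] != (2, 2):
            raise ValueError("tables must have shape (n_strata, 2, 2)")
        if (self.tables < 0).any():
            raise ValueError("allele counts must be nonnegative")


@dataclass
class AssocResult:
    """One SNP's observed association summary."""

    or_observed: float
    se_log_obs: float
    p_value: float
    direction: int
    method: str = ""
    note: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.exp(np.log(self.or_observed) - 1.96 * self.se_log_obs)
        hi = np.exp(np.log(self.or_observed) + 1.96 * self.se_log_obs)
        return float(lo), float(hi)


def allele_tables(
    dosages: Sequence[float],
    groups: Sequence[str],
    strata: Sequence[str] | None = None,
) -> StratifiedAlleleTables:
    """Count effect/other alleles by group within each stratum for one SNP.

    ``dosages`` is the SNP's effect-allele dosage per individual (NaN
    missing); ``groups`` must contain only ``"tall"`` and ``"short"``.
    Strata missing either group are dropped with a warning.
    """
    d = np.asarray(dosages, dtype=float)
    g = np.asarray(groups, dtype=object)
    if d.shape != g.shape:
        raise ValueError("dosages and groups must have equal length")
    extra = set(g) - {TALL, SHORT}
    if extra:
        raise ValueError(f"groups must be exactly tall/short, found {sorted(extra)}")
    s = np.asarray(["all"] * d.size if strata is None else strata, dtype=object)
    ok = np.isfinite(d)
    if not ok.any():
        raise ValueError("all dosages are missing")
    tables, kept = [], []
    for label in dict.fromkeys(s):  # first-appearance order
        m = (s == label) & ok
        tall, short = m & (g == TALL), m & (g == SHORT)
        if not tall.any() or not short.any():
            warnings.warn(
                f"stratum {label!r} lacks one group and was dropped", stacklevel=2
            )
            continue
        eff_t, n_t = d[tall].sum(), tall.sum()
        eff_s, n_s = d[short].sum(), short.sum()
        tables.append([[eff_t, 2 * n_t - eff_t], [eff_s, 2 * n_s - eff_s]])
        kept.append(str(label))
    if not tables:
        raise ValueError("no stratum retained both groups")
    return StratifiedAlleleTables(tables=np.asarray(tables, float), strata=kept)


def cmh_test(tables: StratifiedAlleleTables) -> AssocResult:
    """Cochran-Mantel-Haenszel common odds ratio across strata.

    Uses the Mantel-Haenszel pooled OR, the Robins-Breslow-Greenland
    log-scale SE and the 1-df chi-square test without continuity
    correction. Strata containing a zero cell get a Haldane-Anscombe 0.5
    added to every cell (noted in the result).
    """
    t = tables.tables.copy()
    degenerate = [(row.sum(1) == 0).any() or (row.sum(0) == 0).any() for row in t]
    if all(degenerate):
        raise ValueError("all strata have an empty margin")
    t = t[~np.asarray(degenerate)]
    note = ""
    zero = (t == 0).any(axis=(1, 2))
    if zero.any():
        t[zero] += 0.5
        note = f"haldane-anscombe correction in {int(zero.sum())} stratum/strata"
    st = StratifiedTable(np.moveaxis(t, 0, -1))
    or_mh = float(st.oddsratio_pooled)
    se = float(st.logodds_pooled_se)
    p = float(st.test_null_odds(correction=False).pvalue)
    direction = 0 if or_mh == 1.0 else (1 if or_mh > 1.0 else -1)
    return AssocResult(or_mh, se, p, direction, method="cmh", note=note)


def logistic_assoc(
    dosages: Sequence[float], case_status: Sequence[int]
) -> AssocResult:
    """Per-allele OR from logistic regression of case status on dosage.

    ``case_status`` is 1 for tall-tail (case), 0 for short-tail (control);
    missing dosages are dropped. Complete separation is flagged as an
    error rather than returning a divergent estimate.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(case_status, dtype=float)
    ok = np.isfinite(d)
    d, y = d[ok], y[ok]
    if np.unique(y).size < 2:
        raise ValueError("both case and control statuses are required")
    if np.var(d) == 0:
        raise ValueError("dosage has zero variance")
    x = sm.add_constant(d)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(tol=1e-8)
    except PerfectSeparationError as exc:
        raise ValueError("complete separation: no finite estimate") from exc
    slope, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(se) or abs(slope) > 15:
        raise ValueError("complete separation: no finite estimate")
    z = slope / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = 0 if slope == 0 else (1 if slope > 0 else -1)
    return AssocResult(float(np.exp(slope)), se, p, direction, method="logistic")


def inverse_variance_meta(results: Sequence[AssocResult]) -> AssocResult:
    """Fixed-effect inverse-variance meta-analysis of log odds ratios."""
    if not results:
        raise ValueError("no results to meta-analyze")
    log_or = np.array([np.log(r.or_observed) for r in results])
    se = np.array([r.se_log_obs for r in results])
    if (se <= 0).any() or not np.isfinite(se).all():
        raise ValueError("all studies need finite positive SEs")
    w = 1.0 / se**2
    pooled = float(np.sum(w * log_or) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = 0 if pooled == 0 else (1 if pooled > 0 else -1)
    return AssocResult(float(np.exp(pooled)), pooled_se, p, direction, method="meta")


def direction_consistency_test(
    observed_signs: Sequence[int], expected_signs: Sequence[int]
) -> tuple[int, int, float]:
    """Exact binomial test that effect directions match published signs.

    Returns ``(k matches, n, one-sided p)`` under the null of coin-flip
    agreement; pairs with a zero expected sign are excluded.
    """
    obs = np.asarray(observed_signs, dtype=int)
    exp = np.asarray(expected_signs, dtype=int)
    if obs.shape != exp.shape:
        raise ValueError("sign vectors must have equal length")
    keep = (exp != 0) & (obs != 0)
    obs, exp = obs[keep], exp[keep]
    n = obs.size
    if n == 0:
        raise ValueError("no sign pairs to compare")
    k = int((obs == exp).sum())
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return k, n, float(p)


def nominal_enrichment_test(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[int, float, float]:
    """Excess of nominally significant tests over the chance expectation.

    ``p_values`` should already be filtered to the direction-consistent
    set when enrichment-in-the-expected-direction is the quantity of
    interest (the filter is the caller's, deliberately explicit).
    Returns ``(observed count, expected count, exact binomial tail p)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    observed = int((p < alpha).sum())
    expected = float(p.size * alpha)
    tail = stats.binomtest(observed, p.size, alpha, alternative="greater").pvalue
    return observed, expected, float(tail)
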