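"""Hybrid significance framework for differential deuterium uptake.

A peptide/timepoint cell is called significantly different between two
protein states only if it passes BOTH tests:

1. a per-peptide Welch's t-test on the replicate uptake values (p < alpha),
   which tolerates unequal replicate counts and unequal variances, and
2. a dataset-wide *critical interval* on the uptake difference: |dD| must
   exceed a threshold derived from the replicate variance pooled over every
   peptide and timepoint of the comparison.

The conjunction guards against both flukes of tiny per-peptide variance
(caught by the global interval) and large-but-noisy differences (caught by
the t-test); no additional multiple-testing correction is applied — the
critical interval is the framework's guard against multiplicity.

All testing operates on uptake in Daltons; percent deuteration is used for
display only.  The difference sign convention is test - reference, so
positive dD means more exchange (deprotection) in the test state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats as sps

from .matching import MatchedTable, PeptideKey

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    zero_variance: bool = False


@dataclass(frozen=True)
class GlobalCriticalInterval:
    """Comparison-wide |dD| threshold at confidence ``alpha``.

    ``sd_pooled_*`` are the square roots of the mean per-cell replicate
    variance over all (peptide, timepoint) cells of each state.
    """

    comparison: tuple[str, str]
    alpha: float
    sd_pooled_ref: float
    sd_pooled_test: float
    n_ref: int
    n_test: int
    ci_da: float


@dataclass(frozen=True)
class ComparisonResult:
    """Differential statistics for one peptide at one timepoint."""

    peptide: PeptideKey
    comparison: tuple[str, str]
    timepoint_s: float
    mean_ref: float
    mean_test: float
    delta_d: float
    sd_ref: float
    sd_test: float
    n_ref: int
    n_test: int
    t_stat: float
    df: float
    p_value: float
    ci_da: float
    significant: bool


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch's unequal-variance t-test from summary statistics.

    t = (mean2 - mean1) / sqrt(sd1^2/n1 + sd2^2/n2), with the
    Welch–Satterthwaite degrees of freedom and a two-sided p-value from the
    t distribution.  When both SDs are zero the test is undefined; by
    convention p = 1 if the means are equal and p = 0 otherwise, flagged via
    ``zero_variance``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch's test needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1 = sd1 * sd1 / n1
    v2 = sd2 * sd2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        warnings.warn("zero variance in both groups; p set by convention")
        if mean1 == mean2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, True)
        t = math.copysign(math.inf, mean2 - mean1)
        return WelchResult(t, float(n1 + n2 - 2), 0.0, True)
    t = (mean2 - mean1) / math.sqrt(se2)
    df = se2 * se2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t, df, min(p, 1.0), False)


def _pooled_sd(table: MatchedTable, state: str) -> tuple[float, int]:
    """sqrt(mean per-cell replicate variance) over cells with n >= 2."""
    variances = []
    for key in table.peptides:
        for tp in table.timepoints_s:
            vals = table.uptake_values(key, state, tp)
            if len(vals) >= 2:
                variances.append(float(np.var(vals, ddof=1)))
    if not variances:
        raise ValueError(
            f"state {state!r}: no cells with >= 2 replicates; "
            "cannot pool variance"
        )
    return math.sqrt(float(np.mean(variances))), len(variances)


def critical_interval(
    table: MatchedTable,
    comparison: tuple[str, str],
    alpha: float = DEFAULT_ALPHA,
) -> GlobalCriticalInterval:
    """Global uptake-difference threshold for one state pair.

    Per-cell replicate variances are averaged over all peptides and
    timepoints of each state, propagated to the standard error of a mean
    difference, and scaled by the two-sided t quantile at
    df = n_ref + n_test - 2.
    """
    ref, test = comparison
    sd_ref, _ = _pooled_sd(table, ref)
    sd_test, _ = _pooled_sd(table, test)
    n_ref = table.n_replicates[ref]
    n_test = table.n_replicates[test]
    if n_ref < 2 or n_test < 2:
        raise ValueError("critical interval needs >= 2 replicates per state")
    df_pool = n_ref + n_test - 2
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df_pool))
    ci = t_crit * math.sqrt(sd_ref**2 / n_ref + sd_test**2 / n_test)
    return GlobalCriticalInterval(
        comparison=comparison,
        alpha=alpha,
        sd_pooled_ref=sd_ref,
        sd_pooled_test=sd_test,
        n_ref=n_ref,
        n_test=n_test,
        ci_da=ci,
    )


def compare_states(
    table: MatchedTable, alpha: float = DEFAULT_ALPHA
) -> tuple[list[ComparisonResult], dict[tuple[str, str], GlobalCriticalInterval]]:
    """Run the hybrid test for every non-reference state against the reference.

    Returns one :class:`ComparisonResult` per (comparison, matched peptide,
    timepoint) — cells with fewer than two replicates in either state are
    excluded from testing — plus the per-comparison critical intervals.
    """
    if len(table.states) < 2:
        raise ValueError("need at least two states to compare")
    results: list[ComparisonResult] = []
    intervals: dict[tuple[str, str], GlobalCriticalInterval] = {}
    for comparison in table.comparisons():
        ref, test = comparison
        gci = critical_interval(table, comparison, alpha)
        intervals[comparison] = gci
        for key in table.peptides:
            for tp in table.timepoints_s:
                a = table.uptake_values(key, ref, tp)
                b = table.uptake_values(key, test, tp)
                if len(a) < 2 or len(b) < 2:
                    continue
                m1, m2 = float(np.mean(a)), float(np.mean(b))
                s1 = float(np.std(a, ddof=1))
                s2 = float(np.std(b, ddof=1))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    w = welch_t(m1, s1, len(a), m2, s2, len(b))
                delta = m2 - m1
                sig = (w.p_value < alpha) and (abs(delta) > gci.ci_da)
                results.append(
                    ComparisonResult(
                        peptide=key,
                        comparison=comparison,
                        timepoint_s=tp,
                        mean_ref=m1,
                        mean_test=m2,
                        delta_d=delta,
                        sd_ref=s1,
                        sd_test=s2,
                        n_ref=len(a),
                        n_test=len(b),
                        t_stat=w.t_stat,
                        df=w.df,
                        p_value=w.p_value,
                        ci_da=gci.ci_da,
                        significant=sig,
                    )
                )
    return results, intervals


def significant_any_timepoint(
    results: Iterable[ComparisonResult],
) -> dict[tuple[str, str], set[PeptideKey]]:
    """Peptides significant at >= 1 timepoint, grouped by comparison."""
    out: dict[tuple[str, str], set[PeptideKey]] = {}
    for r in results:
        out.setdefault(r.comparison, set())
        if r.significant:
            out[r.comparison].add(r.peptide)
    return out
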