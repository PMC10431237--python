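"""Group comparisons and derived summary quantities.

Implements the comparison battery used throughout the pipeline: a
Shapiro-Wilk normality gate feeding two-tailed t tests (Welch-corrected
when an F test finds unequal variances) or the Mann-Whitney U test for
non-normal unpaired data, with optional Bonferroni adjustment, plus
percent-change summaries.  Standard tests are delegated to
scipy/statsmodels; the bespoke content here is the gating logic and
bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

__all__ = ["percent_change", "GroupComparison", "compare_groups",
           "repeated_measures_anova"]


def percent_change(reference: float, comparison: float,
                   rounded: bool = False) -> float:
    """Percent reduction of ``comparison`` relative to ``reference``:
    100 (reference - comparison) / reference.

    Not symmetric — always name the reference group when reporting.
    With ``rounded=True`` the value is rounded half away from zero to
    an integer percent, the convention used for reported reductions.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    pct = 100.0 * (reference - comparison) / reference
    if rounded:
        return float(math.floor(abs(pct) + 0.5) * (1 if pct >= 0 else -1))
    return pct


@dataclass
class GroupComparison:
    """Outcome of one two-group comparison."""

    test: str                 # paired_t | unpaired_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    effect: float             # mean(a) - mean(b)
    ci95: Tuple[float, float]
    n_per_group: Tuple[int, int]
    alpha_adjusted: float
    significant: bool
    normality_p: Tuple[float, float]   # Shapiro-Wilk p per group (NaN if skipped)
    welch_gate_p: float = float("nan")  # F-test p for variance equality
    degenerate: bool = False


def _shapiro_p(x: np.ndarray) -> float:
    if x.size < 3 or np.ptp(x) == 0:
        return np.nan
    return float(sstats.shapiro(x).pvalue)


def _variance_ratio_p(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return np.nan
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(sstats.f.cdf(f, dfa, dfb), sstats.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def _mean_diff_ci(a, b, paired, welch):
    if paired:
        d = a - b
        se = d.std(ddof=1) / np.sqrt(d.size)
        df = d.size - 1
        m = d.mean()
    else:
        m = a.mean() - b.mean()
        if welch:
            sa2, sb2 = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            se = np.sqrt(sa2 + sb2)
            df = ((sa2 + sb2) ** 2
                  / (sa2 ** 2 / (a.size - 1) + sb2 ** 2 / (b.size - 1))
                  if se > 0 else 1)
        else:
            df = a.size + b.size - 2
            sp = np.sqrt(((a.size - 1) * a.var(ddof=1)
                          + (b.size - 1) * b.var(ddof=1)) / df)
            se = sp * np.sqrt(1 / a.size + 1 / b.size)
    if se == 0 or df <= 0:
        return float(m), (float(m), float(m))
    tcrit = sstats.t.ppf(0.975, df)
    return float(m), (float(m - tcrit * se), float(m + tcrit * se))


def compare_groups(a: Sequence[float], b: Sequence[float],
                   paired: bool = False, alpha: float = 0.05,
                   bonferroni_divisor: int = 1) -> GroupComparison:
    """Two-tailed comparison of two samples with a normality gate.

    Unpaired data: if either group fails Shapiro-Wilk (p < 0.05), the
    Mann-Whitney U test is used; otherwise a t test, Welch-corrected
    when a variance-ratio F test rejects equal variances at 0.05.
    Paired data always use the paired t test.  Significance is judged
    at alpha / bonferroni_divisor.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired groups must have equal n")
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    alpha_adj = alpha / max(1, bonferroni_divisor)
    sp_a, sp_b = _shapiro_p(a), _shapiro_p(b)

    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        effect = float(a.mean() - b.mean())
        return GroupComparison("unpaired_t", np.nan, np.nan, effect,
                               (effect, effect), (a.size, b.size), alpha_adj,
                               significant=effect != 0,
                               normality_p=(sp_a, sp_b), degenerate=True)

    if paired:
        stat, p = sstats.ttest_rel(a, b)
        effect, ci = _mean_diff_ci(a, b, paired=True, welch=False)
        test, gate_p = "paired_t", np.nan
    else:
        nonnormal = ((not np.isnan(sp_a) and sp_a < 0.05)
                     or (not np.isnan(sp_b) and sp_b < 0.05))
        if nonnormal:
            stat, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
            effect, ci = _mean_diff_ci(a, b, paired=False, welch=True)
            test, gate_p = "mann_whitney", np.nan
        else:
            gate_p = _variance_ratio_p(a, b)
            welch = not np.isnan(gate_p) and gate_p < 0.05
            stat, p = sstats.ttest_ind(a, b, equal_var=not welch)
            effect, ci = _mean_diff_ci(a, b, paired=False, welch=welch)
            test = "welch_t" if welch else "unpaired_t"
    return GroupComparison(test, float(stat), float(p), effect, ci,
                           (a.size, b.size), alpha_adj,
                           significant=bool(p < alpha_adj),
                           normality_p=(sp_a, sp_b), welch_gate_p=gate_p)


def repeated_measures_anova(data, dv: str, within: Sequence[str],
                            subject: str):
    """Repeated-measures ANOVA, delegated to statsmodels' AnovaRM.

    ``data`` is a tidy DataFrame.  Provided for the speed/bar-width
    analyses; the post hoc machinery is whatever statsmodels offers and
    is reported as delegated.
    """
    from statsmodels.stats.anova import AnovaRM
    return AnovaRM(data, depvar=dv, subject=subject,
                   within=list(within)).fit()
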