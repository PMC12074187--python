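"""Normality-gated subgroup comparisons of model-selection metrics.

Best-model criteria (AIC, BIC, LL) are compared across clinical
subgroups: sex, age group (<40 vs >=40 years), hypoxia, hypotension,
pupillary response (three levels) and dichotomized Marshall CT class
(<5 vs >=5). For two-level groupings a pooled-variance two-sample t-test
is used when both groups pass a Shapiro-Wilk normality gate at alpha,
otherwise a two-sided Mann-Whitney U test (exact when the smaller group
has at most 8 observations and there are no ties). For the three-level
pupil grouping the ladder is one-way ANOVA vs Kruskal-Wallis.

No multiple-testing correction is applied by default — each
signal x grouping x metric cell is judged at the raw threshold — but a
Benjamini-Hochberg adjustment over the emitted table is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubgroupTestResult",
    "normality_gate",
    "compare_two",
    "compare_k",
    "subgroup_analysis",
    "significant_table",
    "GROUPINGS",
]

ALPHA = 0.05
EXACT_MW_MAX_N = 8

#: grouping variable -> its levels, in reporting order
GROUPINGS = {
    "sex": ("M", "F"),
    "age_group": (">=40", "<40"),
    "hypoxia": ("yes", "no"),
    "hypotension": ("yes", "no"),
    "pupils": ("bilateral reactive", "unilateral unreactive",
               "bilateral unreactive"),
    "marshall_group": (">=5", "<5"),
}

METRICS = ("aic", "bic", "ll")


@dataclass(frozen=True)
class SubgroupTestResult:
    signal: str
    grouping: str
    levels: tuple[str, ...]
    metric: str
    test_name: str          # t-test / Mann-Whitney U / ANOVA / Kruskal-Wallis
    statistic: float
    p_value: float
    significant: bool
    group_sizes: tuple[int, ...]


def normality_gate(values, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk gate: normal iff p >= alpha. n < 3 is not-normal."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        return False
    if np.ptp(x) == 0:
        return False
    return bool(stats.shapiro(x).pvalue >= alpha)


def _result(signal, grouping, levels, metric, name, stat, p, alpha, sizes):
    return SubgroupTestResult(signal, grouping, tuple(levels), metric, name,
                              float(stat), float(p), bool(p < alpha),
                              tuple(sizes))


def compare_two(values_a, values_b, alpha: float = ALPHA, welch: bool = False,
                signal: str = "", grouping: str = "",
                levels: tuple[str, str] = ("a", "b"),
                metric: str = "",
                force: str | None = None) -> SubgroupTestResult | None:
    """Two-level comparison behind the normality gate.

    Both groups normal: two-sided two-sample t-test (pooled variance
    unless ``welch``). Otherwise: two-sided Mann-Whitney U, exact when
    ``min(n1, n2) <= 8`` and the pooled sample is tie-free, else the
    normal approximation with tie and continuity correction. Groups of
    size < 2 yield None (NA). ``force`` ('t-test' or 'mannwhitney')
    bypasses the gate, e.g. to cross-check one branch directly.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return None
    sizes = (len(a), len(b))
    if force not in (None, "t-test", "mannwhitney"):
        raise ValueError(f"unknown force option {force!r}")
    gate = (normality_gate(a, alpha) and normality_gate(b, alpha)
            if force is None else force == "t-test")
    if gate:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return _result(signal, grouping, levels, metric, "t-test",
                       res.statistic, res.pvalue, alpha, sizes)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(sizes) <= EXACT_MW_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return _result(signal, grouping, levels, metric, "Mann-Whitney U",
                   res.statistic, res.pvalue, alpha, sizes)


def compare_k(groups, alpha: float = ALPHA, signal: str = "",
              grouping: str = "", levels: tuple[str, ...] = (),
              metric: str = "") -> SubgroupTestResult | None:
    """Multi-level comparison: one-way ANOVA iff every group passes the
    gate, otherwise Kruskal-Wallis (tie-corrected)."""
    cleaned = []
    for g in groups:
        x = np.asarray(g, dtype=float)
        x = x[~np.isnan(x)]
        if len(x):
            cleaned.append(x)
    if len(cleaned) < 2:
        return None
    sizes = tuple(len(g) for g in cleaned)
    if not levels:
        levels = tuple(f"group{i + 1}" for i in range(len(cleaned)))
    if all(normality_gate(g, alpha) for g in cleaned):
        res = stats.f_oneway(*cleaned)
        return _result(signal, grouping, levels, metric, "ANOVA",
                       res.statistic, res.pvalue, alpha, sizes)
    try:
        res = stats.kruskal(*cleaned)
    except ValueError:   # all values identical across groups
        return _result(signal, grouping, levels, metric, "Kruskal-Wallis",
                       0.0, 1.0, alpha, sizes)
    return _result(signal, grouping, levels, metric, "Kruskal-Wallis",
                   res.statistic, res.pvalue, alpha, sizes)


def subgroup_analysis(optima: pd.DataFrame, meta: pd.DataFrame,
                      alpha: float = ALPHA, adjust: str | None = None,
                      welch: bool = False) -> pd.DataFrame:
    """Run the full signal x grouping x metric ladder at one resolution.

    ``optima`` needs columns patient_id, signal and the metric columns
    (aic, bic, ll); ``meta`` carries the covariates keyed by patient_id.
    Groupings with a level absent from the cohort are skipped. With
    ``adjust='bh'`` a Benjamini-Hochberg adjusted p-value column is added
    (the significance flag still reflects the raw threshold).
    """
    merged = optima.merge(meta, on="patient_id", how="inner")
    results: list[SubgroupTestResult] = []
    for signal, sig_df in merged.groupby("signal", sort=True):
        for grouping, levels in GROUPINGS.items():
            present = [lv for lv in levels
                       if (sig_df[grouping] == lv).any()]
            if len(present) < len(levels):
                continue
            for metric in METRICS:
                if metric not in sig_df.columns:
                    continue
                samples = [sig_df.loc[sig_df[grouping] == lv, metric]
                           for lv in levels]
                if len(levels) == 2:
                    res = compare_two(samples[0], samples[1], alpha,
                                      welch=welch, signal=signal,
                                      grouping=grouping, levels=levels,
                                      metric=metric.upper())
                else:
                    res = compare_k(samples, alpha, signal=signal,
                                    grouping=grouping, levels=levels,
                                    metric=metric.upper())
                if res is not None:
                    results.append(res)
    frame = pd.DataFrame([
        {
            "signal": r.signal,
            "grouping": r.grouping,
            "subgroup_1": r.levels[0],
            "subgroup_2": r.levels[1] if len(r.levels) > 1 else "",
            "metric": r.metric,
            "test": r.test_name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "significant": r.significant,
            "group_sizes": "/".join(str(s) for s in r.group_sizes),
        }
        for r in results
    ])
    if adjust == "bh" and not frame.empty:
        from statsmodels.stats.multitest import multipletests
        frame["p_adjusted"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame


def significant_table(results: pd.DataFrame) -> pd.DataFrame:
    """Significant-only view in the reporting column order."""
    cols = ["signal", "grouping", "subgroup_1", "subgroup_2", "metric",
            "test", "p_value"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    return (results.loc[results["significant"], cols]
            .reset_index(drop=True))
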