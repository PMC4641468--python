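"""Cohort-level statistics in the field's reporting conventions.

Groups are compared with the two-sample Kolmogorov-Smirnov test; when either
group has fewer than 10 entries a two-tailed unpaired (pooled-variance)
Student's t-test is used instead. Summaries are mean +/- sem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "ks_two_sample",
    "compare_cohorts",
    "summarize_table",
    "TABLE_ROWS",
]

#: Feature rows of the cohort summary table, in publication order.
TABLE_ROWS = (
    "Cm (pF)",
    "m.p. (mV)",
    "R_in (MOhm)",
    "rheobase (pA)",
    "dV/dt AP threshold (mV)",
    "AP peak (mV)",
    "AP half-width (ms)",
    "AHP (mV)",
    "60 pA AP count",
    "100 pA AP count",
    "200 pA AP count",
)


@dataclass
class GroupComparison:
    """Two-group comparison of one feature."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    statistic: float
    p_value: float
    test_used: str  # "ks" or "t"


def ks_two_sample(x, y):
    """Two-sample Kolmogorov-Smirnov statistic and p-value.

    D is the supremum distance between the two empirical CDFs; the p-value
    is exact for small samples and asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(features_a, features_b, label_a: str = "A",
                    label_b: str = "B", min_n_for_ks: int = 10,
                    pooled_t: bool = True) -> GroupComparison:
    """Compare one feature between two cohorts.

    Uses the KS test when both groups have at least ``min_n_for_ks``
    entries, otherwise a two-tailed unpaired Student's t-test
    (pooled variance by default, Welch with ``pooled_t=False``).
    """
    x = np.asarray(features_a, dtype=float)
    y = np.asarray(features_b, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("cohorts must contain at least one finite value")
    if len(x) >= min_n_for_ks and len(y) >= min_n_for_ks:
        stat, p = ks_two_sample(x, y)
        test = "ks"
    else:
        res = stats.ttest_ind(x, y, equal_var=pooled_t)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "t"
    sem = lambda a: float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0
    return GroupComparison(
        label_a=label_a, label_b=label_b, n_a=len(x), n_b=len(y),
        mean_a=float(x.mean()), mean_b=float(y.mean()),
        sem_a=sem(x), sem_b=sem(y), statistic=stat, p_value=p, test_used=test)


def summarize_table(cohort_features: dict, rows=TABLE_ROWS,
                    min_n_for_ks: int = 10) -> pd.DataFrame:
    """Publication-style summary of two cohorts' feature sets.

    ``cohort_features`` maps cohort label -> {feature row -> list of per-cell
    values}; exactly two cohorts are summarized against each other. Missing
    features are listed with NaN entries rather than imputed.
    """
    if len(cohort_features) != 2:
        raise ValueError("summarize_table expects exactly two cohorts")
    (la, fa), (lb, fb) = cohort_features.items()
    recs = []
    for row in rows:
        va = np.asarray(fa.get(row, []), dtype=float)
        vb = np.asarray(fb.get(row, []), dtype=float)
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        rec = {"feature": row}
        for label, v in ((la, va), (lb, vb)):
            rec[f"{label} mean"] = v.mean() if len(v) else np.nan
            rec[f"{label} sem"] = (np.std(v, ddof=1) / np.sqrt(len(v))
                                   if len(v) > 1 else np.nan)
            rec[f"{label} n"] = len(v)
        if len(va) and len(vb):
            cmp = compare_cohorts(va, vb, la, lb, min_n_for_ks=min_n_for_ks)
            rec["p"] = cmp.p_value
            rec["test"] = cmp.test_used
        else:
            rec["p"] = np.nan
            rec["test"] = "absent"
        recs.append(rec)
    return pd.DataFrame(recs).set_index("feature")
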