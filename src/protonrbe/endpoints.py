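"""Two-stage group comparison and endpoint summary statistics.

The comparison procedure used throughout the study is: first an F-test of
variance equality between the two replicate sets (larger sample variance
in the numerator, two-sided p-value); if that p-value falls below 0.05 the
groups are treated as heteroscedastic and compared with Welch's t-test,
otherwise with the pooled-variance Student t-test. Significance of the
difference in means is declared at p_t < 0.05, per comparison, with no
multiplicity correction by default (a Holm adjustment helper is provided).

Endpoint summaries follow the assay conventions: micronucleus (MN)
frequency is total MN over total binucleated cells (BNC), the %BNC-with-MN
is the fraction of BNC bearing at least one MN, and apoptosis is reported
as the control-subtracted excess percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "MNSummary",
    "compare_groups",
    "variance_f_test",
    "mn_summary",
    "control_subtracted",
    "apoptosis_excess",
    "summarize_endpoint",
    "holm_adjust",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the F-then-t two-sample comparison."""

    f_statistic: float
    p_f: float
    equal_variance_assumed: bool
    t_statistic: float
    p_t: float
    significant: bool
    label_x: str = "x"
    label_y: str = "y"
    n_x: int = 0
    n_y: int = 0


def variance_f_test(x, y) -> tuple[float, float]:
    """Two-sided F-test of variance equality, larger variance in numerator.

    Returns (F, p). Symmetric in its arguments. If one sample variance is
    zero the statistic is infinite and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance")
    if vx >= vy:
        num_v, num_df, den_v, den_df = vx, len(x) - 1, vy, len(y) - 1
    else:
        num_v, num_df, den_v, den_df = vy, len(y) - 1, vx, len(x) - 1
    if den_v == 0:
        return float("inf"), 0.0
    f = num_v / den_v
    p = min(2.0 * stats.f.sf(f, num_df, den_df), 1.0)
    return float(f), float(p)


def compare_groups(
    x,
    y,
    alpha_level: float = 0.05,
    variance_alpha: float = 0.05,
    label_x: str = "x",
    label_y: str = "y",
) -> ComparisonResult:
    """F-test-gated two-sample t-test between two replicate sets.

    If the variance F-test's two-sided p-value is below `variance_alpha`
    the groups are compared with Welch's unequal-variance t-test, else with
    the pooled Student t-test; the two-tailed t p-value against
    `alpha_level` decides significance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("groups must contain finite values")
    f, p_f = variance_f_test(x, y)
    equal_var = p_f >= variance_alpha
    t, p_t = stats.ttest_ind(x, y, equal_var=equal_var)
    return ComparisonResult(
        f_statistic=f,
        p_f=p_f,
        equal_variance_assumed=bool(equal_var),
        t_statistic=float(t),
        p_t=float(p_t),
        significant=bool(p_t < alpha_level),
        label_x=label_x,
        label_y=label_y,
        n_x=len(x),
        n_y=len(y),
    )


@dataclass(frozen=True)
class MNSummary:
    """Micronucleus scoring totals for one sample."""

    total_mn: int
    total_bnc: int
    bnc_with_mn: int
    pct_bnc_with_mn: float
    mn_frequency: float  # MN per BNC


def mn_summary(mn_counts_per_bnc) -> MNSummary:
    """Summarize per-binucleated-cell micronucleus counts.

    MN frequency = total MN / total BNC; %BNC-with-MN = share of cells
    with at least one MN. The frequency is always >= pct/100 since every
    MN-bearing cell contributes at least one MN.
    """
    counts = np.asarray(mn_counts_per_bnc)
    if counts.size == 0:
        raise ValueError("empty micronucleus count collection")
    if np.any(counts < 0):
        raise ValueError("micronucleus counts must be non-negative")
    total_bnc = counts.size
    total_mn = int(counts.sum())
    with_mn = int(np.count_nonzero(counts))
    return MNSummary(
        total_mn=total_mn,
        total_bnc=total_bnc,
        bnc_with_mn=with_mn,
        pct_bnc_with_mn=100.0 * with_mn / total_bnc,
        mn_frequency=total_mn / total_bnc,
    )


def control_subtracted(treated, control):
    """Element-wise excess percentage: treated - control.

    Negative excesses (treated below control) are retained, not clamped,
    to keep averages unbiased; a boolean flag array marks them.

    Returns (excess, negative_flag) arrays of the broadcast shape.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    for name, v in (("treated", t), ("control", c)):
        if np.any((v < 0) | (v > 100)):
            raise ValueError(f"{name} percentages must lie in [0, 100]")
    excess = t - c
    return excess, excess < 0


def apoptosis_excess(measurements: pd.DataFrame) -> pd.DataFrame:
    """Control-subtract apoptosis percentages within matched conditions.

    For each (mode, position, time_h, run, replicate) cell the 0 Gy value
    is subtracted from every dosed value of the same cell. Cells lacking a
    0 Gy control raise. Adds ``excess_pct`` and ``negative`` columns and
    drops the control rows.
    """
    df = measurements.copy()
    keys = ["mode", "position", "time_h", "run", "replicate"]
    ctrl = df[df["dose_gy"] == 0].set_index(keys)["value"]
    if ctrl.empty:
        raise ValueError("no 0 Gy control measurements present")
    dosed = df[df["dose_gy"] > 0].copy()
    idx = pd.MultiIndex.from_frame(dosed[keys])
    missing = idx.difference(ctrl.index)
    if len(missing):
        raise ValueError(f"conditions without matching 0 Gy control: {list(missing)[:5]}")
    dosed["excess_pct"] = dosed["value"].to_numpy() - ctrl.loc[idx].to_numpy()
    dosed["negative"] = dosed["excess_pct"] < 0
    return dosed.reset_index(drop=True)


def summarize_endpoint(measurements: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per-condition mean and sample SD across replicates.

    Groups by (endpoint, mode, position, dose_gy, time_h); the SD is the
    n-1 sample standard deviation and is reported as missing for
    single-measurement groups.
    """
    if measurements.empty:
        raise ValueError("no measurements to summarize")
    keys = ["endpoint", "mode", "position", "dose_gy", "time_h"]
    keys = [k for k in keys if k in measurements.columns]
    agg = (
        measurements.groupby(keys, sort=True)[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return agg


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
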