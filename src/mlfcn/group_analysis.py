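"""Difference-analysis workflows: test-retest ICC and group t-tests with FDR.

Test-retest reliability is quantified with the one-way random-effects
intraclass correlation coefficient,

    ICC = (sigma_r^2 - sigma_w^2) / (sigma_r^2 + (n - 1) * sigma_w^2),

where sigma_r^2 is the between-subject variance, sigma_w^2 the
within-subject (between-session) variance, and n the number of sessions
per subject (2 here).  The variances are the one-way ANOVA mean squares
(ICC(1,1)).  Classification uses tissue-specific benchmarks: ICC > 0.6
(GM) or > 0.5 (WM) reflects individual differences; ICC > 0.8 reflects
them significantly, for any tissue.

Group contrasts use pooled-variance (Student) independent-samples t-tests
— degrees of freedom n1 + n2 - 2 — corrected with Benjamini-Hochberg FDR
within each metric family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IccResult",
    "GroupDiffResult",
    "icc",
    "classify_icc",
    "group_ttest",
    "fdr",
    "icc_table",
    "group_diff_table",
    "ICC_GM_THRESHOLD",
    "ICC_WM_THRESHOLD",
    "ICC_SIGNIFICANT_THRESHOLD",
]

log = logging.getLogger(__name__)

ICC_GM_THRESHOLD = 0.6
ICC_WM_THRESHOLD = 0.5
ICC_SIGNIFICANT_THRESHOLD = 0.8

CLASS_NONE = "none"
CLASS_INDIVIDUAL = "individual_difference"
CLASS_SIGNIFICANT = "significant_individual_difference"


@dataclass(frozen=True)
class IccResult:
    unit: str
    metric: str
    icc: float
    classification: str


@dataclass(frozen=True)
class GroupDiffResult:
    unit: str
    metric: str
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float
    q: float
    significant: bool


def icc(session1: Sequence[float], session2: Sequence[float]) -> float:
    """One-way random-effects ICC from two paired measurement sessions.

    Returns NaN (with a warning) when both variance components vanish —
    all subjects and sessions identical — where the coefficient is 0/0.
    May be negative when within-subject variability exceeds
    between-subject variability (lower bound -1 for two sessions).
    """
    x = np.column_stack([np.asarray(session1, float), np.asarray(session2, float)])
    if x.shape[0] < 2:
        raise ValueError("ICC needs at least 2 subjects")
    k, n = x.shape  # k subjects, n repeated measurements each
    subject_means = x.mean(axis=1)
    grand = x.mean()
    msb = n * np.sum((subject_means - grand) ** 2) / (k - 1)
    msw = np.sum((x - subject_means[:, None]) ** 2) / (k * (n - 1))
    denom = msb + (n - 1) * msw
    if denom == 0.0:
        warnings.warn("ICC undefined: no variance in either component", stacklevel=2)
        return float("nan")
    return float((msb - msw) / denom)


def classify_icc(icc_value: float, tissue: str) -> str:
    """Benchmark an ICC value against the tissue-specific thresholds."""
    if not np.isfinite(icc_value):
        return CLASS_NONE
    if icc_value > ICC_SIGNIFICANT_THRESHOLD:
        return CLASS_SIGNIFICANT
    threshold = ICC_GM_THRESHOLD if tissue == "GM" else ICC_WM_THRESHOLD
    if icc_value > threshold:
        return CLASS_INDIVIDUAL
    return CLASS_NONE


def group_ttest(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t-test; returns (t, df, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with differing group means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (step-up, monotone-regularized)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Table-level workflows
# ---------------------------------------------------------------------------

def icc_table(
    session1: pd.DataFrame,
    session2: pd.DataFrame,
    tissue_of_unit: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-unit, per-metric ICC across two sessions.

    Each input frame has columns ``subject_id, unit, metric, value`` with
    one row per subject x unit x metric; subjects must appear in both
    sessions.  ``tissue_of_unit`` maps unit ids to ``GM``/``WM`` for
    benchmark classification (unknown units use the GM benchmark).
    """
    tissue_of_unit = tissue_of_unit or {}
    merged = session1.merge(
        session2, on=["subject_id", "unit", "metric"], suffixes=("_1", "_2")
    )
    rows = []
    for (unit, metric), grp in merged.groupby(["unit", "metric"], sort=False):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = icc(grp["value_1"].to_numpy(), grp["value_2"].to_numpy())
        tissue = tissue_of_unit.get(unit, "GM")
        rows.append(
            IccResult(unit, metric, val, classify_icc(val, tissue)).__dict__
        )
    return pd.DataFrame(rows)


def group_diff_table(
    group_a: pd.DataFrame, group_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-unit t-tests between two groups, BH-corrected per metric family.

    Inputs have columns ``subject_id, unit, metric, value``.  Units with
    no variance in either group (e.g. whole-brain temporal centrality,
    constant by construction) are skipped with a warning.
    """
    rows = []
    metrics = sorted(set(group_a["metric"]) | set(group_b["metric"]))
    for metric in metrics:
        sub_a = group_a[group_a["metric"] == metric]
        sub_b = group_b[group_b["metric"] == metric]
        units = [u for u in sub_a["unit"].unique() if u in set(sub_b["unit"])]
        stats_rows = []
        for unit in units:
            a = sub_a.loc[sub_a["unit"] == unit, "value"].to_numpy()
            b = sub_b.loc[sub_b["unit"] == unit, "value"].to_numpy()
            try:
                t, df, p = group_ttest(a, b)
            except ValueError as exc:
                log.warning("skipping %s/%s: %s", metric, unit, exc)
                continue
            if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
                log.warning("constant metric %s at unit %s; skipped", metric, unit)
                continue
            stats_rows.append((unit, a.mean(), b.mean(), t, df, p))
        if not stats_rows:
            continue
        q = fdr([r[5] for r in stats_rows])
        for (unit, ma, mb, t, df, p), qv in zip(stats_rows, q):
            rows.append(
                GroupDiffResult(
                    unit, metric, ma, mb, t, df, p, float(qv), bool(qv < alpha)
                ).__dict__
            )
    return pd.DataFrame(rows)
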