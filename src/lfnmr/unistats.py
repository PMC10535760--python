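"""Univariate group statistics and the LF/HF cross-correlation map.

Cohort descriptors are compared by a pooled-variance Student t-test
(entry points for both raw data and printed summary statistics), the
Mann–Whitney U test (exact for small untied samples), and the 2x2
chi-squared test without continuity correction.  Per-ROI statistics
report the AUC, the Mann–Whitney p-value and the fold change
FC = median(sepsis)/median(control).  The cross-instrument correlation
map computes all pairwise Pearson coefficients between a low-field ROI
table and a high-field bin table, with Benjamini–Hochberg control of
the false discovery rate (q < 0.10 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BucketTable, roi_label
from .pls import compute_auc

__all__ = [
    "RoiStatRow",
    "CorrelationMap",
    "ttest_from_summary",
    "group_tests",
    "roi_stats",
    "lf_hf_correlation",
]

SEPSIS = "sepsis"
CONTROL = "control"


@dataclass
class RoiStatRow:
    variable: object
    auc: float
    p_value: float
    fold_change: float | None


@dataclass
class CorrelationMap:
    rho: np.ndarray         # p_lf x p_hf Pearson coefficients
    q_values: np.ndarray    # BH-adjusted p-values, same shape
    mask: np.ndarray        # q < q_cut (and cell well-defined)
    q_cut: float
    lf_labels: list[str]
    hf_labels: list[str]


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def group_tests(data, kind: str) -> tuple[float, float]:
    """Two-group comparison; returns (statistic, two-sided p).

    kind="t": ``data`` is either (x1, x2) raw vectors or a 6-tuple of
    summary statistics (mean1, sd1, n1, mean2, sd2, n2); pooled variance.
    kind="mann_whitney": raw vectors; exact U distribution when samples
    are small and untied, tie-corrected normal approximation otherwise.
    kind="chi2": counts (k1, n1, k2, n2) — events of totals; 2x2
    chi-squared without continuity correction.
    """
    if kind == "t":
        if len(data) == 6:
            return ttest_from_summary(*data)
        x1, x2 = (np.asarray(v, float) for v in data)
        return ttest_from_summary(
            x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
        )
    if kind == "mann_whitney":
        x1, x2 = (np.asarray(v, float) for v in data)
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if kind == "chi2":
        k1, n1, k2, n2 = data
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def roi_stats(table: BucketTable, positive: str = SEPSIS) -> list[RoiStatRow]:
    """Per-ROI AUC (positive class scored high), Mann–Whitney p and fold
    change of group medians (positive/other).  FC is reported as missing
    when the reference median is non-positive."""
    if table.group_labels is None:
        raise ValueError("bucket table carries no group labels")
    labels = np.asarray(table.group_labels)
    groups = list(dict.fromkeys(table.group_labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    other = groups[0] if groups[1] == positive else groups[1]
    pos_mask = labels == positive
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    coded = np.where(pos_mask, 1.0, -1.0)
    rows = []
    for j, var in enumerate(table.variables):
        col = table.values[:, j]
        auc = compute_auc(col, coded)
        _, p = group_tests((col[pos_mask], col[~pos_mask]), "mann_whitney")
        med_pos = float(np.median(col[pos_mask]))
        med_other = float(np.median(col[~pos_mask]))
        if med_other > 0 and med_pos > 0:
            fc = med_pos / med_other
        else:
            warnings.warn(
                f"ROI {var}: non-positive median; fold change undefined",
                RuntimeWarning,
            )
            fc = None
        rows.append(RoiStatRow(variable=var, auc=auc, p_value=p, fold_change=fc))
    return rows


def roi_stats_frame(rows: list[RoiStatRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ROI": [
                roi_label(r.variable) if isinstance(r.variable, tuple) else str(r.variable)
                for r in rows
            ],
            "AUC": [r.auc for r in rows],
            "p": [r.p_value for r in rows],
            "FC[SEPSIS/CTRL]": [r.fold_change for r in rows],
        }
    )


def lf_hf_correlation(
    lf: BucketTable, hf: BucketTable, q_cut: float = 0.10
) -> CorrelationMap:
    """All pairwise Pearson correlations between the columns of two tables
    on the same samples, with BH q-values; cells with a constant column
    are undefined and masked out."""
    if lf.sample_ids != hf.sample_ids:
        raise ValueError("tables must cover the same samples in the same order")
    X = lf.values
    Y = hf.values
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sx = X.std(axis=0)
    sy = Y.std(axis=0)
    const_x = sx == 0
    const_y = sy == 0
    if const_x.any() or const_y.any():
        warnings.warn(
            "constant column(s) present; their correlations are undefined and masked",
            RuntimeWarning,
        )
    Xs = (X - X.mean(axis=0)) / np.where(const_x, 1.0, sx)
    Ys = (Y - Y.mean(axis=0)) / np.where(const_y, 1.0, sy)
    rho = Xs.T @ Ys / n
    rho = np.clip(rho, -1.0, 1.0)
    defined = ~const_x[:, None] & ~const_y[None, :]
    # two-sided p-values via the exact t transform of r
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    q = np.full_like(pvals, np.nan)
    flat = pvals[defined]
    if flat.size:
        q[defined] = stats.false_discovery_control(flat, method="bh")
    mask = defined & (q < q_cut)
    rho[~defined] = np.nan
    return CorrelationMap(
        rho=rho,
        q_values=q,
        mask=mask,
        q_cut=q_cut,
        lf_labels=lf.column_labels(),
        hf_labels=hf.column_labels(),
    )
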