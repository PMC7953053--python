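"""Test-retest reliability metrics for activation masks and rCVR maps.

Implements the session-pair metrics: Dice overlap of thresholded activation
masks, absolute rCVR difference, within-subject coefficient of variation
(wCV, sample SD over the pair divided by the pair mean), voxelwise ICC(3,1)
(two-way mixed model, consistency, single measurement) across subjects, ICC
threshold summaries, and Bonferroni-corrected paired t-tests over ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RetestMetrics",
    "dice",
    "wcv_and_diff",
    "icc31",
    "icc_summary",
    "roi_paired_compare",
]

ICC_THRESHOLDS = (0.4, 0.6, 0.8)


@dataclass(frozen=True)
class RetestMetrics:
    """Session-pair repeatability maps and gray-matter summaries."""

    dice: float
    diff_map: np.ndarray
    wcv_map: np.ndarray
    wcv_valid: np.ndarray
    gm_mean_diff: float
    gm_mean_wcv: float


def dice(mask1, mask2) -> float:
    """Dice coefficient 2 |A intersect B| / (|A| + |B|).

    Returns NaN (flagged undefined) when both masks are empty.
    """
    a = np.asarray(mask1, dtype=bool)
    b = np.asarray(mask2, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * np.logical_and(a, b).sum() / denom


def wcv_and_diff(map1, map2, gm_mask) -> RetestMetrics:
    """Voxelwise |difference| and wCV between two sessions, with GM summaries.

    wCV uses the sample SD over the pair (|a - b| / sqrt(2)) divided by the
    pair mean; voxels with nonpositive pair mean are flagged and excluded
    from the summaries. The Dice field is NaN here (masks are not involved);
    use :func:`dice` for overlap.
    """
    m1 = np.asarray(map1, dtype=float)
    m2 = np.asarray(map2, dtype=float)
    gm = np.asarray(gm_mask, dtype=bool)
    if not (m1.shape == m2.shape == gm.shape):
        raise ValueError("maps and mask must share a shape")
    if not gm.any():
        raise ValueError("gray-matter mask is empty")
    diff = np.abs(m1 - m2)
    mean = 0.5 * (m1 + m2)
    sd = diff / np.sqrt(2.0)
    valid = mean > 0
    wcv = np.zeros_like(m1)
    np.divide(sd, mean, out=wcv, where=valid)
    keep = gm & valid
    if not keep.any():
        raise ValueError("no valid gray-matter voxels after exclusion")
    return RetestMetrics(
        dice=float("nan"),
        diff_map=diff,
        wcv_map=wcv,
        wcv_valid=valid,
        gm_mean_diff=float(diff[keep].mean()),
        gm_mean_wcv=float(wcv[keep].mean()),
    )


def icc31(values) -> np.ndarray | float:
    """ICC(3,1): two-way mixed model, consistency, single measurement.

    Parameters
    ----------
    values : array, shape (n_subjects, k_sessions) or (n_subjects, k, ...)
        Complete cases only (subjects missing a session must be dropped
        beforehand). Requires >= 3 subjects; k = 2 in the retest design but
        any k >= 2 is accepted.

    Returns
    -------
    ICC = (BMS - EMS) / (BMS + (k - 1) EMS) from the two-way
    subjects-x-sessions ANOVA, scalar or a map matching trailing axes.
    Cells where both BMS and EMS vanish return NaN (flagged).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim < 2:
        raise ValueError("values must be n_subjects x k_sessions (x voxels)")
    n, k = v.shape[0], v.shape[1]
    if n < 3:
        raise ValueError("ICC(3,1) requires at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 sessions")

    grand = v.mean(axis=(0, 1))
    subj_mean = v.mean(axis=1)      # (n, ...)
    sess_mean = v.mean(axis=0)      # (k, ...)
    ss_total = ((v - grand) ** 2).sum(axis=(0, 1))
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_sess = n * ((sess_mean - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_subj - ss_sess

    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (bms - ems) / np.where(denom > 0, denom, 1.0), np.nan)
    return icc if icc.ndim else float(icc)


def icc_summary(icc_map, gm_mask, thresholds=ICC_THRESHOLDS) -> dict[float, float]:
    """Percentage of gray-matter voxels with ICC above each threshold.

    NaN (flagged) voxels are excluded from the denominator.
    """
    icc = np.asarray(icc_map, dtype=float)
    gm = np.asarray(gm_mask, dtype=bool)
    if not gm.any():
        raise ValueError("gray-matter mask is empty")
    vals = icc[gm]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite ICC values in gray matter")
    return {float(th): 100.0 * float((vals > th).mean()) for th in thresholds}


def roi_paired_compare(maps_a, maps_b, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests of ROI-mean values, A vs B.

    Parameters
    ----------
    maps_a, maps_b : sequences of maps, one per subject (paired order)
        e.g. rCVR maps under two acquisition conditions.
    labels : integer map
        ROI label image; label 0 is background. ROIs with fewer than two
        paired subjects are flagged and excluded from testing.

    Returns
    -------
    DataFrame with one row per ROI: means and SDs per condition, paired t,
    raw p and Bonferroni-adjusted p (multiplied by the number of tested
    ROIs, capped at 1), significance at ``alpha``, and a ``degenerate`` flag
    for zero-variance differences.
    """
    lab = np.asarray(labels)
    maps_a = [np.asarray(m, dtype=float) for m in maps_a]
    maps_b = [np.asarray(m, dtype=float) for m in maps_b]
    if len(maps_a) != len(maps_b):
        raise ValueError("conditions must have the same number of paired subjects")
    rois = [int(r) for r in np.unique(lab) if r != 0]
    rows = []
    for roi in rois:
        m = lab == roi
        a = np.array([mp[m].mean() for mp in maps_a])
        b = np.array([mp[m].mean() for mp in maps_b])
        if a.size < 2:
            rows.append({"roi": roi, "n": int(a.size), "excluded": True})
            continue
        d = a - b
        degenerate = np.allclose(d.std(ddof=1), 0)
        if degenerate:
            t_val = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
            p_raw = 1.0 if np.allclose(d, 0) else 0.0
        else:
            t_val, p_raw = stats.ttest_rel(a, b)
        rows.append({
            "roi": roi, "n": int(a.size),
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
            "t": float(t_val), "p_raw": float(p_raw),
            "degenerate": bool(degenerate), "excluded": False,
        })
    df = pd.DataFrame(rows)
    tested = ~df.get("excluded", pd.Series(False, index=df.index))
    n_tests = int(tested.sum())
    df["p_bonferroni"] = np.minimum(df.get("p_raw", np.nan) * n_tests, 1.0)
    df["significant"] = df["p_bonferroni"] < alpha
    return df
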