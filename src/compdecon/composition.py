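"""Paired comparisons of cell scores between treatment arms.

Per cell type, the per-subject differences d_i = score(control_i) -
score(treated_i) are summarized by a paired t-test with a 95% t-interval;
positive mean differences therefore indicate a HIGHER score in the vehicle
control (i.e. the type is depleted by treatment), and a type expanded by
treatment shows a negative mean difference.  A total-score test applies the
same machinery to the summed absolute scores, and a Spearman helper measures
concordance of per-gene statistics between strata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellScoreTable

__all__ = ["paired_differences", "paired_score_test", "total_score_test", "correlate_stats"]


def paired_differences(
    scores: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Subject x column matrix of (control - treated) score differences."""
    ctrl = metadata.index[metadata["treatment"] == "control"]
    trt = metadata.index[metadata["treatment"] == "ethanol"]
    by_subject_c = scores.loc[ctrl].set_axis(metadata.loc[ctrl, "subject"], axis=0)
    by_subject_t = scores.loc[trt].set_axis(metadata.loc[trt, "subject"], axis=0)
    return by_subject_c - by_subject_t.loc[by_subject_c.index]


def _paired_t_row(d: np.ndarray, label: str) -> dict:
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        warnings.warn(f"zero-variance paired differences for {label!r}; exact tie")
        return {
            "cell_type": label,
            "mean_difference": mean,
            "ci_low": mean,
            "ci_high": mean,
            "statistic": np.nan,
            "p_value": 1.0,
            "n_pairs": n,
        }
    se = sd / np.sqrt(n)
    t = mean / se
    half = stats.t.ppf(0.975, n - 1) * se
    return {
        "cell_type": label,
        "mean_difference": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "statistic": t,
        "p_value": float(2.0 * stats.t.sf(abs(t), n - 1)),
        "n_pairs": n,
    }


def paired_score_test(
    scores: CellScoreTable, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Paired t-test per cell type on absolute scores (control - treated).

    Returns one row per cell type with the mean difference, 95% t-interval,
    two-sided p and number of complete pairs.  Requires >= 3 pairs.
    """
    diffs = paired_differences(scores.absolute, metadata)
    if len(diffs) < 3:
        raise ValueError("need at least 3 complete pairs")
    rows = [_paired_t_row(diffs[ct].to_numpy(dtype=float), ct) for ct in diffs.columns]
    return pd.DataFrame(rows).set_index("cell_type")


def total_score_test(scores: CellScoreTable, metadata: pd.DataFrame) -> pd.Series:
    """Paired t-test on per-subject total absolute score differences."""
    totals = scores.total().to_frame("total")
    diffs = paired_differences(totals, metadata)
    if len(diffs) < 3:
        raise ValueError("need at least 3 complete pairs")
    return pd.Series(_paired_t_row(diffs["total"].to_numpy(dtype=float), "total"))


def correlate_stats(stats_a: pd.Series, stats_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of per-gene statistics on shared genes."""
    shared = stats_a.index.intersection(stats_b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (need >= 10)")
    rho, p = stats.spearmanr(stats_a.loc[shared], stats_b.loc[shared])
    return float(rho), float(p)
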