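"""Effect-size and significance statistics for pre/post assessment scores.

Two standardized-mean-difference estimators are provided.  For AAT
subtest scores, which are T-transformed to a population standard
deviation of 10, the population value is used directly:

    d_s = (mean(z_post) - mean(z_pre)) / 10.

For all other scales the SD is estimated, giving Hedges' g_s with the
two-group pooled standard deviation and the small-sample correction
J = 1 - 3 / (4 (n_pre + n_post - 2) - 1).

Also included: paired two-sided t and Wilcoxon signed-rank tests,
Benjamini-Hochberg FDR control, and the "maximal possible change
realized" score 100 (post - pre) / (max - pre) used to compare patients
on raw AAT point totals (maximum 530 points).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "T_SCORE_SD",
    "AAT_MAX_POINTS",
    "EffectSizeResult",
    "StatsConfig",
    "load_assessment_table",
    "t_score_effect_size",
    "d_s_from_means",
    "hedges_gs",
    "hedges_gs_from_summary",
    "max_change_realized",
    "paired_test",
    "bh_correct",
]

T_SCORE_SD = 10.0
AAT_MAX_POINTS = 530.0

TIMEPOINTS = ("screening", "pre", "mid", "post", "followup")


@dataclass(frozen=True)
class EffectSizeResult:
    estimator: str  # "d_s" or "hedges_gs"
    value: float
    n_pre: int
    n_post: int


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    correction: str = "benjamini-hochberg"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def load_assessment_table(path_or_name) -> pd.DataFrame:
    """Read an assessment CSV (columns patient_id, test, timepoint, value,
    scale).  Names of packaged fixtures ('aat_raw_points', 'aat_tscore_summary',
    'cal_summary') resolve to the bundled published-table data."""
    packaged = {"aat_raw_points", "aat_tscore_summary", "cal_summary"}
    if str(path_or_name) in packaged:
        ref = resources.files("erpbci.data") / f"{path_or_name}.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    df = pd.read_csv(path_or_name)
    required = {"patient_id", "test", "timepoint", "value", "scale"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assessment table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["patient_id", "test", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (patient, test, timepoint) rows")
    return df


def t_score_effect_size(pre_scores, post_scores) -> EffectSizeResult:
    """d_s for paired T-scores: mean change divided by the scale SD 10."""
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired vectors of equal length")
    value = (post.mean() - pre.mean()) / T_SCORE_SD
    return EffectSizeResult("d_s", float(value), pre.size, post.size)


def d_s_from_means(pre_mean: float, post_mean: float, n: int = 0) -> EffectSizeResult:
    """d_s from group means alone (sufficient, since the SD is fixed at 10)."""
    return EffectSizeResult("d_s", (post_mean - pre_mean) / T_SCORE_SD, n, n)


def _hedges_j(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_gs(pre_scores, post_scores) -> EffectSizeResult:
    """Hedges g_s from raw score vectors (two-group pooled SD, J-corrected)."""
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("need at least 2 values per group")
    return hedges_gs_from_summary(
        pre.mean(), pre.std(ddof=1), pre.size, post.mean(), post.std(ddof=1), post.size
    )


def hedges_gs_from_summary(
    pre_mean: float,
    pre_sd: float,
    n_pre: int,
    post_mean: float,
    post_sd: float,
    n_post: int,
) -> EffectSizeResult:
    """Hedges g_s from group summary statistics.

    g_s = J * (mean_post - mean_pre) / s_pooled with
    s_pooled^2 = ((n_pre-1) s_pre^2 + (n_post-1) s_post^2) / (n_pre+n_post-2)
    and J = 1 - 3 / (4 (n_pre + n_post - 2) - 1).
    """
    df = n_pre + n_post - 2
    if df < 1:
        raise ValueError("need n_pre + n_post >= 3")
    s_pooled = np.sqrt(
        ((n_pre - 1) * pre_sd**2 + (n_post - 1) * post_sd**2) / df
    )
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    value = _hedges_j(df) * (post_mean - pre_mean) / s_pooled
    return EffectSizeResult("hedges_gs", float(value), n_pre, n_post)


def max_change_realized(
    pre_points, post_points, max_points: float = AAT_MAX_POINTS
) -> dict:
    """Percentage of the maximal possible improvement realized per patient.

    per-patient: 100 (post - pre) / (max - pre).  Returns the per-patient
    vector plus mean / min / max / SD (SD with ddof=1) over patients.
    """
    pre = np.asarray(pre_points, dtype=float)
    post = np.asarray(post_points, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired vectors")
    if np.any(pre >= max_points):
        raise ValueError(f"pre scores must be below the maximum {max_points}")
    pct = 100.0 * (post - pre) / (max_points - pre)
    return {
        "per_patient": pct,
        "mean": float(pct.mean()),
        "min": float(pct.min()),
        "max": float(pct.max()),
        "sd": float(pct.std(ddof=1)) if pct.size > 1 else 0.0,
    }


def paired_test(pre, post, kind: str = "t") -> tuple[float, float]:
    """Two-sided paired test of post vs pre.

    kind 't': paired t-test.  kind 'wilcoxon_signed_rank': signed-rank
    test with zero differences dropped (exact null distribution up to
    n = 25 pairs, normal approximation with continuity correction
    beyond).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired vectors")
    if kind == "t":
        res = stats.ttest_rel(post, pre)
        return float(res.statistic), float(res.pvalue)
    if kind == "wilcoxon_signed_rank":
        diffs = post - pre
        nz = diffs[diffs != 0]
        if nz.size < 3:
            raise ValueError("wilcoxon needs at least 3 non-zero differences")
        method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) \
            else "approx"
        res = stats.wilcoxon(nz, method=method, correction=(method == "approx"))
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def bh_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values) in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj
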