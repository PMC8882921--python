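"""The three-axis evaluation protocol for microstate detection results.

Microstate quality: |R| correlation matrices of identified templates against
a reference set (after optimal matching), row/column/overall diagonal
ratios, GEV tables across strategies with Cronbach's alpha consistency.

Task efficacy: per feature x state x dimension comparison of low vs high
groups, normality-gated (Lilliefors at alpha = 0.05 on both groups -> Welch
t-test, otherwise Wilcoxon rank-sum), two-sided, with Benjamini-Hochberg
FDR adjustment applied jointly across the comparisons of one dimension.

Computational efficiency: the per-stage wall-clock timings recorded by the
strategies, laid out as first-step / second-step / total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import MicrostateSet, _prepare_maps, match_templates
from .exceptions import DegenerateClusteringError, InvalidInputError

__all__ = [
    "CorrelationComparison",
    "reference_correlation_matrix",
    "cronbach_alpha",
    "fdr_adjust",
    "task_efficacy_tests",
    "timing_table",
]


@dataclass
class CorrelationComparison:
    """K x K |R| matrix (identified rows x reference columns) and its ratios.

    Rows are re-ordered by the optimal matching so the diagonal holds the
    matched pairing. Ratios measure how much of each row/column's correlation
    mass sits on the diagonal; the chance floor of the overall ratio is 1/K.
    """

    matrix: np.ndarray
    row_ratios: np.ndarray
    col_ratios: np.ndarray
    overall_ratio: float
    mean_matched_r: float
    permutation: tuple


def reference_correlation_matrix(
    identified: MicrostateSet, reference: MicrostateSet
) -> CorrelationComparison:
    """Compare identified templates to a reference set of equal size."""
    if identified.K != reference.K:
        raise InvalidInputError("template sets must have equal K")
    m = match_templates(identified, reference)
    A = m.aligned.templates  # matched order, unit norm, centered
    B = _prepare_maps(reference.templates)
    M = np.abs(A @ B.T)
    row = np.diag(M) / M.sum(axis=1)
    col = np.diag(M) / M.sum(axis=0)
    overall = float(np.trace(M) / M.sum())
    return CorrelationComparison(
        matrix=M,
        row_ratios=row,
        col_ratios=col,
        overall_ratio=overall,
        mean_matched_r=float(np.diag(M).mean()),
        permutation=m.permutation,
    )


def cronbach_alpha(items_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an observations x items matrix.

    alpha = (k/(k-1)) * (1 - sum_j var_j / var_total) with unbiased
    variances; var_total is the variance of the per-observation sums. Used
    here with strategies as items and per-trial GEV values as observations.
    Raises on zero total variance (alpha undefined/degenerate).
    """
    X = np.asarray(items_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidInputError("need >= 2 observations and >= 2 items")
    k = X.shape[1]
    var_items = X.var(axis=0, ddof=1).sum()
    var_total = X.sum(axis=1).var(ddof=1)
    if var_total <= 0:
        raise DegenerateClusteringError("zero total variance: Cronbach's alpha undefined")
    return float(k / (k - 1) * (1.0 - var_items / var_total))


def fdr_adjust(pvalues: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_(i) * m / i with cumulative-minimum monotonicity enforcement from the
    largest p downward, capped at 1; order-preserving in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


FEATURES = ("duration_ms", "coverage", "occurrence")


def task_efficacy_tests(
    features: pd.DataFrame,
    group_labels: dict | pd.Series,
    dimension: str = "valence",
    alpha_normality: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Low vs high group comparisons for every feature x state.

    `features` is the long-format table of :func:`features_table` (one row
    per trial x state with duration_ms / coverage / occurrence columns);
    `group_labels` maps (subject_id, trial_id) to "low"/"high". Each
    comparison runs the Lilliefors normality test on both groups; if both
    pass, a two-sided Welch t-test, otherwise a two-sided Wilcoxon rank-sum.
    Raw p-values are BH-adjusted jointly across all comparisons of the
    dimension. Groups smaller than `min_group` skip the comparison.
    """
    from statsmodels.stats.diagnostic import lilliefors

    labels = dict(group_labels)
    df = features.copy()
    df["_group"] = [
        labels.get((s, t)) for s, t in zip(df["subject_id"], df["trial_id"])
    ]
    rows = []
    for state, sdf in df.groupby("state", sort=True):
        for feat in FEATURES:
            low = sdf.loc[sdf["_group"] == "low", feat].to_numpy(dtype=float)
            high = sdf.loc[sdf["_group"] == "high", feat].to_numpy(dtype=float)
            if low.size < min_group or high.size < min_group:
                warnings.warn(f"state {state} {feat}: a group has < {min_group} trials; skipped")
                continue
            normal = True
            for grp in (low, high):
                if np.ptp(grp) == 0:
                    normal = False
                    break
                _, p_norm = lilliefors(grp, dist="norm")
                if p_norm < alpha_normality:
                    normal = False
                    break
            if normal:
                stat, p = stats.ttest_ind(low, high, equal_var=False)
                test = "welch_t"
            else:
                stat, p = stats.ranksums(low, high)
                test = "wilcoxon_ranksum"
            rows.append(
                {
                    "dimension": dimension,
                    "state": state,
                    "state_name": f"MS{int(state) + 1}",
                    "feature": feat,
                    "test": test,
                    "statistic": float(stat),
                    "p_raw": float(p),
                    "mean_low": low.mean(),
                    "sd_low": low.std(ddof=1),
                    "mean_high": high.mean(),
                    "sd_high": high.std(ddof=1),
                    "n_low": low.size,
                    "n_high": high.size,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    return table


def timing_table(results: dict) -> pd.DataFrame:
    """Per-stage timings of several strategy runs in first/second/total layout."""
    rows = []
    for name, res in results.items():
        timings = res.timings if hasattr(res, "timings") else res
        first = timings.get("step1", 0.0)
        second = sum(v for k, v in timings.items() if k.startswith(("step2", "step3")))
        rows.append(
            {
                "strategy": name,
                "first_step_s": first,
                "second_step_s": second,
                "total_s": timings.get("total", first + second),
            }
        )
    return pd.DataFrame(rows)
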