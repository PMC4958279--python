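"""Per-feature differential-abundance statistics.

Two-sample t-tests (Welch by default, pooled/Student optionally) on the
log2 feature table, Benjamini–Hochberg q-values, the joint significance
rule (P < 0.05 and q < 0.10 by default), and a summary-statistic t-test
for comparisons where only group means, SDs and n are available (e.g. a
serum assay reported as mean±SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, LOG2, AUTOSCALED, group_masks
from .preprocess import fold_change as _fold_change

__all__ = [
    "welch_t",
    "bh_qvalues",
    "summary_stat_ttest",
    "top_k_by_p",
    "differential_abundance",
]

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.10


def welch_t(
    table: FeatureTable, metadata: pd.DataFrame, variant: str = "welch"
) -> pd.DataFrame:
    """Per-feature two-sided two-sample t-test, sorted by p-value.

    ``variant`` selects Welch (unequal variances, Welch–Satterthwaite df)
    or ``"pooled"`` (classical Student, df = n1+n2−2).  Features with zero
    variance in both groups get t=0, p=1 and a ``degenerate`` flag.  The
    input order is recoverable from the ``input_index`` column.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    table.require_scale(LOG2, AUTOSCALED, op="welch_t")
    table.require_complete(op="welch_t")
    ctrl, case = group_masks(metadata, table.sample_ids)
    if ctrl.sum() < 2 or case.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    x = table.data.to_numpy()
    a, b = x[case], x[ctrl]  # case first: t > 0 means elevated in cases
    res = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    out = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "degenerate": degenerate,
            "input_index": np.arange(table.n_features),
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summary_stat_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from group summary statistics.

    Returns (t, df, two-sided p).  The pooled variant uses the pooled
    variance with df = n1+n2−2; ``"welch"`` uses the Welch–Satterthwaite
    approximation.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def top_k_by_p(results: pd.DataFrame, k: int = 70) -> pd.DataFrame:
    """The k most significant features; ties by larger |t|, then feature_id."""
    if k > len(results):
        raise ValueError(f"k={k} exceeds the number of features ({len(results)})")
    ordered = results.assign(_abs_t=-results["t_stat"].abs()).sort_values(
        ["p_value", "_abs_t", "feature_id"], kind="stable"
    )
    return ordered.drop(columns="_abs_t").head(k).reset_index(drop=True)


def differential_abundance(
    raw_table: FeatureTable,
    metadata: pd.DataFrame,
    variant: str = "welch",
    p_threshold: float = P_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Full differential-abundance result for a filtered, imputed raw table.

    Fold changes are computed on the raw scale, the t-test on log2 data;
    q-values are BH step-up; ``significant`` applies the joint rule
    p < p_threshold and q < q_threshold.  Sorted by p-value.
    """
    from .preprocess import log2_transform

    fc = _fold_change(raw_table, metadata).set_index("feature_id")
    res = welch_t(log2_transform(raw_table), metadata, variant=variant)
    res["q_value"] = bh_qvalues(res["p_value"].to_numpy())
    res["fold_change"] = fc.loc[res["feature_id"], "fold_change"].to_numpy()
    res["log2_fc"] = fc.loc[res["feature_id"], "log2_fc"].to_numpy()
    res["significant"] = (res["p_value"] < p_threshold) & (res["q_value"] < q_threshold)
    cols = [
        "feature_id", "fold_change", "log2_fc", "t_stat", "df",
        "p_value", "q_value", "significant", "degenerate", "input_index",
    ]
    return res[cols]
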