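"""Feature-table preprocessing: filter → impute → fold change → log2 → autoscale.

The chain mirrors the standard metabolomics workflow for a two-group
feature table: metabolites with ≥50% missing values in either group are
discarded, remaining gaps are filled by k-nearest-neighbor imputation,
fold changes are taken as ratios of arithmetic group means on the raw
scale (before any transformation), and the matrix handed to statistics
and classification is log2-transformed and autoscaled (per-feature
z-scores).  The order is enforced through the :class:`FeatureTable` scale
tag.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, RAW, LOG2, AUTOSCALED, check_metadata, group_masks

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "filter_missing",
    "knn_impute",
    "fold_change",
    "log2_transform",
    "autoscale",
    "preprocess",
]


@dataclass
class PreprocessReport:
    """What a preprocessing step did to the table."""

    step: str
    #: feature_id -> (missing proportion in control, in case) for discards
    discarded_features: pd.DataFrame | None = None
    #: (sample_id, feature_id) cells that were imputed
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    #: features imputed by the feature-mean fallback (no usable neighbor)
    fallback_features: list[str] = field(default_factory=list)
    #: constant features zeroed by autoscaling
    constant_features: list[str] = field(default_factory=list)
    k_used: int | None = None


def filter_missing(
    table: FeatureTable, metadata: pd.DataFrame, threshold: float = 0.5
) -> tuple[FeatureTable, PreprocessReport]:
    """Discard features with a missing proportion ≥ threshold in either group.

    The threshold is inclusive ("50% or more"), applied per group; the
    sample set is unchanged.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    table.require_scale(RAW, op="filter_missing")
    ctrl, case = group_masks(metadata, table.sample_ids)
    miss = table.data.isna().to_numpy()
    prop_ctrl = miss[ctrl].mean(axis=0)
    prop_case = miss[case].mean(axis=0)
    drop = (prop_ctrl >= threshold) | (prop_case >= threshold)
    kept = table.data.loc[:, ~drop]
    if kept.shape[1] == 0:
        raise ValueError("all features were discarded by the missingness filter")
    report = PreprocessReport(
        step="filter_missing",
        discarded_features=pd.DataFrame(
            {
                "feature_id": np.asarray(table.feature_ids)[drop],
                "missing_prop_control": prop_ctrl[drop],
                "missing_prop_case": prop_case[drop],
            }
        ).reset_index(drop=True),
    )
    log.info(
        "filter_missing: %d -> %d features (%d discarded at threshold %.2f)",
        table.n_features, kept.shape[1], int(drop.sum()), threshold,
    )
    return FeatureTable(kept.copy(), RAW), report


def _standardize_for_distance(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
    return (x - mean) / sd


def knn_impute(table: FeatureTable, k: int = 10) -> tuple[FeatureTable, PreprocessReport]:
    """Fill missing cells with the mean of the k nearest samples' values.

    Neighbors are ranked by Euclidean distance over co-observed,
    per-feature-standardized values (distances rescaled by the number of
    co-observed features, as in the NaN-aware Euclidean convention).  Only
    samples with the target feature observed are candidates; the effective
    k shrinks when fewer are available, and a feature observed in no other
    sample falls back to its observed mean (recorded in the report).
    Complete tables are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table.require_scale(RAW, op="knn_impute")
    x = table.data.to_numpy(copy=True)
    missing = np.isnan(x)
    report = PreprocessReport(step="knn_impute", k_used=k)
    if not missing.any():
        return table.copy(), report

    z = _standardize_for_distance(x)
    n, p = x.shape
    obs = ~missing
    # pairwise NaN-aware Euclidean distances on standardized values
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            co = obs[i] & obs[j]
            n_co = int(co.sum())
            if n_co == 0:
                continue
            d2 = np.sum((z[i, co] - z[j, co]) ** 2) * (p / n_co)
            dist[i, j] = dist[j, i] = math.sqrt(d2)

    out = x.copy()
    samples, features = table.sample_ids, table.feature_ids
    for i, j in zip(*np.nonzero(missing)):
        donors = np.flatnonzero(obs[:, j])
        donors = donors[donors != i]
        if donors.size == 0:
            raise ValueError(
                f"feature {features[j]!r} is observed in no sample; filter first"
            )
        if not np.isfinite(dist[i, donors]).any():
            # no donor shares an observed feature with this sample: fall back
            # to the feature mean over all observed values
            out[i, j] = x[donors, j].mean()
            if features[j] not in report.fallback_features:
                report.fallback_features.append(features[j])
        else:
            order = np.lexsort((donors, dist[i, donors]))  # distance, then index
            chosen = donors[order[: min(k, donors.size)]]
            out[i, j] = x[chosen, j].mean()
        report.imputed_cells.append((samples[i], features[j]))
    log.info("knn_impute: filled %d cells (k=%d)", len(report.imputed_cells), k)
    return FeatureTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns), RAW), report


def fold_change(
    table: FeatureTable, metadata: pd.DataFrame, pairwise_complete: bool = True
) -> pd.DataFrame:
    """Per-feature case/control ratio of arithmetic group means, raw scale.

    Computed before any normalization by contract; missing cells are
    excluded pairwise when ``pairwise_complete`` (otherwise any NaN is an
    error).  Returns a frame with ``fold_change`` and ``log2_fc``.
    """
    table.require_scale(RAW, op="fold_change")
    if not pairwise_complete:
        table.require_complete(op="fold_change")
    ctrl, case = group_masks(metadata, table.sample_ids)
    if ctrl.sum() == 0 or case.sum() == 0:
        raise ValueError("both groups must be nonempty")
    x = table.data.to_numpy()
    mean_ctrl = np.nanmean(x[ctrl], axis=0)
    mean_case = np.nanmean(x[case], axis=0)
    if np.any(~(mean_ctrl > 0)):
        bad = np.asarray(table.feature_ids)[~(mean_ctrl > 0)]
        raise ValueError(f"non-positive or undefined control mean for {list(bad)[:5]}")
    ratio = mean_case / mean_ctrl
    return pd.DataFrame(
        {"feature_id": table.feature_ids, "fold_change": ratio, "log2_fc": np.log2(ratio)}
    )


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise log2; requires strictly positive raw values."""
    table.require_scale(RAW, op="log2_transform")
    x = table.data.to_numpy()
    bad = np.argwhere(~np.isnan(x) & (x <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"log2_transform: non-positive value at sample "
            f"{table.sample_ids[i]!r}, feature {table.feature_ids[j]!r}"
        )
    return FeatureTable(np.log2(table.data), LOG2)


def autoscale(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Per-feature standardization to mean 0, sample SD 1 (ddof=1).

    Constant features become all-zero columns and are flagged rather than
    raising.  Idempotent.
    """
    if table.n_samples < 2:
        raise ValueError("autoscale needs at least 2 samples")
    table.require_complete(op="autoscale")
    x = table.data.to_numpy()
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    # relative tolerance: identical values can leave an O(eps·|mean|) residual SD
    constant = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    safe_sd = np.where(constant, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, constant] = 0.0
    report = PreprocessReport(
        step="autoscale",
        constant_features=list(np.asarray(table.feature_ids)[constant]),
    )
    if constant.any():
        log.warning("autoscale: %d constant feature(s) set to zero", constant.sum())
    return (
        FeatureTable(pd.DataFrame(z, index=table.data.index, columns=table.data.columns), AUTOSCALED),
        report,
    )


def preprocess(
    table: FeatureTable,
    metadata: pd.DataFrame,
    threshold: float = 0.5,
    k: int = 10,
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame, list[PreprocessReport]]:
    """Run the full chain; returns (autoscaled, imputed-raw, fold changes, reports)."""
    filtered, rep_f = filter_missing(table, metadata, threshold)
    imputed, rep_i = knn_impute(filtered, k)
    fc = fold_change(imputed, metadata)
    logged = log2_transform(imputed)
    scaled, rep_a = autoscale(logged)
    return scaled, imputed, fc, [rep_f, rep_i, rep_a]
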