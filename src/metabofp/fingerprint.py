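"""Resampled linear-SVM classification and rank-aggregated feature importance.

The core procedure: 50 independent stratified 70/30 train/test splits of
the samples; in each split a soft-margin linear SVM is fitted on the
training part, its decision scores on the test part give a ROC curve and
AUC (computed as the Mann–Whitney rank statistic), and metabolites are
ranked by |linear weight|.  Averaging the per-iteration ranks yields the
metabolite fingerprint; re-running the whole procedure on label-shuffled
data yields the permutation null against which the mean AUC is judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .tables import FeatureTable, AUTOSCALED, GROUP_CASE, check_metadata

__all__ = [
    "ResamplePlan",
    "IterationResult",
    "FingerprintReport",
    "NullResult",
    "make_resample_plan",
    "fit_linear_svm",
    "rank_auc",
    "evaluate_iteration",
    "average_roc",
    "permutation_null",
    "aggregate_importance",
    "run_fingerprint",
]

N_ITERATIONS = 50
TRAIN_FRACTION = 0.7
TOP_N = 25
SVM_COST = 1.0
ROC_GRID_POINTS = 101


@dataclass(frozen=True)
class ResamplePlan:
    """Stratified train/test partitions for the resampling loop."""

    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    train_fraction: float
    master_seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.splits)


@dataclass
class IterationResult:
    """One fitted split: weights, test scores, ROC, AUC, importance ranks."""

    iteration: int
    weights: pd.Series          # per-feature linear weights
    bias: float
    test_scores: pd.Series      # decision scores for the test samples
    test_labels: pd.Series      # 1 = case
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    importance_rank: pd.Series  # 1 = most important (largest |weight|)
    degenerate: bool = False


@dataclass
class NullResult:
    """Permutation-null summary: 50 label-shuffled AUCs and a normal CI."""

    aucs: np.ndarray
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class FingerprintReport:
    """Average-rank fingerprint plus classifier performance summaries."""

    avg_rank: pd.DataFrame      # feature_id, avg_rank (+ fc/p/q annotations)
    top: pd.DataFrame           # the top-N rows of avg_rank
    iteration_aucs: np.ndarray
    mean_auc: float
    roc: pd.DataFrame           # fpr, tpr_mean, tpr_se
    null: NullResult | None = None


def _stratified_split(ids_by_class, train_fraction, rng):
    train, test = [], []
    for ids in ids_by_class:
        n = len(ids)
        n_train = int(round(train_fraction * n))
        n_train = min(n_train, n - 2)  # keep >= 2 test samples per class
        if n_train < 2:
            raise ValueError("class too small for a stratified 70/30 split")
        perm = rng.permutation(n)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return tuple(sorted(train)), tuple(sorted(test))


def make_resample_plan(
    metadata: pd.DataFrame,
    n_iterations: int = N_ITERATIONS,
    train_fraction: float = TRAIN_FRACTION,
    master_seed: int = 0,
) -> ResamplePlan:
    """Independent stratified train/test partitions.

    Per class, round(train_fraction·n) samples train, the rest test, with
    the train count reduced if needed so every test set keeps ≥2 samples
    of each class (12/8 samples ⇒ 8+6 train, 4+2 test).  Per-iteration
    RNGs are spawned deterministically from ``master_seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    meta = check_metadata(metadata)
    classes = [
        list(meta.index[meta["group"] == g]) for g in sorted(meta["group"].unique())
    ]
    if any(len(c) < 4 for c in classes):
        raise ValueError("each class needs at least 4 samples for stratification")
    seeds = np.random.SeedSequence(master_seed).spawn(n_iterations)
    splits = tuple(
        _stratified_split(classes, train_fraction, np.random.default_rng(s))
        for s in seeds
    )
    return ResamplePlan(splits, train_fraction, master_seed)


def fit_linear_svm(x: np.ndarray, y: np.ndarray, cost: float = SVM_COST):
    """Soft-margin linear SVM; returns (weights, bias).

    ``y`` is binary with 1 = case; the decision score is w·x + b, positive
    toward the case class.  Deterministic for fixed input.
    """
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    model = SVC(kernel="linear", C=cost)
    model.fit(x, y)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann–Whitney statistic: P(case score > control score)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes in the test set")
    r = rankdata(scores)
    u = r[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_iteration(
    table: FeatureTable,
    metadata: pd.DataFrame,
    train_ids,
    test_ids,
    iteration: int = 0,
    cost: float = SVM_COST,
    labels: pd.Series | None = None,
) -> IterationResult:
    """Fit on the training samples, score and rank on the test samples.

    ``labels`` may override the metadata groups (used by the permutation
    null).  Importance rank is descending |weight| with average-rank ties.
    """
    table.require_scale(AUTOSCALED, op="evaluate_iteration")
    table.require_complete(op="evaluate_iteration")
    if labels is None:
        meta = check_metadata(metadata, table.sample_ids)
        labels = (meta["group"] == GROUP_CASE).astype(int)
    labels = labels.loc[table.sample_ids]
    x_train = table.data.loc[list(train_ids)].to_numpy()
    y_train = labels.loc[list(train_ids)].to_numpy()
    x_test = table.data.loc[list(test_ids)].to_numpy()
    y_test = labels.loc[list(test_ids)].to_numpy()

    w, b = fit_linear_svm(x_train, y_train, cost)
    scores = x_test @ w + b
    degenerate = bool(np.ptp(scores) == 0)
    auc = 0.5 if degenerate else rank_auc(scores, y_test)
    if degenerate:
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
    else:
        fpr, tpr, _ = roc_curve(y_test, scores)
    rank = rankdata(-np.abs(w), method="average")
    return IterationResult(
        iteration=iteration,
        weights=pd.Series(w, index=table.feature_ids, name="weight"),
        bias=b,
        test_scores=pd.Series(scores, index=list(test_ids), name="score"),
        test_labels=pd.Series(y_test, index=list(test_ids), name="label"),
        auc=auc,
        fpr=np.asarray(fpr, dtype=float),
        tpr=np.asarray(tpr, dtype=float),
        importance_rank=pd.Series(rank, index=table.feature_ids, name="rank"),
        degenerate=degenerate,
    )


def run_iterations(
    table: FeatureTable,
    metadata: pd.DataFrame,
    plan: ResamplePlan,
    cost: float = SVM_COST,
    labels: pd.Series | None = None,
) -> list[IterationResult]:
    return [
        evaluate_iteration(table, metadata, tr, te, iteration=i, cost=cost, labels=labels)
        for i, (tr, te) in enumerate(plan.splits)
    ]


def average_roc(
    results: list[IterationResult], n_grid: int = ROC_GRID_POINTS
) -> tuple[pd.DataFrame, float]:
    """Vertical ROC averaging on a fixed FPR grid, plus the mean AUC.

    TPR is linearly interpolated at each grid FPR per iteration, then
    averaged with a per-point standard error of the mean.  The headline
    AUC is the arithmetic mean of the per-iteration rank AUCs.
    """
    if len(results) < 2:
        raise ValueError("average_roc needs at least 2 iterations")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.vstack([np.interp(grid, r.fpr, r.tpr) for r in results])
    mean = tprs.mean(axis=0)
    se = tprs.std(axis=0, ddof=1) / math.sqrt(len(results))
    roc = pd.DataFrame({"fpr": grid, "tpr_mean": mean, "tpr_se": se})
    mean_auc = float(np.mean([r.auc for r in results]))
    return roc, mean_auc


def permutation_null(
    table: FeatureTable,
    metadata: pd.DataFrame,
    n_iterations: int = N_ITERATIONS,
    train_fraction: float = TRAIN_FRACTION,
    master_seed: int = 0,
    cost: float = SVM_COST,
) -> NullResult:
    """The resampling procedure on independently label-shuffled data.

    Labels are re-shuffled before every iteration, the split is stratified
    on the shuffled labels, and the full fit/score/AUC step is repeated.
    The CI is the normal approximation mean ± 1.96·SD/√n.
    """
    meta = check_metadata(metadata, table.sample_ids)
    y = (meta["group"] == GROUP_CASE).astype(int)
    seeds = np.random.SeedSequence([master_seed, 1]).spawn(n_iterations)
    aucs = []
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        shuffled = pd.Series(
            rng.permutation(y.to_numpy()), index=y.index, name="label"
        )
        classes = [
            list(shuffled.index[shuffled == v]) for v in sorted(shuffled.unique())
        ]
        train, test = _stratified_split(classes, train_fraction, rng)
        res = evaluate_iteration(
            table, metadata, train, test, iteration=i, cost=cost, labels=shuffled
        )
        aucs.append(res.auc)
    aucs = np.asarray(aucs)
    mean = float(aucs.mean())
    half = 1.96 * aucs.std(ddof=1) / math.sqrt(len(aucs))
    return NullResult(aucs, mean, mean - half, mean + half)


def aggregate_importance(
    results: list[IterationResult],
    annotations: pd.DataFrame | None = None,
    top_n: int = TOP_N,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature average importance rank and the top-N fingerprint.

    ``annotations`` (a differential-abundance frame with feature_id,
    fold_change, p_value, q_value) is merged in when given.  Ties in
    average rank break by feature_id.
    """
    if not results:
        raise ValueError("no iteration results")
    ranks = pd.concat([r.importance_rank for r in results], axis=1)
    if ranks.isna().any().any():
        raise ValueError("iterations rank different feature sets")
    avg = ranks.mean(axis=1).rename("avg_rank").rename_axis("feature_id").reset_index()
    if annotations is not None:
        cols = [c for c in ("fold_change", "log2_fc", "p_value", "q_value") if c in annotations]
        avg = avg.merge(annotations[["feature_id", *cols]], on="feature_id", how="left")
    avg = avg.sort_values(["avg_rank", "feature_id"], kind="stable").reset_index(drop=True)
    return avg, avg.head(top_n).copy()


def run_fingerprint(
    table: FeatureTable,
    metadata: pd.DataFrame,
    master_seed: int = 0,
    n_iterations: int = N_ITERATIONS,
    train_fraction: float = TRAIN_FRACTION,
    cost: float = SVM_COST,
    top_n: int = TOP_N,
    annotations: pd.DataFrame | None = None,
    with_null: bool = True,
) -> FingerprintReport:
    """The whole classification stage as a pure function of its inputs."""
    plan = make_resample_plan(metadata, n_iterations, train_fraction, master_seed)
    results = run_iterations(table, metadata, plan, cost=cost)
    roc, mean_auc = average_roc(results)
    avg, top = aggregate_importance(results, annotations=annotations, top_n=top_n)
    null = None
    if with_null:
        null = permutation_null(
            table, metadata, n_iterations, train_fraction, master_seed, cost
        )
    return FingerprintReport(
        avg_rank=avg,
        top=top,
        iteration_aucs=np.array([r.auc for r in results]),
        mean_auc=mean_auc,
        roc=roc,
        null=null,
    )
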