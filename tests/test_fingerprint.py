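"""Resampled linear-SVM classification, ROC averaging, rank aggregation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from metabofp import (
    StudyDesign,
    aggregate_importance,
    average_roc,
    evaluate_iteration,
    fit_linear_svm,
    generate_dataset,
    make_resample_plan,
    permutation_null,
    preprocess,
    rank_auc,
    run_fingerprint,
)
from metabofp.fingerprint import IterationResult, run_iterations
from metabofp.tables import AUTOSCALED

from conftest import make_metadata, make_table


@pytest.fixture(scope="module")
def default_meta():
    return make_metadata(
        ["control"] * 12 + ["case"] * 8,
        sample_ids=[f"x{i:02d}" for i in range(20)],
    )


class TestResamplePlan:
    def test_default_design_split_sizes(self, default_meta):
        plan = make_resample_plan(default_meta, master_seed=0)
        groups = default_meta.set_index("sample_id")["group"]
        assert plan.n_iterations == 50
        for train, test in plan.splits:
            assert len(train) == 14 and len(test) == 6
            assert (groups.loc[list(train)] == "control").sum() == 8
            assert (groups.loc[list(test)] == "control").sum() == 4
            assert (groups.loc[list(test)] == "case").sum() == 2

    def test_partitions_disjoint_and_covering(self, default_meta):
        plan = make_resample_plan(default_meta, master_seed=1)
        everyone = set(default_meta["sample_id"])
        for train, test in plan.splits:
            assert set(train) | set(test) == everyone
            assert set(train) & set(test) == set()

    def test_same_seed_identical_plan(self, default_meta):
        a = make_resample_plan(default_meta, master_seed=5)
        b = make_resample_plan(default_meta, master_seed=5)
        assert a.splits == b.splits
        c = make_resample_plan(default_meta, master_seed=6)
        assert a.splits != c.splits

    def test_small_class_rejected(self):
        meta = make_metadata(["control"] * 8 + ["case"] * 3)
        with pytest.raises(ValueError, match="at least 4"):
            make_resample_plan(meta)


class TestLinearSvm:
    def test_symmetric_pair_boundary_at_zero(self):
        w, b = fit_linear_svm(np.array([[-1.0], [1.0]]), np.array([0, 1]))
        assert w[0] > 0
        assert b == pytest.approx(0.0, abs=1e-9)
        assert np.sign(np.array([[-1.0], [1.0]]) @ w + b).tolist() == [-1, 1]

    def test_hand_max_margin_solution(self):
        """Classes split by x=1 with margin 1: canonical w=(1,0), b=-1."""
        x = np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 2.0], [2.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        w, b = fit_linear_svm(x, y)
        assert np.allclose(w, [1.0, 0.0], atol=1e-6)
        assert b == pytest.approx(-1.0, abs=1e-6)

    def test_duplicated_features_split_weight_keep_scores(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(-2, 0.5, (8, 3)), rng.normal(2, 0.5, (8, 3))])
        y = np.repeat([0, 1], 8)
        w, b = fit_linear_svm(x, y)
        x_dup = np.hstack([x, x])
        w_dup, b_dup = fit_linear_svm(x_dup, y)
        assert np.allclose(x @ w + b, x_dup @ w_dup + b_dup, atol=1e-5)
        assert np.allclose(w_dup[:3], w / 2, atol=1e-5)
        assert np.allclose(w_dup[3:], w / 2, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_linear_svm(np.zeros((3, 2)), np.zeros(3))


class TestAuc:
    def test_rank_auc_equals_threshold_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(4, 12)
            labels = np.zeros(n, int)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = rng.choice(np.linspace(-2, 2, 7), size=n)  # with ties
            assert rank_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_granularity_exhaustive_4x2(self):
        """Tie-free 4-control/2-case test sets only allow AUC multiples of ⅛."""
        seen = set()
        scores = np.arange(6, dtype=float)
        for case_pos in combinations(range(6), 2):
            labels = np.zeros(6, int)
            labels[list(case_pos)] = 1
            auc = rank_auc(scores, labels)
            assert (8 * auc) == pytest.approx(round(8 * auc), abs=1e-12)
            seen.add(round(8 * auc))
        assert seen == set(range(9))


class TestEvaluateIteration:
    def _separable_setup(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(-1, 0.1, (12, 5)), rng.normal(1, 0.1, (8, 5))])
        table = make_table(x, scale=AUTOSCALED,
                           sample_ids=[f"x{i:02d}" for i in range(20)])
        meta = make_metadata(["control"] * 12 + ["case"] * 8,
                             sample_ids=table.sample_ids)
        return table, meta

    def test_separated_data_perfect_auc(self):
        table, meta = self._separable_setup()
        plan = make_resample_plan(meta, n_iterations=5, master_seed=0)
        for res in run_iterations(table, meta, plan):
            assert res.auc == 1.0

    def test_degenerate_scores_flagged_half(self):
        table = make_table(np.zeros((8, 3)), scale=AUTOSCALED)
        meta = make_metadata(["control"] * 4 + ["case"] * 4)
        train = ["s1", "s2", "s5", "s6"]  # both classes, all-zero features
        test = ["s3", "s4", "s7", "s8"]
        res = evaluate_iteration(table, meta, train, test)
        assert res.degenerate
        assert res.auc == 0.5

    def test_importance_ranks_are_permutation(self):
        table, meta = self._separable_setup()
        plan = make_resample_plan(meta, n_iterations=2, master_seed=1)
        res = run_iterations(table, meta, plan)[0]
        assert sorted(res.importance_rank) == list(range(1, 6))

    def test_reproducible_for_fixed_seed(self, preprocessed, default_dataset):
        scaled = preprocessed[0]
        _, metadata, _ = default_dataset
        a = run_fingerprint(scaled, metadata, master_seed=3, n_iterations=8,
                            with_null=False)
        b = run_fingerprint(scaled, metadata, master_seed=3, n_iterations=8,
                            with_null=False)
        assert np.array_equal(a.iteration_aucs, b.iteration_aucs)
        assert a.avg_rank.equals(b.avg_rank)


class TestAverageRoc:
    def _result(self, fpr, tpr, auc, i=0):
        n = 3
        return IterationResult(
            iteration=i,
            weights=pd.Series(np.ones(n)),
            bias=0.0,
            test_scores=pd.Series(np.arange(4.0)),
            test_labels=pd.Series([0, 0, 1, 1]),
            auc=auc,
            fpr=np.asarray(fpr, float),
            tpr=np.asarray(tpr, float),
            importance_rank=pd.Series(np.arange(1, n + 1)),
        )

    def test_identical_iterations_zero_se(self):
        r = self._result([0, 0, 1], [0, 1, 1], 1.0)
        roc, mean_auc = average_roc([r, r, r])
        assert mean_auc == 1.0
        assert np.allclose(roc["tpr_se"], 0.0)

    def test_mean_of_perfect_and_chance(self):
        perfect = self._result([0, 0, 1], [0, 1, 1], 1.0)
        chance = self._result([0, 1], [0, 1], 0.5)
        roc, mean_auc = average_roc([perfect, chance])
        assert mean_auc == 0.75

    def test_curve_area_close_to_mean_auc(self):
        """Vertical-average area matches mean AUC up to interpolation error."""
        rng = np.random.default_rng(5)
        results = []
        from sklearn.metrics import roc_curve

        for i in range(20):
            labels = np.array([0, 0, 0, 0, 1, 1])
            scores = rng.normal(size=6) + labels * rng.uniform(0, 2)
            fpr, tpr, _ = roc_curve(labels, scores)
            results.append(self._result(fpr, tpr, rank_auc(scores, labels), i))
        roc, mean_auc = average_roc(results)
        area = np.trapezoid(roc["tpr_mean"], roc["fpr"])
        assert abs(area - mean_auc) < 0.02

    def test_needs_two_iterations(self):
        r = self._result([0, 1], [0, 1], 0.5)
        with pytest.raises(ValueError):
            average_roc([r])


class TestPermutationNull:
    def test_long_run_mean_is_chance(self, preprocessed, default_dataset):
        scaled = preprocessed[0]
        _, metadata, _ = default_dataset
        means = [
            permutation_null(scaled, metadata, n_iterations=10, master_seed=s).mean
            for s in range(20)
        ]
        assert abs(np.mean(means) - 0.5) < 0.06

    def test_ci_contains_its_mean(self, preprocessed, default_dataset):
        scaled = preprocessed[0]
        _, metadata, _ = default_dataset
        null = permutation_null(scaled, metadata, n_iterations=20, master_seed=0)
        assert null.ci_low <= null.mean <= null.ci_high

    def test_no_signal_data_true_labels_match_null(self):
        """Without informative features the true-label AUC is also chance."""
        table, metadata, _ = generate_dataset(
            StudyDesign(n_features=40, n_high_missing=0, n_up=0, n_down=0, seed=8)
        )
        scaled = preprocess(table, metadata)[0]
        truth_means = [
            run_fingerprint(scaled, metadata, master_seed=s, n_iterations=10,
                            with_null=False).mean_auc
            for s in range(10)
        ]
        assert abs(np.mean(truth_means) - 0.5) < 0.1


class TestAggregateImportance:
    def _manual_result(self, weights, i):
        from scipy.stats import rankdata

        w = pd.Series(weights, index=[f"f{j + 1}" for j in range(len(weights))])
        return IterationResult(
            iteration=i, weights=w, bias=0.0,
            test_scores=pd.Series(dtype=float), test_labels=pd.Series(dtype=int),
            auc=1.0, fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
            importance_rank=pd.Series(rankdata(-np.abs(w)), index=w.index),
        )

    def test_always_first_feature(self):
        results = [self._manual_result([9.0, 1.0, 2.0], i) for i in range(5)]
        avg, top = aggregate_importance(results, top_n=2)
        assert top.iloc[0]["feature_id"] == "f1"
        assert top.iloc[0]["avg_rank"] == 1.0

    def test_two_iteration_hand_average(self):
        # |weights| ranks: iter0 -> f1:1, f3:2, f2:3 ; iter1 -> f2:1, f3:2, f1:3
        results = [
            self._manual_result([5.0, 1.0, 3.0], 0),
            self._manual_result([-1.0, 6.0, 2.0], 1),
        ]
        avg, _ = aggregate_importance(results, top_n=3)
        expected = {"f1": 2.0, "f2": 2.0, "f3": 2.0}
        got = dict(zip(avg["feature_id"], avg["avg_rank"]))
        assert got == expected
        # tie on avg_rank broken by feature_id
        assert list(avg["feature_id"]) == ["f1", "f2", "f3"]

    def test_top25_dominated_by_strongest_designed_effects(self):
        """The fingerprint picks true effects, preferentially the strongest.

        Every top-25 feature is designed-differential, and on average ≥20
        of the 25 fall within the 50 largest designed standardized effects
        (|log2 FC| / noise SD) — many designed effects sit close together,
        so exact top-25-to-top-25 identity is not expected.
        """
        overlaps = []
        for seed in range(5):
            table, metadata, truth = generate_dataset(StudyDesign(seed=seed))
            scaled = preprocess(table, metadata)[0]
            rep = run_fingerprint(scaled, metadata, master_seed=seed, with_null=False)
            strength = (
                np.abs(np.log2(truth["fold_change"])) / truth["noise_sd_log"]
            )
            strongest50 = set(truth.loc[strength.nlargest(50).index, "feature_id"])
            true_ids = set(truth.loc[truth["is_differential"], "feature_id"])
            top = set(rep.top["feature_id"])
            assert top <= true_ids
            overlaps.append(len(strongest50 & top))
        assert np.mean(overlaps) >= 20


class TestSignalVsNull:
    def test_signal_auc_exceeds_null_upper_ci(self):
        """True-label mean AUC clears the permutation-null CI on every run."""
        for seed in range(8):
            table, metadata, _ = generate_dataset(StudyDesign(seed=seed))
            scaled = preprocess(table, metadata)[0]
            rep = run_fingerprint(scaled, metadata, master_seed=seed)
            assert rep.mean_auc > rep.null.ci_high

    def test_null_calibration_on_pure_noise(self):
        """On null data the true labels beat the null 97.5th pct ≤7% of runs."""
        exceed = 0
        n_seeds = 40
        for seed in range(n_seeds):
            table, metadata, _ = generate_dataset(
                StudyDesign(n_features=40, n_high_missing=0, n_up=0, n_down=0,
                            seed=500 + seed)
            )
            scaled = preprocess(table, metadata)[0]
            rep = run_fingerprint(scaled, metadata, master_seed=seed,
                                  n_iterations=20)
            exceed += rep.mean_auc > np.quantile(rep.null.aucs, 0.975)
        assert exceed / n_seeds <= 0.07
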