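import numpy as np
import pandas as pd
import pytest

from fidgetquant import (
    ConfigurationError,
    CVConfig,
    ModelSpec,
    compute_metrics,
    nested_cv,
    rank_features,
    rank_models,
    sem,
    summarize,
)
from .oracles import naive_auc, naive_metrics


def separable_feature(rng, n_pos=20, n_neg=20, gap=10.0):
    x = np.concatenate([rng.normal(gap, 1, n_pos), rng.normal(0, 1, n_neg)])
    y = np.array(["pos"] * n_pos + ["neg"] * n_neg)
    return x, y


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        # (TP, FN, TN, FP) = (9, 1, 8, 2)
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        m = compute_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_scores_equal_to_labels_give_auc_one(self):
        y = np.array([0, 1, 0, 1, 1])
        m = compute_metrics(y, y, scores=y.astype(float))
        assert m["auc"] == 1.0

    def test_random_scores_auc_near_half(self, rng):
        """AUC of noise scores is within 3 SE of 0.5 (Mann-Whitney null)."""
        n = 1000
        y = rng.integers(0, 2, n)
        scores = rng.normal(size=n)
        m = compute_metrics(y, y, scores=scores)
        n1, n0 = y.sum(), n - y.sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(m["auc"] - 0.5) <= 3 * se

    def test_matches_naive_oracles(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            scores = rng.normal(size=n)
            m = compute_metrics(y_true, y_pred, scores)
            acc, sens, spec = naive_metrics(y_true.tolist(), y_pred.tolist())
            assert m["accuracy"] == pytest.approx(acc)
            for got, ref in ((m["sensitivity"], sens), (m["specificity"], spec)):
                assert (np.isnan(got) and np.isnan(ref)) or got == pytest.approx(ref)
            auc_ref = naive_auc(y_true.tolist(), scores.tolist())
            assert (np.isnan(m["auc"]) and np.isnan(auc_ref)) or m[
                "auc"
            ] == pytest.approx(auc_ref)

    def test_single_class_fold_yields_nan_not_crash(self):
        y = np.ones(5, dtype=int)
        m = compute_metrics(y, y, scores=np.ones(5))
        assert m["accuracy"] == 1.0
        assert np.isnan(m["specificity"]) and np.isnan(m["auc"])


class TestSem:
    def test_constant_values(self):
        assert sem(np.full(100, 0.9)) == pytest.approx(0.0, abs=1e-15)

    def test_unit_sd_over_100(self, rng):
        v = rng.normal(size=100)
        v = (v - v.mean()) / v.std(ddof=1)  # exactly sigma = 1
        assert sem(v) == pytest.approx(0.1)

    def test_matches_two_pass_oracle(self, rng):
        v = rng.gamma(2, 3, size=57)
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        assert sem(v) == pytest.approx(sd / len(v) ** 0.5, rel=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ConfigurationError):
            sem(np.array([1.0]))


class TestNestedCV:
    def test_exactly_100_iterations_at_defaults(self, rng):
        x, y = separable_feature(rng, 43, 42)
        perf = nested_cv(x, y, "decision_tree_cart", CVConfig(seed=0))
        assert len(perf) == 100
        assert perf["iteration"].tolist() == list(range(1, 101))

    def test_perfect_separation_classified_perfectly(self, rng):
        """A wide-margin 1-D feature needs only one threshold: every
        iteration of a depth-limited tree scores accuracy 1."""
        x, y = separable_feature(rng, 20, 20, gap=50.0)
        perf = nested_cv(x, y, "decision_tree_cart", CVConfig(repeats=2, seed=1))
        assert np.all(perf["accuracy"] == 1.0)
        assert np.all(perf["auc"] == 1.0)

    def test_permuted_labels_auc_near_chance(self, rng):
        """Label-permutation null: mean AUC within 3 SEM of 0.5. Averaged
        over permutations, since any single permutation keeps a chance
        association with the feature."""
        x, y = separable_feature(rng, 25, 25, gap=3.0)
        perm_rng = np.random.default_rng(4)
        means = []
        for i in range(10):
            y_perm = perm_rng.permutation(y)
            perf = nested_cv(
                x, y_perm, "decision_tree_cart", CVConfig(repeats=2, seed=4 + i)
            )
            means.append(perf["auc"].dropna().mean())
        means = np.array(means)
        assert abs(means.mean() - 0.5) <= max(3 * sem(means), 0.05)

    def test_deterministic_under_fixed_seed(self, rng):
        x, y = separable_feature(rng, 12, 12, gap=2.0)
        cv = CVConfig(repeats=2, seed=7)
        a = nested_cv(x, y, "decision_tree_cart", cv)
        b = nested_cv(x, y, "decision_tree_cart", cv)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            nested_cv(np.arange(10.0), np.zeros(10), "knn", CVConfig())

    def test_constant_feature_warns_but_runs(self, rng):
        y = np.array(["pos", "neg"] * 15)
        with pytest.warns(UserWarning, match="constant"):
            perf = nested_cv(np.ones(30), y, "knn", CVConfig(repeats=1, seed=0))
        assert len(perf) == 10
        assert perf["accuracy"].between(0, 1).all()

    def test_accuracy_is_prevalence_weighted_convex_combination(self, rng):
        """Per fold: acc = prev * sens + (1 - prev) * spec. Verified by
        re-deriving the confusion counts from the stored fold metrics."""
        x, y = separable_feature(rng, 13, 17, gap=2.0)
        cv = CVConfig(repeats=1, seed=3)
        perf = nested_cv(x, y, "knn", cv)
        # reconstruct fold sizes from stratified 10-fold of 13/17
        from sklearn.model_selection import StratifiedKFold

        y_bin = (y == "pos").astype(int)
        folds = StratifiedKFold(10, shuffle=True, random_state=cv.seed).split(x, y_bin)
        for (_, te), (_, row) in zip(folds, perf.iterrows()):
            n_pos = y_bin[te].sum()
            prev = n_pos / len(te)
            expected = prev * row["sensitivity"] + (1 - prev) * row["specificity"]
            assert row["accuracy"] == pytest.approx(expected, abs=1e-12)

    def test_outer_folds_partition_cohort(self, rng):
        """Within one repeat the outer test folds are disjoint and cover all
        subjects; no subject is in both train and test of one iteration."""
        from sklearn.model_selection import StratifiedKFold

        x, y = separable_feature(rng, 43, 42)
        y_bin = (y == "pos").astype(int)
        seen = []
        for tr, te in StratifiedKFold(10, shuffle=True, random_state=0).split(x, y_bin):
            assert set(tr).isdisjoint(te)
            seen.extend(te)
        assert sorted(seen) == list(range(85))


def _toy_perf():
    """Hand-built performance records: feature A dominates everywhere."""
    rows = []
    for model in ("m1", "m2"):
        for feature, acc in (("A", 0.9), ("B", 0.7), ("C", 0.5)):
            for it in range(3):
                rows.append(
                    {
                        "model": model,
                        "feature": feature,
                        "iteration": it,
                        "accuracy": acc,
                        "sensitivity": acc,
                        "specificity": acc,
                        "auc": acc,
                    }
                )
    return pd.DataFrame(rows)


class TestRanking:
    def test_dominant_feature_ranks_first_everywhere(self):
        ranks = rank_features(_toy_perf())
        assert np.all(ranks.loc["A"] == 1.0)
        assert np.all(ranks.loc["C"] == 3.0)

    def test_exact_tie_shares_average_rank(self):
        perf = _toy_perf()
        perf.loc[perf["feature"] == "B", ["accuracy"]] = 0.9  # tie with A
        ranks = rank_features(perf)
        assert ranks.loc["A", "accuracy"] == 1.5
        assert ranks.loc["B", "accuracy"] == 1.5

    def test_missing_cell_rejected(self):
        perf = _toy_perf()
        perf = perf[~((perf["model"] == "m2") & (perf["feature"] == "C"))]
        with pytest.raises(ConfigurationError, match="missing"):
            rank_features(perf)

    def test_rank_models_matches_brute_force_sort(self):
        perf = _toy_perf()
        rng = np.random.default_rng(0)
        perf["accuracy"] += rng.normal(0, 0.01, len(perf))
        ranks = rank_models(perf, "A")
        sub = perf[perf["feature"] == "A"]
        means = sub.groupby("model")["accuracy"].mean().sort_values(ascending=False)
        assert ranks["accuracy"].idxmin() == means.index[0]

    def test_model_ranks_are_permutation_without_ties(self):
        ranks = rank_models(_toy_perf(), "A")
        # two models, distinct? equal means here -> tie 1.5 each
        assert sorted(ranks["accuracy"].tolist()) == [1.5, 1.5]

    def test_entropy_constructed_most_discriminative_ranks_first(self, rng):
        """On a cohort built so entropy separates best, entropy's average
        accuracy rank is 1.0."""
        from fidgetquant import evaluate_features

        n = 30
        df = pd.DataFrame(
            {
                "label": ["pos"] * (n // 2) + ["neg"] * (n // 2),
                "mu": rng.normal(0, 1, n),                       # noise
                "var_bar": np.abs(rng.normal(0, 1, n)) + 0.5,    # noise
                "se_bar": np.r_[rng.normal(8, 0.5, n // 2), rng.normal(0, 0.5, n // 2)],
            }
        )
        cv = CVConfig(outer_folds=5, inner_folds=3, repeats=1, seed=2)
        perf = evaluate_features(
            df, ["mu", "var_bar", "se_bar"], ["decision_tree_cart", "knn"], cv
        )
        ranks = rank_features(perf)
        assert ranks.loc["se_bar", "accuracy"] == 1.0


class TestSummarize:
    def test_mean_and_sem_per_cell(self):
        perf = _toy_perf()
        summary = summarize(perf)
        row = summary[(summary["model"] == "m1") & (summary["feature"] == "A")]
        assert row["accuracy_mean"].iloc[0] == pytest.approx(0.9)
        assert row["accuracy_sem"].iloc[0] == pytest.approx(0.0)
        assert row["accuracy_n_missing"].iloc[0] == 0

    def test_nan_metrics_counted_missing(self):
        perf = _toy_perf()
        perf.loc[0, "auc"] = np.nan
        summary = summarize(perf)
        row = summary[(summary["model"] == "m1") & (summary["feature"] == "A")]
        assert row["auc_n_missing"].iloc[0] == 1
        assert row["auc_mean"].iloc[0] == pytest.approx(0.9)


class TestModelSpec:
    def test_published_grids_are_default(self):
        assert ModelSpec("svm_rbf").grid == {
            "gamma": [50, 100, 300, 500],
            "C": [0.001, 0.01, 0.1, 1],
        }
        assert ModelSpec("xgboost_cart").grid["n_estimators"] == [1, 5, 10, 20]

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("neural_net")

    def test_grid_override(self):
        spec = ModelSpec("knn", {"n_neighbors": [3]})
        assert spec.grid == {"n_neighbors": [3]}

    @pytest.mark.parametrize(
        "family", ["svm_rbf", "random_forest", "knn", "adaboost_cart", "xgboost_cart"]
    )
    def test_every_family_runs_one_repeat(self, rng, family):
        x, y = separable_feature(rng, 10, 10, gap=6.0)
        small_grid = {k: v[:2] for k, v in ModelSpec(family).grid.items()}
        perf = nested_cv(
            x, y, ModelSpec(family, small_grid),
            CVConfig(outer_folds=5, inner_folds=3, repeats=1, seed=0),
        )
        assert len(perf) == 5
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            assert perf[metric].dropna().between(0, 1).all()
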