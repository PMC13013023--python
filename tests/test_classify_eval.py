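import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from branchflow.classify_eval import (
    METHODS,
    balance_cohort,
    fit_predict,
    image_accuracy,
    report_table,
    roc_auc_ci,
    run_comparison,
    split_by_image,
)
from branchflow.pipeline import cohort_feature_tables
from branchflow.synthetic_data import ArborSpec, CohortSpec


def toy_tables(n_cells=4, beta_a=0.3, beta_b=0.8, sd=0.05, depth=3, seed=0):
    """Two-class cohort with configurable separation."""
    spec_a = ArborSpec(depth=depth, beta_mean_profile=beta_a, beta_diff_profile=0.05,
                       noise_sd=sd, seed=0)
    spec_b = ArborSpec(depth=depth, beta_mean_profile=beta_b, beta_diff_profile=0.05,
                       noise_sd=sd, seed=0)
    cohort = CohortSpec(class_specs={"A": spec_a, "B": spec_b},
                        n_cells_per_class=n_cells, seed=seed)
    return cohort_feature_tables(cohort)


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: fraction of positive/negative pairs ranked correctly."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestBalance:
    def tables(self, n_a, n_b):
        rng = np.random.default_rng(0)
        out = {}
        for lab, n in (("A", n_a), ("B", n_b)):
            out[lab] = pd.DataFrame({
                "cell_id": [f"{lab}{i}" for i in range(n) for _ in range(3)],
                "label": lab,
                "beta_mean": rng.uniform(0.4, 0.8, 3 * n),
                "beta_diff": rng.uniform(-0.1, 0.1, 3 * n),
                "rel_leaf_number": rng.integers(0, 4, 3 * n).astype(float),
            })
        return out

    def test_subsamples_larger_class_cells(self):
        out = balance_cohort(self.tables(12, 5), seed=0)
        assert out["A"]["cell_id"].nunique() == 5
        assert out["B"]["cell_id"].nunique() == 5

    def test_identity_when_balanced(self):
        tabs = self.tables(4, 4)
        out = balance_cohort(tabs, seed=0)
        assert out["A"].equals(tabs["A"]) and out["B"].equals(tabs["B"])

    def test_deterministic_given_seed(self):
        a = balance_cohort(self.tables(12, 5), seed=9)
        b = balance_cohort(self.tables(12, 5), seed=9)
        assert set(a["A"]["cell_id"]) == set(b["A"]["cell_id"])


class TestSplit:
    def test_three_one_split_at_075(self):
        tables = toy_tables(n_cells=4)
        plan = split_by_image(tables, 0.75, seed=0)
        for lab in ("A", "B"):
            cells = set(tables[lab]["cell_id"].unique())
            assert len(cells & plan.train_cells) == 3
            assert len(cells & plan.test_cells) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_disjoint_and_covering_over_seeds(self, seed):
        tables = toy_tables(n_cells=5)
        plan = split_by_image(tables, 0.7, seed=seed)
        assert not (plan.train_cells & plan.test_cells)
        all_cells = set(pd.concat(tables.values())["cell_id"])
        assert plan.train_cells | plan.test_cells == all_cells

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_by_image(toy_tables(), train_fraction=1.0)


class TestRocAucCi:
    def test_perfect_and_tied_scores(self):
        auc, lo, hi, _ = roc_auc_ci([0.9, 0.1], [1, 0])
        assert auc == 1.0
        auc, lo, hi, _ = roc_auc_ci([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ci([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        labels = np.r_[np.ones(n // 2 + 1, int), np.zeros(n // 2 + 1, int)]
        scores = np.round(rng.uniform(0, 1, len(labels)), 1)  # force ties
        auc, lo, hi, _ = roc_auc_ci(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert lo <= auc <= hi

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (40, 400):
            labels = np.r_[np.ones(n, int), np.zeros(n, int)]
            scores = rng.normal(labels * 0.5, 1.0)
            _, lo, hi, _ = roc_auc_ci(scores, labels)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 2  # ~ sqrt(10) shrink expected

    def test_roc_points_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.uniform(0, 1, 50)
        *_, roc = roc_auc_ci(scores, labels)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()
        assert roc[0].tolist() == [0.0, 0.0] and roc[-1].tolist() == [1.0, 1.0]


class TestFitPredict:
    def split_frames(self, tables, seed=0):
        plan = split_by_image(tables, 0.75, seed=seed)
        rows = pd.concat(tables.values(), ignore_index=True)
        train = rows[rows["cell_id"].isin(plan.train_cells)].reset_index(drop=True)
        test = rows[rows["cell_id"].isin(plan.test_cells)].reset_index(drop=True)
        return train, test

    def test_disjoint_supports_give_auc_one_for_every_method(self):
        train, test = self.split_frames(toy_tables(beta_a=0.3, beta_b=0.8, sd=0.02))
        for method in METHODS:
            res = fit_predict(train, test, method, "2d", seed=0)
            assert res.auc == 1.0, method

    def test_single_class_training_rejected(self):
        train, test = self.split_frames(toy_tables())
        with pytest.raises(ValueError):
            fit_predict(train[train["label"] == "A"], test, "LR")

    def test_nan_features_rejected(self):
        train, test = self.split_frames(toy_tables())
        train = train.copy()
        train.loc[0, "beta_mean"] = np.nan
        with pytest.raises(ValueError):
            fit_predict(train, test, "LR")

    def test_knn_records_selected_k(self):
        train, test = self.split_frames(toy_tables(n_cells=6))
        res = fit_predict(train, test, "KNN", "2d", seed=1)
        assert res.knn_k is not None and 1 <= res.knn_k <= 51 and res.knn_k % 2 == 1


class TestImageAccuracy:
    def frame(self, cells):
        rows = []
        for cid, label, n in cells:
            rows += [{"cell_id": cid, "label": label}] * n
        return pd.DataFrame(rows)

    def test_all_rows_correct_means_all_cells_correct(self):
        test = self.frame([("a", "pos", 3), ("b", "neg", 2)])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        assert image_accuracy(scores, test, "pos") == (2, 2)

    def test_majority_two_of_three_counts_correct(self):
        test = self.frame([("a", "pos", 3)])
        assert image_accuracy(np.array([0.9, 0.9, 0.1]), test, "pos") == (1, 1)

    def test_exact_tie_called_negative(self):
        test = self.frame([("a", "pos", 2)])
        assert image_accuracy(np.array([0.9, 0.1]), test, "pos") == (0, 1)


class TestRunComparison:
    def test_fourteen_results_and_no_leakage(self):
        tables = toy_tables(n_cells=4)
        report = run_comparison(tables, seed=0, methods=("LR", "RF"))
        assert len(report["results"]) == 4  # 2 methods x 2 modes here
        assert not (report["split"].train_cells & report["split"].test_cells)
        full = run_comparison(tables, seed=0)
        assert len(full["results"]) == 14

    def test_rerun_reproduces_auc_table(self):
        tables = toy_tables(n_cells=4)
        t1 = report_table(run_comparison(tables, seed=5, methods=("RF", "KNN")))
        t2 = report_table(run_comparison(tables, seed=5, methods=("RF", "KNN")))
        pd.testing.assert_frame_equal(t1, t2)
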