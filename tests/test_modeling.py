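"""Feature selection, metrics, AUC, repeated CV and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegmci.errors import InvalidConfigError, InvalidInputError
from eegmci.modeling import (
    CLASSIFIER_NAMES,
    ConfusionCounts,
    _fit_fold,
    auc_rank,
    compute_metrics,
    f_statistic,
    make_classifier,
    mann_whitney_map,
    repeated_cv,
    select_top_k,
    summary_grid,
)


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive pair-counting oracle: ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFStatistic:
    def test_identical_groups_zero(self):
        x = np.tile(np.arange(5.0), 2)[:, None]
        y = np.repeat([0, 1], 5)
        assert f_statistic(x, y)[0] == pytest.approx(0.0)

    def test_equals_squared_t(self, rng):
        x = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        while len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
            y = rng.integers(0, 2, size=30)
        t, _ = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=True)
        assert f_statistic(x[:, None], y)[0] == pytest.approx(t**2)

    def test_matches_scipy_anova_many_features(self, rng):
        x = rng.normal(size=(40, 25))
        y = np.r_[np.zeros(22, int), np.ones(18, int)]
        ours = f_statistic(x, y)
        ref = np.array([stats.f_oneway(x[y == 0, j], x[y == 1, j]).statistic
                        for j in range(25)])
        assert np.allclose(ours, ref)

    def test_perfect_separator_ranks_first(self, rng):
        noise = rng.normal(size=(20, 10))
        y = np.repeat([0, 1], 10)
        noise[:, 4] = y * 10 + rng.normal(scale=0.1, size=20)
        sel = select_top_k(noise, y, k=1)
        assert sel.retained.tolist() == [4]

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            f_statistic(rng.normal(size=(10, 2)), np.zeros(10, int))


class TestSelectTopK:
    def test_retains_exactly_100_of_1968(self, rng):
        x = rng.normal(size=(40, 1968))
        y = np.repeat([0, 1], 20)
        sel = select_top_k(x, y, k=100)
        assert sel.retained.size == 100

    def test_k_clipped_to_feature_count(self, rng):
        x = rng.normal(size=(20, 7))
        sel = select_top_k(x, np.repeat([0, 1], 10), k=100)
        assert sel.retained.size == 7

    def test_deterministic_tie_break(self):
        x = np.repeat(np.arange(6.0)[:, None], 4, axis=1)  # identical columns
        y = np.array([0, 0, 0, 1, 1, 1])
        sel = select_top_k(x, y, k=2)
        assert sel.retained.tolist() == [0, 1]

    def test_invalid_k(self, rng):
        with pytest.raises(InvalidConfigError):
            select_top_k(rng.normal(size=(10, 3)), np.repeat([0, 1], 5), k=0)


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=9, fn=1, fp=2, tn=18))
        assert m["ACC"] == pytest.approx(0.9000, abs=1e-4)
        assert m["SEN"] == pytest.approx(0.9000, abs=1e-4)
        assert m["SPE"] == pytest.approx(0.9000, abs=1e-4)
        assert m["PPV"] == pytest.approx(0.8182, abs=1e-4)
        assert m["F1"] == pytest.approx(0.8571, abs=1e-4)

    def test_all_correct(self):
        m = compute_metrics(ConfusionCounts(tp=5, fn=0, fp=0, tn=7))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_symmetric_errors_give_half(self):
        m = compute_metrics(ConfusionCounts(tp=3, fn=3, fp=4, tn=4))
        assert m["ACC"] == pytest.approx(0.5)

    def test_f1_is_harmonic_mean(self):
        m = compute_metrics(ConfusionCounts(tp=7, fn=2, fp=3, tn=10))
        hm = 2 * m["SEN"] * m["PPV"] / (m["SEN"] + m["PPV"])
        assert m["F1"] == pytest.approx(hm)

    def test_undefined_ppv_reported_as_nan(self):
        m = compute_metrics(ConfusionCounts(tp=0, fn=4, fp=0, tn=6))
        assert np.isnan(m["PPV"])

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=5)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_toy_example_three_of_four_pairs(self):
        assert auc_rank([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 50))
    def test_matches_pair_counting_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        r.shuffle(labels)
        scores = np.round(r.normal(size=n), 1)  # rounding forces ties
        assert auc_rank(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert auc_rank(np.exp(scores), labels) == pytest.approx(auc_rank(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            auc_rank([0.1, 0.2], [1, 1])


def random_table(n=40, p=60, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(size=(n, p))
    x[y == 1, : p // 4] += effect
    cols = [f"f{i}__MF" for i in range(p)]
    table = pd.DataFrame(x, columns=cols,
                         index=[f"S{i:02d}" for i in range(n)])
    table.insert(0, "label", y)
    return table


class TestRepeatedCv:
    def test_scheme_arithmetic_and_coverage(self):
        table = random_table()
        report = repeated_cv(table, classifier="NB", folds=5, repeats=3, k=10, seed=1)
        assert len(report.folds) == 15
        for rep in range(3):
            tested = np.concatenate(
                [f.test_indices for f in report.folds if f.repeat == rep])
            assert sorted(tested.tolist()) == list(range(len(table)))

    def test_reproducible_from_seed(self):
        table = random_table(effect=1.0)
        a = repeated_cv(table, "SVM", folds=4, repeats=2, k=10, seed=3)
        b = repeated_cv(table, "SVM", folds=4, repeats=2, k=10, seed=3)
        assert a.summary() == b.summary()

    def test_informative_features_learned(self):
        table = random_table(effect=2.5, seed=5)
        report = repeated_cv(table, "SVM", folds=5, repeats=2, k=15, seed=5)
        assert report.summary()["ACC"]["mean"] > 0.85

    def test_null_table_accuracy_within_chance_band(self):
        # no signal at all: mean accuracy must stay inside the 95% binomial
        # band around the majority-class rate (leakage would inflate it)
        table = random_table(n=40, p=60, seed=9, effect=0.0)
        accs = []
        for clf in ("SVM", "NB"):
            rep = repeated_cv(table, clf, folds=5, repeats=3, k=10, seed=11)
            accs.append(rep.summary()["ACC"]["mean"])
        majority = 0.5
        half_width = 1.96 * np.sqrt(majority * (1 - majority) / len(table))
        for acc in accs:
            assert acc < majority + half_width

    def test_selection_ignores_test_rows(self):
        table = random_table(effect=1.0, seed=2)
        x = table.drop(columns="label").to_numpy()
        y = table["label"].to_numpy()
        tr, te = np.arange(0, 30), np.arange(30, 40)
        scaler1, sel1, _ = _fit_fold(x[tr], y[tr], make_classifier("NB"), k=10)
        x2 = x.copy()
        x2[te] = np.random.default_rng(0).normal(size=(10, x.shape[1])) * 100
        scaler2, sel2, _ = _fit_fold(x2[tr], y[tr], make_classifier("NB"), k=10)
        assert np.array_equal(sel1.retained, sel2.retained)
        assert np.allclose(scaler1.mean_, scaler2.mean_)

    def test_too_few_subjects_per_class_rejected(self):
        table = random_table(n=6)
        with pytest.raises(InvalidConfigError):
            repeated_cv(table, "NB", folds=5, repeats=1, k=5, seed=0)

    def test_all_eight_classifiers_instantiate(self):
        for name in CLASSIFIER_NAMES:
            assert make_classifier(name, seed=0) is not None
        with pytest.raises(InvalidConfigError):
            make_classifier("MLP")

    def test_summary_grid_shape(self):
        table = random_table(effect=2.0)
        reports = {name: repeated_cv(table, name, folds=4, repeats=1, k=10, seed=0)
                   for name in ("NB", "KNN")}
        grid = summary_grid(reports)
        assert grid.shape == (2, 12)
        assert "ACC_mean" in grid.columns


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = pd.DataFrame({"A__ch": np.ones(20)})
        pmap = mann_whitney_map(x, np.repeat([0, 1], 10))
        assert pmap.loc["A__ch", "p"] == pytest.approx(1.0)

    def test_fully_separated_minimal_p(self):
        x = pd.DataFrame({"A__ch": np.r_[np.arange(10), np.arange(100, 110)]})
        pmap = mann_whitney_map(x, np.repeat([0, 1], 10))
        assert pmap.loc["A__ch", "U"] in (0.0, 100.0)
        assert pmap.loc["A__ch", "p"] < 2e-4

    def test_type_one_error_near_nominal(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 300)),
                         columns=[f"N__c{i}" for i in range(300)])
        pmap = mann_whitney_map(x, np.repeat([0, 1], 20))
        frac = (pmap["p"] < 0.05).mean()
        assert 0.005 < frac < 0.12

    def test_bh_correction_column(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("ABCDE"))
        pmap = mann_whitney_map(x, np.repeat([0, 1], 10), correction="bh")
        assert "p_bh" in pmap.columns
        assert (pmap["p_bh"] >= pmap["p"] - 1e-12).all()

    def test_channel_parsing(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 1)), columns=["Ratio2__O1"])
        pmap = mann_whitney_map(x, np.repeat([0, 1], 5))
        assert pmap.loc["Ratio2__O1", "kind"] == "Ratio2"
        assert pmap.loc["Ratio2__O1", "channel"] == "O1"
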