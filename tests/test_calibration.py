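"""Calibration method: binarization, TSS, the algorithm suite, projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predchar import calibration as cal
from predchar.types import DomainError, ValidationError


class TestBinarizeDsr:
    def test_first_decile_of_ten_values(self):
        df = pd.DataFrame({"dsr": np.arange(0, 100, 10, dtype=float)})
        out = cal.binarize_dsr(df, quantile=0.10)
        assert out.attrs["n_resistant"] == 1
        assert out["resistant"].tolist() == [True] + [False] * 9

    def test_quantile_zero_gives_no_resistant(self):
        df = pd.DataFrame({"dsr": np.linspace(0, 90, 20)})
        out = cal.binarize_dsr(df, quantile=0.0)
        assert out.attrs["n_resistant"] == 0

    def test_counts_partition_the_records(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"dsr": rng.uniform(0, 100, 204)})
        out = cal.binarize_dsr(df)
        assert out.attrs["n_resistant"] + out.attrs["n_sensitive"] == 204
        assert out.attrs["n_resistant"] <= int(np.ceil(0.10 * 204))

    def test_degenerate_distribution_rejected(self):
        df = pd.DataFrame({"dsr": [50.0] * 20})
        with pytest.raises(DomainError):
            cal.binarize_dsr(df)

    def test_boundary_ties_excluded_by_strict_inequality(self):
        # values equal to the decile threshold are sensitive, not resistant
        dsr = np.array([1.0, 2.0, 25.0, 25.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0])
        df = pd.DataFrame({"dsr": dsr})
        out = cal.binarize_dsr(df, quantile=0.10)
        thr = out.attrs["dsr_threshold"]
        assert (out["resistant"] == (dsr < thr)).all()
        assert not out.loc[np.isclose(dsr, thr), "resistant"].any()


class TestTss:
    def test_perfect_confusion(self):
        assert cal.tss(10, 0, 10, 0) == pytest.approx(1.0)

    def test_predict_all_one_class_scores_zero(self):
        assert cal.tss(10, 0, 0, 10) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        assert cal.tss(3, 1, 4, 2) == pytest.approx(0.75 + 2 / 3 - 1)

    def test_empty_true_class_undefined(self):
        with pytest.raises(DomainError):
            cal.tss(0, 0, 5, 5)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        tp=st.integers(0, 20), fn=st.integers(0, 20),
        tn=st.integers(0, 20), fp=st.integers(0, 20),
    )
    def test_class_swap_symmetry(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        assert cal.tss(tp, fn, tn, fp) == pytest.approx(cal.tss(tn, fp, tp, fn))


class TestPerformanceBins:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.05, "Fail"),
            (-0.3, "Fail"),
            (0.2, "Poor"),
            (0.54, "Fair"),
            (0.58, "Fair"),
            (0.588, "Fair"),
            (0.6, "Good"),
            (0.828, "Excellent"),
            (1.0, "Excellent"),
        ],
    )
    def test_bins(self, value, expected):
        assert cal.classify_performance(value) == expected


class TestSurfaceRangeEnvelope:
    def test_training_presence_inside_envelope(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        model = cal.sre_envelope(X, quantile_pair=(0.0, 1.0))
        assert np.all(model.suitability(X) == 1.0)

    def test_far_point_scores_zero(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        model = cal.sre_envelope(X)
        assert model.suitability(np.full((1, 3), 100.0))[0] == 0.0

    def test_quantile_bounds_on_one_to_hundred(self):
        X = np.arange(1, 101, dtype=float).reshape(-1, 1)
        model = cal.sre_envelope(X, quantile_pair=(0.025, 0.975))
        assert model.suitability([[50.0]])[0] == 1.0
        assert model.suitability([[200.0]])[0] == 0.0

    def test_suitability_is_fraction_of_variables_inside(self):
        X = np.tile(np.arange(1, 101, dtype=float).reshape(-1, 1), (1, 2))
        model = cal.sre_envelope(X)
        assert model.suitability([[50.0, 200.0]])[0] == pytest.approx(0.5)

    def test_too_few_presences_rejected(self):
        with pytest.raises(DomainError):
            cal.sre_envelope(np.ones((1, 2)))


def separable_records(n=120, seed=0, informative_x2=False):
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n // 4, dtype=int), np.zeros(n - n // 4, dtype=int)])
    x1 = np.where(y == 1, 5.0, -5.0) + 0.1 * rng.normal(size=n)
    if informative_x2:
        x2 = np.where(y == 1, 4.0, -4.0) + 0.1 * rng.normal(size=n)
    else:
        x2 = rng.normal(size=n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "dsr": np.where(y == 1, 1.0, 80.0)})
    df["resistant"] = y.astype(bool)
    return df


class TestTrainSuite:
    def test_perfectly_separable_data_high_tss(self):
        df = separable_records(informative_x2=True)
        _, summaries = cal.train_suite(df, ["x1", "x2"], n_runs=5, seed=1)
        for algo, s in summaries.items():
            assert s.mean_tss >= 0.95, f"{algo} scored {s.mean_tss}"

    def test_shuffled_labels_near_zero_tss(self):
        rng = np.random.default_rng(3)
        df = separable_records(n=160)
        df["resistant"] = rng.permutation(df["resistant"].to_numpy())
        _, summaries = cal.train_suite(df, ["x1", "x2"], n_runs=20, seed=2)
        for algo, s in summaries.items():
            assert abs(s.mean_tss) < 0.25, f"{algo} scored {s.mean_tss}"

    def test_reproducible_for_fixed_seed(self):
        df = separable_records()
        runs1, s1 = cal.train_suite(df, ["x1", "x2"], algorithms=["GLM", "RF"], n_runs=4, seed=9)
        runs2, s2 = cal.train_suite(df, ["x1", "x2"], algorithms=["GLM", "RF"], n_runs=4, seed=9)
        assert [r.tss for r in runs1] == [r.tss for r in runs2]
        assert s1["RF"].mean_tss == s2["RF"].mean_tss

    def test_single_class_rejected(self):
        df = separable_records()
        df["resistant"] = True
        with pytest.raises(ValidationError):
            cal.train_suite(df, ["x1", "x2"], n_runs=2)

    def test_tss_evaluated_on_heldout_quarter(self):
        df = separable_records(n=100)
        runs, _ = cal.train_suite(df, ["x1", "x2"], algorithms=["GLM"], n_runs=3, seed=0)
        for r in runs:
            assert len(r.test_index) == 25
            assert len(r.train_index) == 75
            assert not set(r.test_index) & set(r.train_index)


class TestPermutationImportance:
    def fit_single_variable_run(self):
        df = separable_records(n=150, seed=5)
        runs, summaries = cal.train_suite(df, ["x1", "x2"], algorithms=["GLM"], n_runs=3, seed=4)
        best = summaries["GLM"].best_run
        X = df[["x1", "x2"]].to_numpy(float)
        return best, X

    def test_driving_variable_dominates(self):
        best, X = self.fit_single_variable_run()
        imp = cal.permutation_importance(best, X, ["x1", "x2"], n_perm=30, seed=0)
        assert imp["x1"] > imp["x2"]
        assert 0.0 <= min(imp.values()) and max(imp.values()) <= 1.0

    def test_ignored_variable_scores_zero(self):
        best, X = self.fit_single_variable_run()
        X3 = np.column_stack([X, np.random.default_rng(0).normal(size=len(X))])

        class Wrapper:
            def __init__(self, inner):
                self.inner = inner
                self.classes_ = inner.classes_

            def predict_proba(self, X):
                return self.inner.predict_proba(X[:, :2])

        from predchar.calibration import ModelRun

        run = ModelRun(algorithm="GLM", run=0, seed=0, tss=1.0, cutoff=500.0,
                       model=Wrapper(best.model))
        imp = cal.permutation_importance(run, X3, ["x1", "x2", "x3"], n_perm=10, seed=1)
        assert imp["x3"] == 0.0


class TestSelectAndProject:
    def make_summaries(self, mean_tss_by_algo, best_run=None):
        return {
            a: cal.AlgorithmSummary(
                algorithm=a, mean_tss=t, performance=cal.classify_performance(t),
                n_runs=5, n_failed=0, best_run=best_run,
            )
            for a, t in mean_tss_by_algo.items()
        }

    def test_all_below_poor_is_unmodelable(self):
        summaries = self.make_summaries({"GLM": 0.1, "RF": 0.15, "SRE": -0.02})
        result = cal.select_and_project(
            summaries, pd.DataFrame(), ["x1", "x2"], np.zeros((4, 2)), trait="broomrape"
        )
        assert result.unmodelable
        assert result.projections is None and result.top_subset is None

    def test_cutoff_labels_projection(self):
        df = separable_records(n=120, seed=8)
        _, summaries = cal.train_suite(df, ["x1", "x2"], algorithms=["GLM"], n_runs=3, seed=8)
        pops = pd.DataFrame(
            {
                "pop_id": [f"ID_{i}" for i in range(60)],
                "x1": np.where(np.arange(60) < 30, 5.0, -5.0),
                "x2": 0.0,
            }
        )
        X = df[["x1", "x2"]].to_numpy(float)
        result = cal.select_and_project(summaries, pops, ["x1", "x2"], X, top_n=10, n_perm=5)
        assert not result.unmodelable
        proj = result.projections
        assert ((proj["suitability"] > result.cutoff) == (proj["label"] == "resistant")).all()
        assert len(result.top_subset) == 10
        suit = result.top_subset["suitability"].to_numpy()
        assert (np.diff(suit) <= 0).all()

    def test_labels_forced_by_cutoff_definition(self):
        # suitabilities {900, 500, 100} against cutoff 106
        suit = np.array([900.0, 500.0, 100.0])
        labels = np.where(suit > 106.0, "resistant", "sensitive")
        assert labels.tolist() == ["resistant", "resistant", "sensitive"]

    def test_choose_overrides_ranking(self):
        df = separable_records(n=120, seed=8)
        _, summaries = cal.train_suite(
            df, ["x1", "x2"], algorithms=["GLM", "CTA"], n_runs=3, seed=8
        )
        pops = pd.DataFrame({"pop_id": ["A"], "x1": [5.0], "x2": [0.0]})
        X = df[["x1", "x2"]].to_numpy(float)
        result = cal.select_and_project(summaries, pops, ["x1", "x2"], X, choose="CTA", n_perm=5)
        assert result.chosen_algorithm == "CTA"


class TestBestCutoff:
    def test_separates_perfectly_when_possible(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        c, t = cal.best_cutoff(y, scores)
        assert t == pytest.approx(1.0)
        assert 0.2 < c < 0.8

    def test_rank_preserving_under_affine_scaling(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        scores = rng.uniform(size=50)
        c1, t1 = cal.best_cutoff(y, scores)
        c2, t2 = cal.best_cutoff(y, 1000.0 * scores)
        assert t1 == pytest.approx(t2)
        assert (scores > c1).tolist() == ((1000.0 * scores) > c2).tolist()
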