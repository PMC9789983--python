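"""Cross-validation, AUC, calibration, bootstrap directions, thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptombn import reference_network, sample_binary
from symptombn.evaluation import (
    auc_roc,
    bootstrap_edge_directions,
    calibration,
    calibration_from_predictions,
    cv_algorithm_selection,
    kfold_split,
    operating_thresholds,
    symptom_auc_cv,
)
from symptombn.graph import CPT, DAG, DiscreteBayesianNetwork
from symptombn.structure import algorithm_menu


def brute_force_auc(pred, labels):
    """All-pairs concordance oracle: ties count one half."""
    pos = [p for p, y in zip(pred, labels) if y == 1]
    neg = [p for p, y in zip(pred, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestKfold:
    def test_study_scale_fold_sizes(self):
        folds = kfold_split(532, 4, seed=0)
        assert np.bincount(folds).tolist() == [133, 133, 133, 133]

    def test_tiny_even_split(self):
        assert np.bincount(kfold_split(8, 4, seed=1)).tolist() == [2, 2, 2, 2]

    def test_partition_contract(self):
        folds = kfold_split(101, 4, seed=3)
        assert len(folds) == 101
        sizes = np.bincount(folds)
        assert sizes.sum() == 101 and sizes.max() - sizes.min() <= 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            kfold_split(3, 4)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc([0.4] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_six_point_example_matches_all_pairs_oracle(self):
        pred = [0.1, 0.8, 0.35, 0.35, 0.6, 0.2]
        labels = [0, 1, 1, 0, 1, 0]
        assert auc_roc(pred, labels) == pytest.approx(brute_force_auc(pred, labels))

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        pred = rng.random(200).round(2)  # rounding forces ties
        labels = rng.integers(0, 2, size=200)
        assert auc_roc(pred, labels) == pytest.approx(roc_auc_score(labels, pred))

    def test_single_class_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            assert np.isnan(auc_roc([0.2, 0.4], [1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        a = auc_roc(pred, labels)
        assert auc_roc(np.exp(3 * pred) - 1, labels) == pytest.approx(a)
        assert a == pytest.approx(brute_force_auc(list(pred), list(labels)))


@pytest.fixture(scope="module")
def sample():
    return sample_binary(reference_network(), 1500, seed=44)


class TestCvAlgorithmSelection:
    def test_nine_ranked_rows_and_determinism(self, sample):
        table = cv_algorithm_selection(sample, k=4, seed=2)
        assert len(table) == 9
        assert table["mean"].is_monotonic_decreasing
        again = cv_algorithm_selection(sample, k=4, seed=2)
        pd.testing.assert_frame_equal(table, again)
        assert table.attrs["winner"] == again.attrs["winner"]

    def test_failing_algorithm_excluded_with_warning(self, sample):
        def broken(ds, seed=0):
            raise RuntimeError("boom")

        registry = {"tabu": algorithm_menu()["tabu"], "broken": broken}
        with pytest.warns(UserWarning, match="broken"):
            table = cv_algorithm_selection(sample, registry, k=4, seed=0)
        assert list(table.index) == ["tabu"]

    def test_heldout_criterion_runs(self, sample):
        registry = {"tabu": algorithm_menu()["tabu"]}
        table = cv_algorithm_selection(sample, registry, k=4, seed=0, heldout=True)
        assert table.attrs["criterion"] == "heldout_loglik"
        assert np.isfinite(table["mean"]).all()


class TestSymptomAucCv:
    def test_reference_sample_gives_eleven_informative_rows(self, ref_net):
        df = sample_binary(ref_net, 3000, seed=45)
        summary = symptom_auc_cv(df, "tabu", k=4, seed=0)
        assert summary.shape[0] == 11
        assert set(summary.columns) >= {"mean_auc", "sd_auc", "satisfactory"}
        # every node has a non-empty Markov blanket in the generator
        assert (summary["mean_auc"] > 0.5).all()
        assert (summary["satisfactory"] == (summary["mean_auc"] >= 0.65)).all()

    def test_independent_symptom_has_no_signal(self):
        rng = np.random.default_rng(46)
        net = reference_network()
        df = sample_binary(net, 3000, seed=46).copy()
        df["pain"] = rng.integers(0, 2, size=len(df))  # sever pain from the rest
        summary = symptom_auc_cv(df, "tabu", k=4, seed=0)
        assert summary.loc["pain", "mean_auc"] == pytest.approx(0.5, abs=0.06)


class TestCalibration:
    def test_decile_bookkeeping(self, ref_net):
        df = sample_binary(ref_net, 500, seed=47)
        result = calibration(df, "tabu", k=4, seed=0)
        assert result.n_total == 110
        for table in result.tables.values():
            assert table["n"].sum() == 500
            assert table["n"].max() - table["n"].min() <= 1
            assert table["mean_predicted"].is_monotonic_increasing

    def test_count_weighted_observed_equals_prevalence(self, ref_net):
        df = sample_binary(ref_net, 500, seed=48)
        result = calibration(df, "tabu", k=4, seed=0)
        for name, table in result.tables.items():
            pooled = (table["observed"] * table["n"]).sum() / table["n"].sum()
            assert pooled == pytest.approx(df[name].mean(), abs=1e-12)

    def test_true_model_on_large_sample_is_fully_accurate(self, ref_net):
        from symptombn.inference import predict_proba_all

        df = sample_binary(ref_net, 20_000, seed=49)
        preds = predict_proba_all(ref_net, df)
        result = calibration_from_predictions(preds, df)
        assert result.n_accurate == result.n_total == 110

    def test_constant_predictions_flagged(self):
        df = pd.DataFrame({"a": [0, 1] * 10})
        result = calibration_from_predictions(np.full((20, 1), 0.5), df)
        assert result.constant_prediction == ["a"]
        assert all(t["n"].max() - t["n"].min() <= 1 for t in result.tables.values())

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [0, 1, 0]})
        with pytest.raises(ValueError, match="at least"):
            calibration_from_predictions(np.full((3, 1), 0.4), df)


class TestBootstrapDirections:
    def test_threshold_arithmetic(self):
        """A 0.60/0.25 split resolves at the 0.51 majority; 0.50/0.50 does not."""
        from symptombn.evaluation import EdgeDirectionVote

        # exercised through the public API on a deterministic two-node learner
        calls = {"n": 0}

        def learner(ds, seed=0):
            calls["n"] += 1
            i = calls["n"]
            if i <= 12:
                edges = [("A", "B")]
            elif i <= 17:
                edges = [("B", "A")]
            else:
                edges = []
            from symptombn.structure import LearnedStructure

            return LearnedStructure("stub", DAG(("A", "B"), edges), 0.0)

        df = pd.DataFrame({"A": [0, 1] * 10, "B": [0, 1] * 10})
        votes = bootstrap_edge_directions(df, learner, n_boot=20, seed=0)
        (vote,) = votes
        assert vote.forward_fraction == pytest.approx(0.60)
        assert vote.reverse_fraction == pytest.approx(0.25)
        assert vote.resolved == ("A", "B")

        calls["n"] = 0
        votes = bootstrap_edge_directions(df, learner, n_boot=20, majority=0.61, seed=0)
        assert votes[0].resolved is None  # same tallies, stricter majority

    def test_collider_edges_resolved_toward_the_effect(self):
        net = DiscreteBayesianNetwork(
            DAG(("A", "B", "C"), [("A", "C"), ("B", "C")]),
            {
                "A": CPT("A", (), [0.5]),
                "B": CPT("B", (), [0.5]),
                "C": CPT("C", ("A", "B"), [0.9, 0.6, 0.4, 0.1]),
            },
        )
        df = sample_binary(net, 10_000, seed=50)
        votes = bootstrap_edge_directions(df, "tabu", n_boot=60, seed=1)
        resolved = {v.resolved for v in votes if v.resolved}
        assert ("A", "C") in resolved and ("B", "C") in resolved

    def test_unresolved_below_majority(self):
        def learner(ds, seed=0):
            from symptombn.structure import LearnedStructure

            edges = [("A", "B")] if seed % 2 == 0 else [("B", "A")]
            return LearnedStructure("stub", DAG(("A", "B"), edges), 0.0)

        rng_balanced = pd.DataFrame({"A": [0, 1] * 5, "B": [1, 0] * 5})
        votes = bootstrap_edge_directions(rng_balanced, learner, n_boot=100, seed=0)
        (vote,) = votes
        if abs(vote.forward_fraction - 0.5) < 0.01:
            assert vote.resolved is None


class TestOperatingThresholds:
    def test_perfect_separation(self):
        pred = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        out = operating_thresholds(pred, labels, 0.9, 0.9)
        assert out["high_specificity"]["specificity"] == 1.0
        assert out["high_sensitivity"]["sensitivity"] == 1.0
        assert 0.2 < out["high_specificity"]["threshold"] <= 0.8
        assert 0.2 < out["high_sensitivity"]["threshold"] <= 0.8

    def test_degenerate_constraint_flags_everything(self):
        pred = [0.3, 0.5, 0.7, 0.9]
        labels = [0, 1, 0, 1]
        out = operating_thresholds(pred, labels, min_sensitivity=0.5, min_specificity=0.0)
        assert out["high_specificity"]["threshold"] == 0.3  # lowest cut-off

    def test_ten_point_example_matches_exhaustive_scan(self):
        rng = np.random.default_rng(51)
        pred = rng.random(10).round(2)
        labels = rng.integers(0, 2, size=10)
        labels[:2] = [0, 1]
        out = operating_thresholds(pred, labels, 0.8, 0.8)
        # exhaustive oracle
        best_spec = None
        best_sens = None
        n1, n0 = labels.sum(), (1 - labels).sum()
        for t in sorted(set(pred)):
            flag = pred >= t
            sens = flag[labels == 1].sum() / n1
            spec = (~flag)[labels == 0].sum() / n0
            if best_spec is None and spec >= 0.8:
                best_spec = t
            if sens >= 0.8:
                best_sens = t
        assert (out["high_specificity"] or {}).get("threshold") == best_spec
        assert (out["high_sensitivity"] or {}).get("threshold") == best_sens

    def test_unattainable_reported_as_none(self):
        pred = [0.5, 0.5]
        labels = [0, 1]
        out = operating_thresholds(pred, labels, min_sensitivity=1.0, min_specificity=1.0)
        assert out["high_specificity"] is None

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            operating_thresholds([0.1, 0.2], [1, 1])
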