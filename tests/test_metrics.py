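"""Survey-weighted metric correctness against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from themewise.metrics import (SplitSpec, choose_threshold, confusion_metrics,
                               evaluate_scores, make_split, weighted_auc)


def brute_force_auc(scores, y, w):
    """Direct pair enumeration of the weighted Mann-Whitney statistic."""
    num = den = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            den += w[i] * w[j]
            if scores[i] > scores[j]:
                num += w[i] * w[j]
            elif scores[i] == scores[j]:
                num += 0.5 * w[i] * w[j]
    return num / den


class TestWeightedAUC:
    def test_perfect_separation_gives_one(self):
        assert weighted_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert weighted_auc([0.3] * 6, [1, 0, 0, 1, 0, 0]) == 0.5

    @pytest.mark.parametrize("y,expected", [((1, 0, 0), 1.0), ((0, 1, 0), 0.5)])
    def test_three_point_hand_example(self, y, expected):
        # (0.9 > 0.8), (0.9 > 0.3) -> 1.0 ; (0.8 < 0.9) + (0.8 > 0.3) -> 0.5
        assert weighted_auc([0.9, 0.8, 0.3], list(y)) == expected

    def test_matches_pair_enumeration_with_ties_and_weights(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            scores = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            w = rng.lognormal(0, 0.5, n)
            got = weighted_auc(scores, y, w)
            want = brute_force_auc(scores, y, w)
            assert got == pytest.approx(want, abs=1e-12)

    def test_unit_weights_reduce_to_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        assert weighted_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        w = rng.lognormal(0, 0.3, 100)
        a = weighted_auc(scores, y, w)
        assert weighted_auc(-scores, y, w) == pytest.approx(1 - a, abs=1e-12)

    def test_integer_weights_equal_row_replication(self, rng):
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        w = rng.integers(1, 4, 30).astype(float)
        rep = np.repeat(np.arange(30), w.astype(int))
        assert weighted_auc(scores, y, w) == pytest.approx(
            weighted_auc(scores[rep], y[rep]), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            weighted_auc([0.1, 0.2], [1, 1])


class TestConfusionMetrics:
    def test_hand_computed_confusion_matrix(self):
        # TP=8, FN=2, TN=85, FP=5 -> sens .8, spec 85/90, BER ~ .1278
        y = np.r_[np.ones(10), np.zeros(90)].astype(int)
        yhat = np.r_[np.ones(8), np.zeros(2), np.zeros(85), np.ones(5)].astype(int)
        m = confusion_metrics(yhat, y)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(85 / 90)
        assert m.ber == pytest.approx(1 - (0.8 + 85 / 90) / 2)
        assert m.ber == pytest.approx(0.1278, abs=5e-5)

    def test_perfect_predictions_zero_ber(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(y, y)
        assert m.ber == 0.0

    def test_predict_all_positive(self):
        y = np.array([0, 1, 0, 0])
        m = confusion_metrics(np.ones(4, dtype=int), y)
        assert (m.sensitivity, m.specificity, m.ber) == (1.0, 0.0, 0.5)

    def test_ber_identity_holds(self, rng):
        y = rng.integers(0, 2, 50)
        yhat = rng.integers(0, 2, 50)
        w = rng.lognormal(0, 0.5, 50)
        m = confusion_metrics(yhat, y, w)
        assert m.ber == pytest.approx(1 - (m.sensitivity + m.specificity) / 2)

    def test_integer_weights_equal_row_replication(self, rng):
        y = rng.integers(0, 2, 40)
        yhat = rng.integers(0, 2, 40)
        w = rng.integers(1, 5, 40).astype(float)
        rep = np.repeat(np.arange(40), w.astype(int))
        a = confusion_metrics(yhat, y, w)
        b = confusion_metrics(yhat[rep], y[rep])
        assert a.sensitivity == pytest.approx(b.sensitivity, abs=1e-12)
        assert a.specificity == pytest.approx(b.specificity, abs=1e-12)
        assert a.ber == pytest.approx(b.ber, abs=1e-12)


class TestChooseThreshold:
    def test_separable_scores_reach_zero_ber(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        t = choose_threshold(scores, y)
        assert t == 0.8  # lower boundary of the separating gap
        m = evaluate_scores(scores, y, threshold=t)
        assert m.ber == 0.0

    def test_all_equal_scores_degenerate(self):
        t = choose_threshold([0.5] * 5, [0, 1, 0, 1, 0])
        m = evaluate_scores([0.5] * 5, [0, 1, 0, 1, 0], threshold=t)
        assert m.ber == 0.5

    def test_matches_exhaustive_search(self, rng):
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.8, 0.95], size=25)
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        w = rng.lognormal(0, 0.4, 25)
        best = min(
            np.unique(scores),
            key=lambda t: (confusion_metrics((scores >= t).astype(int), y, w).ber, t),
        )
        assert choose_threshold(scores, y, w) == best


class TestMakeSplit:
    def test_partition_and_determinism(self):
        y = np.r_[np.ones(6), np.zeros(94)].astype(int)
        tr1, te1 = make_split(100, SplitSpec(seed=3), y=y)
        tr2, te2 = make_split(100, SplitSpec(seed=3), y=y)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert len(tr1) + len(te1) == 100
        assert np.array_equal(np.sort(np.r_[tr1, te1]), np.arange(100))

    def test_stratification_bounds_rare_class(self):
        y = np.r_[np.ones(6), np.zeros(94)].astype(int)
        _, te = make_split(100, SplitSpec(seed=0), y=y)
        assert y[te].sum() in (1, 2)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            make_split(5, SplitSpec())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_weighted_auc_reduction_property(seed):
    """Weighted AUC with unit weights equals the unweighted formula exactly."""
    r = np.random.default_rng(seed)
    n = int(r.integers(6, 60))
    scores = r.normal(size=n)
    y = r.integers(0, 2, n)
    y[:2] = [0, 1]
    assert weighted_auc(scores, y, np.ones(n)) == weighted_auc(scores, y)


class TestReportWriting:
    def test_report_json_round_trip_and_markdown(self, tmp_path):
        import json
        from themewise.metrics import write_report
        report = {
            "config": {"seed": 1}, "stop_reason": "auc_floor",
            "excluded_themes": ["violence"],
            "rounds": [{"round": 1,
                        "test_metrics": {"auc": 0.91, "ber": 0.2},
                        "knee_rank": 7,
                        "selected_variables": ["a", "b"],
                        "qualified_themes": ["violence"],
                        "dominant_theme": "violence"}],
        }
        paths = write_report(report, tmp_path)
        back = json.loads(paths["json"].read_text())
        assert back == report
        md = paths["markdown"].read_text()
        assert "auc_floor" in md and "violence" in md

    def test_export_tables(self, rng):
        import numpy as np
        from themewise.knee import CoefficientCurve, curve_to_frame, find_knee
        from themewise.models import (CVResult, RegularizedFit, cv_to_frame,
                                      fit_to_frame)
        fit = RegularizedFit(theta=np.array([0.4, -0.1]), intercept=0.0,
                             penalty="l1", lam=2.0, converged=True,
                             objective_value=1.0, feature_names=("a", "b"))
        df = fit_to_frame(fit)
        assert list(df["feature"]) == ["a", "b"]
        cv = CVResult(lambda_grid=np.array([2.0, 1.0]),
                      fold_auc=np.full((2, 5), 0.7), best_lambda=2.0, seed=0)
        assert len(cv_to_frame(cv)) == 10
        v = np.sort(rng.exponential(size=30))[::-1]
        c = CoefficientCurve(values=v, names=tuple(f"f{i}" for i in range(30)))
        table = curve_to_frame(c, find_knee(c))
        assert {"rank", "value", "curvature", "above_knee"} <= set(table.columns)
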