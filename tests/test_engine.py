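"""Theme qualification, exclusion, stopping rules, and the full loop."""

import json

import numpy as np
import pytest

from conftest import fast_engine_config, small_config
from themewise.engine import (CodingRequired, EngineConfig, IterationState,
                              MappingProvider, ThemeMap, apply_exclusion,
                              check_stopping, coder_agreement,
                              filter_previously_excluded, find_dominant_theme,
                              ground_truth_provider, qualify_themes,
                              read_completed_worksheet, request_coding,
                              run_iterative_analysis)
from themewise.prep import VariableDictionary, prepare
from themewise.synthetic import generate_population


def tmap(d):
    return ThemeMap({k: set(v) for k, v in d.items()})


class TestQualifyThemes:
    def test_five_percent_rule_forty_selected(self):
        # ceil(0.05 * 40) = 2: a two-member theme qualifies
        sel = [f"v{i}" for i in range(40)]
        m = tmap({"v0": ["diet"], "v1": ["diet"]})
        assert qualify_themes(sel, m) == {"diet"}

    def test_five_percent_rule_hundred_selected(self):
        # ceil(0.05 * 100) = 5: four members do not qualify
        sel = [f"v{i}" for i in range(100)]
        m = tmap({f"v{i}": ["diet"] for i in range(4)})
        assert qualify_themes(sel, m) == set()

    def test_minimum_two_members_overrides_small_selections(self):
        # with 10 selected, ceil(0.05*10) = 1 but a single member never counts
        sel = [f"v{i}" for i in range(10)]
        m = tmap({"v0": ["diet"]})
        assert qualify_themes(sel, m) == set()
        m2 = tmap({"v0": ["diet"], "v1": ["diet"]})
        assert qualify_themes(sel, m2) == {"diet"}

    def test_multi_membership_counts_in_every_theme(self):
        sel = [f"v{i}" for i in range(10)]
        m = tmap({"v0": ["diet", "health"], "v1": ["diet"], "v2": ["health"]})
        assert qualify_themes(sel, m) == {"diet", "health"}


class TestFindDominantTheme:
    def test_top_ranked_variable_decides(self):
        m = tmap({"a": ["violence"], "b": ["diet"]})
        assert find_dominant_theme(["a", "b"], {"violence", "diet"}, m) == "violence"

    def test_walks_past_unqualified_and_unthemed(self):
        m = tmap({"b": ["diet"], "c": ["noise"]})
        assert find_dominant_theme(["a", "c", "b"], {"diet"}, m) == "diet"

    def test_tie_breaks_by_member_count(self):
        m = tmap({"top": ["big", "small"],
                  **{f"b{i}": ["big"] for i in range(5)},
                  **{f"s{i}": ["small"] for i in range(2)}})
        assert find_dominant_theme(["top"], {"big", "small"}, m) == "big"

    def test_no_qualified_theme_raises(self):
        with pytest.raises(ValueError):
            find_dominant_theme(["a"], set(), tmap({"a": ["x"]}))


class FakeEncoded:
    """Minimal provenance shim for exclusion tests."""

    def __init__(self, feats):
        self._src = dict(feats)

    def source_variable(self, f):
        return self._src[f]


class TestExclusionRules:
    def test_single_theme_variable_removed(self):
        m = tmap({"a": ["violence"], "b": ["health"]})
        st = IterationState(active_features=["a=1", "a=2", "b"])
        enc = FakeEncoded({"a=1": "a", "a=2": "a", "b": "b"})
        apply_exclusion(st, "violence", m, enc)
        assert st.active_features == ["b"]
        assert st.excluded_themes == ["violence"]

    def test_multi_theme_variable_retained_then_removed(self):
        m = tmap({"a": ["violence", "health"]})
        st = IterationState(active_features=["a"])
        enc = FakeEncoded({"a": "a"})
        apply_exclusion(st, "violence", m, enc)
        assert st.active_features == ["a"]  # health still active
        apply_exclusion(st, "health", m, enc)
        assert st.active_features == []

    def test_filter_previously_excluded_subset_rule(self):
        m = tmap({"new1": ["substance_abuse"],
                  "new2": ["substance_abuse", "diet"]})
        st = IterationState(excluded_themes=["substance_abuse"])
        kept, dropped = filter_previously_excluded(["new1", "new2"], st, m)
        assert kept == ["new2"]
        assert dropped == ["new1"]

    def test_filter_identity_without_exclusions(self):
        st = IterationState()
        kept, dropped = filter_previously_excluded(["x"], st, tmap({"x": ["t"]}))
        assert (kept, dropped) == (["x"], [])


class TestCheckStopping:
    def test_auc_floor_boundary(self):
        st = IterationState(round=1)
        assert check_stopping(st, 0.74) == (True, "auc_floor")
        assert check_stopping(st, 0.75) == (False, None)

    def test_three_rounds_without_new_theme(self):
        st = IterationState(round=4, rounds_without_new_theme=3)
        assert check_stopping(st, 0.78) == (True, "no_new_themes_3")
        st.rounds_without_new_theme = 2
        assert check_stopping(st, 0.78) == (False, None)

    def test_no_new_variables(self):
        st = IterationState(round=2)
        assert check_stopping(st, 0.80, new_variables_found=False) == \
            (True, "no_new_variables")

    def test_max_rounds_guard(self):
        st = IterationState(round=25)
        assert check_stopping(st, 0.9) == (True, "max_rounds")

    def test_continue_when_all_clear(self):
        st = IterationState(round=3, rounds_without_new_theme=1)
        assert check_stopping(st, 0.80, new_variables_found=True) == (False, None)


class TestCoderAgreement:
    def test_nineteen_of_twenty(self):
        a = tmap({f"v{i}": ["x"] for i in range(20)})
        b = tmap({**{f"v{i}": ["x"] for i in range(19)}, "v19": ["y"]})
        assert coder_agreement(a, b, [f"v{i}" for i in range(20)]) == 95.0

    def test_identical_and_disjoint(self):
        a = tmap({"v": ["x"], "u": ["y"]})
        assert coder_agreement(a, a, ["v", "u"]) == 100.0
        b = tmap({"v": ["p"], "u": ["q"]})
        assert coder_agreement(a, b, ["v", "u"]) == 0.0

    def test_uncovered_variable_raises(self):
        a = tmap({"v": ["x"]})
        with pytest.raises(ValueError):
            coder_agreement(a, a, ["v", "w"])


class TestCodingWorksheet:
    def test_worksheet_contents(self):
        ws = request_coding(["b", "d"], ["a", "b", "c", "d"],
                            {"a": 0.9, "b": 0.5, "d": 0.2})
        assert list(ws["variable"]) == ["b", "d"]
        assert list(ws["rank"]) == [2, 4]
        assert (ws["theme"] == "").all()

    def test_completed_worksheet_round_trip(self, tmp_path):
        ws = request_coding(["b"], ["a", "b"], {"b": 0.5})
        ws.loc[0, "theme"] = "diet|health"
        p = tmp_path / "ws.csv"
        ws.to_csv(p, index=False)
        codes = read_completed_worksheet(p)
        assert codes == {"b": {"diet", "health"}}

    def test_unassigned_rows_rejected_by_name(self, tmp_path):
        ws = request_coding(["b", "c"], ["a", "b", "c"], {})
        ws.loc[0, "theme"] = "diet"
        p = tmp_path / "ws.csv"
        ws.to_csv(p, index=False)
        with pytest.raises(ValueError, match="c"):
            read_completed_worksheet(p)


@pytest.fixture(scope="module")
def small_run(small_encoded):
    enc, gt = small_encoded
    cfg = fast_engine_config(seed=4)
    report = run_iterative_analysis(enc, ground_truth_provider(gt), cfg)
    return enc, gt, cfg, report


class TestIterativeLoop:
    def test_strong_theme_dominates_round_one(self, small_run):
        enc, gt, cfg, report = small_run
        assert report["rounds"][0]["dominant_theme"] == "alpha"

    def test_active_features_monotonically_shrink(self, small_run):
        _, _, _, report = small_run
        sizes = [r["n_active_features"] for r in report["rounds"]]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_excluded_themes_grow_monotonically(self, small_run):
        _, _, _, report = small_run
        seen = []
        for r in report["rounds"]:
            if r.get("dominant_theme"):
                assert r["dominant_theme"] not in seen
                seen.append(r["dominant_theme"])
        assert report["excluded_themes"] == seen

    def test_full_report_reproducible_byte_identical(self, small_encoded):
        enc, gt = small_encoded
        cfg = fast_engine_config(seed=9)
        r1 = run_iterative_analysis(enc, ground_truth_provider(gt), cfg)
        r2 = run_iterative_analysis(enc, ground_truth_provider(gt), cfg)
        assert json.dumps(r1, sort_keys=True, default=str) == \
            json.dumps(r2, sort_keys=True, default=str)

    def test_signal_free_data_stops_round_one_auc_floor(self):
        table, dct, gt = generate_population(small_config(seed=21, signal=False))
        enc = prepare(table, VariableDictionary.from_mapping(dct))
        report = run_iterative_analysis(enc, ground_truth_provider(gt),
                                        fast_engine_config(seed=21))
        assert len(report["rounds"]) == 1
        assert report["stop_reason"] in ("auc_floor", "empty_support")
        assert report["rounds"][0]["test_metrics"]["auc"] < 0.75

    def test_coding_request_raised_for_unknown_variables(self, small_encoded):
        enc, gt = small_encoded
        provider = MappingProvider(ThemeMap({}), fallback="request")
        with pytest.raises(CodingRequired) as exc:
            run_iterative_analysis(enc, provider, fast_engine_config(seed=4))
        ws = exc.value.worksheet
        assert len(ws) > 0
        assert set(ws.columns) >= {"variable", "rank", "coefficient", "theme"}

    def test_resume_with_merged_map_matches_uninterrupted(self, small_run):
        """Completing the worksheet and re-running reproduces the run."""
        enc, gt, cfg, report = small_run
        provider = MappingProvider(ThemeMap({}), fallback="request")
        with pytest.raises(CodingRequired) as excinfo:
            run_iterative_analysis(enc, provider, cfg)
        ws = excinfo.value.worksheet
        full = ground_truth_provider(gt).theme_map
        merged = {v: full.themes_of(v) if full.is_coded(v)
                  else {f"misc::{v}"} for v in ws["variable"]}
        provider2 = MappingProvider(ThemeMap({}), fallback="request")
        provider2.theme_map.update(merged)
        # keep answering until the loop runs through (simulates repeated
        # worksheet rounds, exactly the resume workflow)
        for _ in range(20):
            try:
                resumed = run_iterative_analysis(enc, provider2, cfg)
                break
            except CodingRequired as exc:
                extra = {v: full.themes_of(v) if full.is_coded(v)
                         else {f"misc::{v}"} for v in exc.worksheet["variable"]}
                provider2.theme_map.update(extra)
        else:
            raise AssertionError("coding never completed")
        assert json.dumps(resumed, sort_keys=True, default=str) == \
            json.dumps(report, sort_keys=True, default=str)

    def test_excluded_theme_soundness_invariant(self, small_run):
        enc, gt, cfg, report = small_run
        # replay: no surviving selected variable has all themes excluded
        provider = ground_truth_provider(gt)
        excluded = set()
        for r in report["rounds"]:
            for v in r["selected_variables"]:
                labels = provider.theme_map.themes_of(v)
                assert not labels or not (labels <= excluded)
            if r.get("dominant_theme"):
                excluded.add(r["dominant_theme"])
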