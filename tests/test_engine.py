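"""ITA loop: theme rules, dropping semantics, termination, replay."""

import numpy as np
import pytest

from itakit import (
    DesignMatrix,
    ITAConfig,
    IterativeThematicAnalysis,
    SyntheticConfig,
    ThemeMap,
    build_design_matrix,
    default_catalog,
    generate_survey,
    replay_trace,
    run_ita,
)
from itakit.engine import drop_theme, identify_themes, theme_score
from itakit.knee import CoefficientCurve


@pytest.fixture
def curve():
    values = np.array([0.9, 0.7, 0.4, 0.2, 0.1, 0.05])
    names = ("v1", "v2", "v3", "v4", "v5", "v6")
    return CoefficientCurve(values, names)


class TestIdentifyThemes:
    def test_small_selection_needs_two_members(self):
        tm = ThemeMap({f"v{i}": ["wealth"] if i < 2 else ["other"]
                       for i in range(20)})
        valid, _ = identify_themes([f"v{i}" for i in range(20)], tm)
        assert "wealth" in valid  # 2 >= max(2, ceil(0.05*20)=1)

    def test_large_selection_raises_the_bar(self):
        tm = ThemeMap({f"v{i}": ["small"] if i < 4 else ["big"]
                       for i in range(100)})
        valid, _ = identify_themes([f"v{i}" for i in range(100)], tm)
        assert "small" not in valid  # 4 < max(2, ceil(0.05*100)=5)
        assert "big" in valid

    def test_unthemed_variables_reported_individually(self):
        tm = ThemeMap({"a": ["t"], "b": ["t"], "tv": []})
        valid, unthemed = identify_themes(["a", "b", "tv"], tm)
        assert unthemed == ("tv",)
        assert valid == {"t": ("a", "b")}

    def test_unknown_variable_warns_and_counts_unthemed(self):
        tm = ThemeMap({"a": ["t"], "b": ["t"]})
        with pytest.warns(UserWarning, match="absent"):
            _, unthemed = identify_themes(["a", "b", "ghost"], tm)
        assert "ghost" in unthemed

    def test_empty_selection_warns(self):
        tm = ThemeMap({"a": ["t"]})
        with pytest.warns(UserWarning, match="empty"):
            valid, unthemed = identify_themes([], tm)
        assert valid == {} and unthemed == ()

    def test_multi_theme_variable_counts_for_each(self):
        tm = ThemeMap({"a": ["t1", "t2"], "b": ["t1"], "c": ["t2"]})
        valid, _ = identify_themes(["a", "b", "c"], tm)
        assert set(valid) == {"t1", "t2"}


class TestThemeScore:
    def test_max_is_default(self, curve):
        assert theme_score("t", curve, ["v1", "v3"]) == pytest.approx(0.9)

    def test_mean_mode(self, curve):
        score = theme_score("t", curve, ["v1", "v3"], mode="mean")
        assert score == pytest.approx((0.9 + 0.4) / 2)

    def test_variance_mode(self, curve):
        score = theme_score("t", curve, ["v2", "v4"], mode="variance")
        assert score == pytest.approx(np.var([0.7, 0.2]))

    def test_dummy_to_source_aggregation(self):
        dummy_curve = CoefficientCurve(
            np.array([0.9, 0.7, 0.4]), ("v1=a", "v2=b", "v2=a")
        )
        source_map = {n: n.split("=")[0] for n in dummy_curve.names}
        score = theme_score("t", dummy_curve, ["v2"], source_map)
        assert score == pytest.approx(0.7)  # best dummy of the variable

    def test_no_members_rejected(self, curve):
        with pytest.raises(ValueError, match="no members"):
            theme_score("t", curve, [])


class TestDropTheme:
    tm = ThemeMap({"x": ["A"], "y": ["A", "B"], "z": ["B"], "tv": [], "n1": []})

    def test_single_theme_member_removed(self):
        assert "x" not in drop_theme(("x", "y", "z", "tv"), "A", self.tm)

    def test_multi_theme_member_survives_first_drop(self):
        active = drop_theme(("x", "y", "z"), "A", self.tm)
        assert "y" in active

    def test_multi_theme_member_removed_at_last_drop(self):
        active = drop_theme(("x", "y", "z"), "A", self.tm)
        active = drop_theme(active, "B", self.tm, dropped={"A"})
        assert "y" not in active and "z" not in active

    def test_unthemed_variables_untouched(self):
        active = drop_theme(("x", "y", "tv", "n1"), "A", self.tm)
        assert "tv" in active and "n1" in active

    def test_unknown_theme_rejected(self):
        with pytest.raises(KeyError):
            drop_theme(("x",), "nope", self.tm)


class TestThemeMap:
    def test_labels_must_be_nonempty(self):
        with pytest.raises(ValueError):
            ThemeMap({"a": [""]})

    def test_unknown_query_raises(self):
        tm = ThemeMap({"a": ["t"]})
        with pytest.raises(KeyError):
            tm.themes_of("b")

    def test_file_roundtrip(self, tmp_path):
        tm = ThemeMap({"a": ["t1", "t2"], "b": []})
        path = tmp_path / "themes.yaml"
        import yaml

        path.write_text(yaml.safe_dump(tm.to_dict()))
        again = ThemeMap.from_file(path)
        assert again.assignments == tm.assignments


def _tiny_ita_inputs(seed=0, n=4000):
    cfg = SyntheticConfig(
        n_respondents=n, n_themes=1, vars_per_theme=4, n_noise_vars=30,
        n_redundant_vars=0, theme_effects=(1.3,), target_prevalence=0.1,
        within_theme_correlation=0.4, seed=seed, noise_theme_size=0,
    )
    survey = generate_survey(cfg)
    table = survey.table.copy()
    table["outcome"] = survey.outcome
    matrix = build_design_matrix(table, default_catalog(survey))
    return matrix, ThemeMap(survey.true_theme_map)


class TestRunITA:
    def test_single_planted_theme_found_then_stop(self):
        matrix, tm = _tiny_ita_inputs()
        result = run_ita(matrix, tm, ITAConfig(seed=0))
        assert result.iterations[0].valid_themes.keys() == {"theme_1"}
        assert result.n_iterations <= 2
        assert result.all_themes == ("theme_1",)

    def test_all_empty_theme_map_exhausts(self):
        matrix, _ = _tiny_ita_inputs()
        empty = ThemeMap({v: [] for v in matrix.sources})
        result = run_ita(matrix, empty, ITAConfig(seed=0))
        assert result.stop_reason == "exhausted"
        assert result.n_iterations == 1
        assert result.iterations[0].unthemed  # findings reported, not grouped

    def test_termination_bound(self):
        matrix, tm = _tiny_ita_inputs(seed=2)
        result = run_ita(matrix, tm, ITAConfig(seed=2))
        assert result.n_iterations <= len(tm.all_labels) + 3

    def test_trace_replay_reproduces_result(self):
        matrix, tm = _tiny_ita_inputs(seed=1)
        cfg = ITAConfig(seed=1)
        result = run_ita(matrix, tm, cfg)
        replayed = replay_trace(matrix, tm, result)
        assert replayed.to_dict() == result.to_dict()

    def test_metrics_reported_per_iteration(self):
        matrix, tm = _tiny_ita_inputs(seed=3)
        result = run_ita(matrix, tm, ITAConfig(seed=3))
        m = result.iterations[0].metrics
        assert m is not None and 0.5 <= m.auc <= 1.0 and 0.0 <= m.ber <= 0.5

    def test_single_class_outcome_rejected(self):
        matrix, tm = _tiny_ita_inputs()
        bad = DesignMatrix(matrix.X, np.zeros(matrix.n, int),
                           matrix.feature_names, dict(matrix.source_map))
        with pytest.raises(ValueError, match="both classes"):
            run_ita(bad, tm)


class TestEstimator:
    def test_sklearn_param_interface(self):
        est = IterativeThematicAnalysis(theme_map={"a": ["t"]}, seed=5)
        params = est.get_params()
        assert params["seed"] == 5
        est.set_params(min_count=3)
        assert est.min_count == 3

    def test_fit_from_design_matrix(self):
        matrix, tm = _tiny_ita_inputs(seed=5)
        est = IterativeThematicAnalysis(theme_map=tm, seed=5).fit(matrix)
        assert est.themes_ == ("theme_1",)
        assert est.stop_reason_ in ("no_new_variables", "no_new_themes_3x",
                                    "exhausted")
        assert est.result_.n_iterations == est.n_iterations_

    def test_fit_from_dataframe_infers_sources(self):
        matrix, tm = _tiny_ita_inputs(seed=6)
        df = matrix.to_frame()
        est = IterativeThematicAnalysis(theme_map=tm, seed=6).fit(df, matrix.y)
        assert "theme_1" in est.themes_

    def test_report_table_lists_themes(self):
        matrix, tm = _tiny_ita_inputs(seed=1)
        result = run_ita(matrix, tm, ITAConfig(seed=1))
        text = result.report_table()
        assert "theme_1" in text
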