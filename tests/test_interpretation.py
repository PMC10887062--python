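"""Weight profiles, forest summaries, Cox correlation, counterfactuals."""

import numpy as np
import pandas as pd
import pytest

from isdkit.cohort import Categorical, Continuous, cohort_from_frame, encode_design
from isdkit.exceptions import SchemaError, ValidationError
from isdkit.interpretation import (
    WeightProfiles,
    bootstrap_mean_weight_ci,
    collect_out_of_fold_weights,
    correlate_with_cox,
    counterfactual_curves,
    rank_influential,
    weight_significance,
    weight_summary,
)
from isdkit.mtlr import MTLRModel, MTLRParams, TimeGrid


def make_model(W, tau, names):
    return MTLRModel(MTLRParams(np.asarray(W, dtype=float), np.zeros(len(tau))),
                     TimeGrid(np.asarray(tau, dtype=float)), list(names))


def profiles_from_values(values_by_cov):
    rows = []
    for cov, vals in values_by_cov.items():
        for i, v in enumerate(vals):
            rows.append((cov, i % 2, float(i + 1), float(v)))
    data = pd.DataFrame(rows, columns=["covariate", "fold", "tau", "weight"])
    return WeightProfiles(data, list(values_by_cov))


class TestCollect:
    def test_identical_fits_give_identical_profiles(self):
        model = make_model([[0.2, -0.1], [0.3, 0.0]], [5.0, 10.0], ["a", "b"])
        profiles = collect_out_of_fold_weights([model, model])
        by_fold = profiles.data.pivot_table(index=["covariate", "tau"],
                                            columns="fold", values="weight")
        np.testing.assert_allclose(by_fold[0], by_fold[1])

    def test_schema_mismatch_raises(self):
        a = make_model([[0.1]], [5.0], ["a"])
        b = make_model([[0.1]], [5.0], ["b"])
        with pytest.raises(SchemaError):
            collect_out_of_fold_weights([a, b])

    def test_pooling_handles_unequal_grid_sizes(self):
        a = make_model([[0.1], [0.2]], [5.0, 10.0], ["a"])
        b = make_model([[0.3]], [7.0], ["a"])
        profiles = collect_out_of_fold_weights([a, b])
        assert len(profiles.values_for("a")) == 3


class TestRanking:
    def test_absolute_value_ordering(self):
        profiles = profiles_from_values({"A": [0.04], "B": [-0.05], "C": [0.01]})
        assert rank_influential(profiles) == ["B", "A", "C"]

    def test_all_zero_falls_back_to_alphabetical(self):
        profiles = profiles_from_values({"b": [0.0], "a": [0.0], "c": [0.0]})
        assert rank_influential(profiles) == ["a", "b", "c"]


class TestBootstrap:
    def test_constant_vector_degenerate_ci(self):
        mean, lo, hi = bootstrap_mean_weight_ci(np.full(20, 0.7), seed=0)
        assert mean == lo == hi == pytest.approx(0.7)

    def test_ci_contains_sample_mean(self, rng):
        vals = rng.normal(0.1, 0.5, 200)
        mean, lo, hi = bootstrap_mean_weight_ci(vals, seed=1)
        assert lo <= mean <= hi

    def test_half_width_matches_normal_theory(self):
        vals = np.array([-1.0, 1.0] * 50)
        mean, lo, hi = bootstrap_mean_weight_ci(vals, n_boot=1000, seed=2)
        half = (hi - lo) / 2
        expected = 1.96 / np.sqrt(100)
        assert abs(half - expected) < 0.2 * expected
        assert abs(mean) < 1e-12

    def test_reproducible(self):
        vals = np.linspace(-1, 1, 37)
        assert bootstrap_mean_weight_ci(vals, seed=9) == bootstrap_mean_weight_ci(vals, seed=9)


class TestSignificance:
    def test_benjamini_hochberg_step_up(self):
        profiles = profiles_from_values({
            "a": [0.5, 0.6, 0.4, 0.7, 0.5],
            "b": [0.1, -0.2, 0.3, 0.15, -0.05],
            "c": [0.0, 0.01, -0.01, 0.02, 0.0],
        })
        from statsmodels.stats.multitest import multipletests

        out = weight_significance(profiles)
        expected = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(out["p_adj"].to_numpy(), expected)
        # BH is monotone and never below raw
        assert np.all(out["p_adj"] >= out["p_raw"] - 1e-15)

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_all_zero_weights_give_p_one(self):
        profiles = profiles_from_values({"a": [0.0] * 10, "b": [0.1, 0.2, 0.3, 0.1, 0.2]})
        out = weight_significance(profiles)
        assert out.loc["a", "p_raw"] == 1.0

    def test_all_positive_wilcoxon_exact_minimum(self):
        vals = np.linspace(0.1, 2.0, 20)
        profiles = profiles_from_values({"a": vals, "b": vals})
        out = weight_significance(profiles)
        assert np.isclose(out.loc["a", "p_raw"], 2 * 2.0**-20)

    def test_null_weights_rarely_significant(self, rng):
        ps = []
        for _ in range(40):
            profiles = profiles_from_values({"a": rng.normal(0, 1, 30)})
            ps.append(weight_significance(profiles).loc["a", "p_raw"])
        assert 0.2 < np.mean(np.asarray(ps) > 0.5) < 0.8  # roughly uniform

    def test_ttest_variant(self):
        profiles = profiles_from_values({"a": [0.5, 0.6, 0.4], "b": [0.0, 0.1, -0.1]})
        out = weight_significance(profiles, method="ttest")
        assert 0 <= out.loc["a", "p_raw"] <= 1


class TestWeightSummary:
    def test_summary_table_invariants(self, rng):
        profiles = profiles_from_values({
            "a": rng.normal(0.3, 0.1, 40),
            "b": rng.normal(-0.2, 0.1, 40),
            "c": rng.normal(0.0, 0.1, 40),
        })
        table = weight_summary(profiles, n_boot=300, seed=4)
        assert list(table["rank"]) == [1, 2, 3]
        assert np.all(table["ci_lo"] <= table["mean_weight"])
        assert np.all(table["mean_weight"] <= table["ci_hi"])
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-15)


class TestCoxCorrelation:
    def test_identical_and_negated_vectors(self):
        w = pd.Series([0.1, -0.2, 0.3], index=["a", "b", "c"])
        r, p, _ = correlate_with_cox(w, w)
        assert np.isclose(r, 1.0)
        r, _, _ = correlate_with_cox(w, -w)
        assert np.isclose(r, -1.0)

    def test_too_few_covariates_raises(self):
        w = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValidationError):
            correlate_with_cox(w, w)


SCHEMA = (
    Continuous("age"),
    Categorical("treatment", ("No", "Yes"), "No"),
)


def _toy_design():
    df = pd.DataFrame({
        "time_months": [5.0, 10.0, 15.0, 20.0],
        "event": [1, 1, 1, 0],
        "age": [50.0, 60.0, 70.0, 55.0],
        "treatment": ["No", "Yes", "No", "Yes"],
    })
    return encode_design(cohort_from_frame(df, SCHEMA))


class TestCounterfactual:
    def test_null_weights_give_identical_curves(self):
        design = _toy_design()
        model = make_model(np.zeros((3, 2)), [5.0, 10.0, 15.0], design.column_names)
        patient = {"age": 60.0, "treatment": "No"}
        out = counterfactual_curves(model, design, patient, {"treatment": "Yes"})
        np.testing.assert_allclose(out["base"].probs, out["toggled"].probs)
        assert out["diff_at"][24.0] == 0.0

    def test_protective_toggle_raises_curve_everywhere(self):
        design = _toy_design()
        W = np.zeros((3, 2))
        W[:, 1] = -0.8  # treatment column: protective at every time point
        model = make_model(W, [5.0, 10.0, 15.0], design.column_names)
        patient = {"age": 60.0, "treatment": "No"}
        out = counterfactual_curves(model, design, patient, {"treatment": "Yes"})
        assert np.all(out["toggled"].probs[1:] >= out["base"].probs[1:])
        assert out["diff_at"][24.0] >= 0.0

    def test_unknown_toggle_covariate_raises(self):
        design = _toy_design()
        model = make_model(np.zeros((3, 2)), [5.0, 10.0, 15.0], design.column_names)
        with pytest.raises(ValidationError):
            counterfactual_curves(model, design, {"age": 60.0, "treatment": "No"},
                                  {"chemo": "Yes"})

    def test_difference_summary_matches_spline_queries(self):
        design = _toy_design()
        W = np.full((3, 2), -0.3)
        model = make_model(W, [5.0, 10.0, 15.0], design.column_names)
        patient = {"age": 52.0, "treatment": "No"}
        out = counterfactual_curves(model, design, patient, {"treatment": "Yes"},
                                    query_times=(8.0, 12.0))
        for t in (8.0, 12.0):
            direct = out["toggled"].survival_at(t) - out["base"].survival_at(t)
            assert np.isclose(out["diff_at"][t], direct)
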