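"""Overrepresentation, logistic fitting and AUC evaluation."""

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germlinekit.models import (
    cross_cohort_evaluate,
    evaluate_auc,
    fit_logistic,
    make_feature_table,
    ora_test,
)
from germlinekit.types import ClinicalRecord

from oracles import auc_pair_oracle, ora_tail_oracle


class TestOra:
    def test_query_equals_universe_gives_p_one(self):
        genes = {f"G{i}" for i in range(8)}
        (res,) = ora_test(genes, {"S": genes}, genes)
        assert res.p == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        universe = {f"G{i}" for i in range(20)}
        gene_set = {f"G{i}" for i in range(5)}
        (res,) = ora_test(gene_set, {"S": gene_set}, universe)
        assert res.p == pytest.approx(1 / 15504, rel=1e-9)
        assert (res.k, res.K, res.n, res.N) == (5, 5, 5, 20)

    def test_no_overlap_gives_p_one(self):
        universe = {f"G{i}" for i in range(12)}
        (res,) = ora_test({"G0", "G1"}, {"S": {"G10", "G11"}}, universe)
        assert res.k == 0 and res.p == pytest.approx(1.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            ora_test(set(), {"S": {"A"}}, set())

    def test_query_outside_universe_is_an_error(self):
        with pytest.raises(ValueError):
            ora_test({"X"}, {"S": {"A"}}, {"A", "B"})

    def test_matches_exhaustive_draw_enumeration(self):
        rng = random.Random(99)
        for _ in range(25):
            N = rng.randint(4, 12)
            universe = {f"G{i}" for i in range(N)}
            gene_set = set(rng.sample(sorted(universe), rng.randint(1, N)))
            query = set(rng.sample(sorted(universe), rng.randint(1, min(6, N))))
            (res,) = ora_test(query, {"S": gene_set}, universe)
            expected = float(ora_tail_oracle(query, gene_set, universe))
            assert res.p == pytest.approx(expected, rel=1e-9)

    def test_results_sorted_by_gene_ratio(self):
        universe = {f"G{i}" for i in range(30)}
        sets = {"big": {f"G{i}" for i in range(15)}, "small": {"G0", "G1"}}
        results = ora_test({"G0", "G1", "G2"}, sets, universe)
        ratios = [r.gene_ratio for r in results]
        assert ratios == sorted(ratios, reverse=True)


def simulate_logistic(rng, n, beta):
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
    })
    eta = beta[0] + beta[1] * X["x1"] + beta[2] * X["x2"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestLogistic:
    def test_null_coefficients_shrink_to_zero(self):
        rng = np.random.default_rng(0)
        X, _ = simulate_logistic(rng, 5000, (0.0, 0.0, 0.0))
        y = (rng.random(5000) < 0.5).astype(int)
        fit = fit_logistic(X, y)
        assert all(abs(v) < 0.1 for k, v in fit.coefficients.items() if k != "intercept")

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        X, y = simulate_logistic(rng, 2000, (-1.0, 0.8, 0.5))
        fit = fit_logistic(X, y)
        assert fit.coefficients["intercept"] == pytest.approx(-1.0, abs=0.15)
        assert fit.coefficients["x1"] == pytest.approx(0.8, abs=0.15)
        assert fit.coefficients["x2"] == pytest.approx(0.5, abs=0.15)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X, y = simulate_logistic(rng, 500, (-0.5, 1.0, -0.7))
        fit = fit_logistic(X, y)
        res = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coefficients["intercept"] == pytest.approx(res.params["const"], abs=1e-6)
        assert fit.coefficients["x1"] == pytest.approx(res.params["x1"], abs=1e-6)
        assert fit.coefficients["x2"] == pytest.approx(res.params["x2"], abs=1e-6)

    def test_separable_data_raises_the_separation_flag(self):
        X = pd.DataFrame({"x1": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]})
        y = [0, 0, 0, 1, 1, 1]
        fit = fit_logistic(X, y)
        assert fit.separation

    def test_single_class_outcome_is_an_error(self):
        X = pd.DataFrame({"x1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_logistic(X, [1, 1, 1])

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X, y = simulate_logistic(rng, 200, (0.0, 1.0, 0.0))
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_logistic(X, y)
        assert "flat" not in fit.coefficients


class TestAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_pair_counting_example(self):
        assert evaluate_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert evaluate_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_one_class_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = np.round(rng.random(60), 2)  # rounding forces ties
        labels = (rng.random(60) < 0.4).astype(int)
        ours = evaluate_auc(scores, labels)
        assert ours == pytest.approx(auc_pair_oracle(scores, labels), rel=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30), st.data())
    def test_invariant_under_strictly_increasing_transform(self, scores, data):
        scores = [round(s, 3) for s in scores]  # keep the transform injective in float64
        labels = data.draw(st.lists(st.sampled_from([0, 1]),
                                    min_size=len(scores), max_size=len(scores)))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        transformed = [np.exp(0.5 * s) + 3 for s in scores]
        assert evaluate_auc(scores, labels) == pytest.approx(
            evaluate_auc(transformed, labels), rel=1e-12)


class TestCrossCohort:
    def test_train_equals_test_with_separable_data(self):
        df = pd.DataFrame({
            "psa": [0.1, 0.2, 0.3, 2.1, 2.2, 2.3],
            "isup": [1.0, 1.0, 2.0, 5.0, 5.0, 4.0],
            "metastasis": [0, 0, 0, 1, 1, 1],
        })
        full, control = cross_cohort_evaluate(df, df, ["psa", "isup"], ["psa"])
        assert full.auc_train == 1.0 and full.auc_test == 1.0
        assert control.auc_test == 1.0

    def test_missing_feature_in_test_cohort_is_an_error(self):
        train = pd.DataFrame({"psa": [0.1, 2.0], "gene": [0, 1], "metastasis": [0, 1]})
        test = pd.DataFrame({"psa": [0.5, 1.0], "metastasis": [0, 1]})
        with pytest.raises(ValueError, match="missing from test cohort"):
            cross_cohort_evaluate(train, test, ["psa", "gene"], ["psa"])


def test_make_feature_table_transforms_and_indicators():
    clinical = [
        ClinicalRecord(sample_id="P1", age=70, psa=99.0, isup=4, metastasis="M1"),
        ClinicalRecord(sample_id="P2", age=60, psa=0.0, isup=1, metastasis="M0"),
    ]
    table = make_feature_table(clinical, {"TSC2": {"P1"}}, ["TSC2"])
    assert table.loc["P1", "psa"] == pytest.approx(2.0)  # log10(100)
    assert table.loc["P2", "psa"] == 0.0
    assert table.loc["P1", "TSC2"] == 1.0 and table.loc["P2", "TSC2"] == 0.0
    assert table.loc["P1", "metastasis"] == 1
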