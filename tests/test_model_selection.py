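"""AICc machinery: enumeration, weights, nested filtering, averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pglspath as pp
from pglspath.model_selection import CandidateModel, rank_models

from conftest import PUBLISHED_LH_MODELS, published_candidates


class TestEnumeration:
    def test_life_history_candidate_count(self):
        sets = pp.enumerate_candidates(
            ["CS", "PR", "FM", "BM", "NP"],
            min_size=1, max_size=4,
            forbidden_pair_with_others=("BM", "NP"),
            include_null=True,
        )
        assert len(sets) == 25
        # the bare forbidden pair itself is retained
        assert ("BM", "NP") in sets
        # but no larger set contains both members
        for s in sets:
            if len(s) > 2:
                assert not ({"BM", "NP"} <= set(s))

    @pytest.mark.parametrize("n_pred,expected", [(11, 2048), (9, 512)])
    def test_all_subset_counts(self, n_pred, expected):
        sets = pp.enumerate_candidates(
            [f"v{i}" for i in range(n_pred)], min_size=0, include_null=False
        )
        assert len(sets) == expected

    def test_forbidden_pair_must_be_present(self):
        with pytest.raises(ValueError):
            pp.enumerate_candidates(["a", "b"], forbidden_pair_with_others=("a", "zzz"))

    def test_duplicate_predictors_rejected(self):
        with pytest.raises(ValueError):
            pp.enumerate_candidates(["a", "a"])


class TestAICc:
    def test_equal_inputs_equal_outputs(self):
        assert pp.aicc(-50.0, 3, 40) == pp.aicc(-50.0, 3, 40)

    def test_plug_in_arithmetic(self):
        assert pp.aicc(-70.0, 2, 65) == pytest.approx(144.1935, abs=1e-4)

    def test_extra_parameter_costs_two_at_large_n(self):
        diff = pp.aicc(-70.0, 3, 10**6) - pp.aicc(-70.0, 2, 10**6)
        assert diff == pytest.approx(2.0, abs=1e-3)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            pp.aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_single_model(self):
        assert pp.akaike_weights([123.4]) == pytest.approx([1.0])

    def test_two_models_delta_two(self):
        w = pp.akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.731, abs=1e-3)
        assert w[1] == pytest.approx(0.269, abs=1e-3)

    def test_published_table_top_weight(self):
        w = pp.akaike_weights(list(PUBLISHED_LH_MODELS.values()))
        assert w[0] == pytest.approx(0.314, abs=1e-3)

    @given(st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weights_sum_to_one(self, aiccs):
        assert pp.akaike_weights(aiccs).sum() == pytest.approx(1.0)


class TestTrulyCompetingFilter:
    def test_published_table_yields_six_models(self):
        comp = pp.truly_competing_filter(published_candidates())
        names = {m.predictors for m in comp}
        assert names == {
            ("CS", "PR", "FM"), ("CS", "PR"), ("CS", "FM"),
            ("PR", "FM"), ("PR",), ("CS",),
        }
        assert comp[0].weight == pytest.approx(0.63, abs=5e-3)
        assert sum(m.weight for m in comp) == pytest.approx(1.0)

    def test_no_nesting_keeps_all_plausible(self):
        models = [
            CandidateModel(predictors=("a",), aicc=100.0, K=3),
            CandidateModel(predictors=("b",), aicc=101.0, K=3),
            CandidateModel(predictors=("c",), aicc=108.0, K=3),
            CandidateModel(predictors=("d",), aicc=120.0, K=3),
        ]
        comp = pp.truly_competing_filter(models)
        assert {m.predictors for m in comp} == {("a",), ("b",), ("c",)}

    def test_superset_with_lower_aicc_not_removed(self):
        # removal only goes one way: a better-supported superset survives,
        # and so does its worse subset
        models = [
            CandidateModel(predictors=("a", "b"), aicc=100.0, K=4),
            CandidateModel(predictors=("a",), aicc=103.0, K=3),
        ]
        comp = pp.truly_competing_filter(models)
        assert {m.predictors for m in comp} == {("a", "b"), ("a",)}

    def test_order_invariance(self):
        cands = published_candidates()
        rev = list(reversed(cands))
        a = {m.predictors for m in pp.truly_competing_filter(cands)}
        b = {m.predictors for m in pp.truly_competing_filter(rev)}
        assert a == b


class TestEvidenceRatio:
    def test_identical_models(self):
        assert pp.evidence_ratio(100.0, 100.0) == pytest.approx(1.0)

    def test_published_ratios(self):
        t = PUBLISHED_LH_MODELS
        assert pp.evidence_ratio(t[("CS", "PR", "FM")], t[("CS", "FM")]) == pytest.approx(
            7.8, abs=0.1
        )
        assert pp.evidence_ratio(t[("PR",)], t[()]) == pytest.approx(681, rel=0.01)
        assert pp.evidence_ratio(t[("CS",)], t[()]) == pytest.approx(339, rel=0.01)

    @given(
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=0, max_value=300),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_transitivity(self, a, b, c):
        lhs = pp.evidence_ratio(a, b) * pp.evidence_ratio(b, c)
        assert lhs == pytest.approx(pp.evidence_ratio(a, c), rel=1e-9)


class TestPartialSDStandardize:
    def _fit(self, X, y):
        return pp.fit_gls(y, X, np.eye(len(y)), names=[f"x{j}" for j in range(X.shape[1])])

    def test_orthogonal_large_n_matches_classic(self, rng):
        n = 4000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 0.5 * x1 - 0.2 * x2 + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x1, x2])
        res = pp.fit_gls(y, X, np.eye(n), names=["const", "x1", "x2"])
        est, _ = pp.partial_sd_standardize(res, X, y, names=["const", "x1", "x2"])
        s_y = np.std(y, ddof=1)
        classic = {
            "x1": res.params[1] * np.std(x1, ddof=1) / s_y,
            "x2": res.params[2] * np.std(x2, ddof=1) / s_y,
        }
        for k in classic:
            assert est[k] == pytest.approx(classic[k], rel=0.01)

    def test_duplicated_predictor_flagged_undefined(self, rng):
        n = 30
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x + 0.0])
        res = pp.PGLSResults(
            params=np.array([0.0, 1.0, 1.0]), bse=np.ones(3), df_resid=n - 3,
            nobs=n, lambda_hat=0.0, llf=0.0, sigma2_ml=1.0,
            exog_names=["const", "a", "b"],
        )
        est, err = pp.partial_sd_standardize(res, X, y, names=["const", "a", "b"])
        assert math.isnan(est["a"]) and math.isnan(est["b"])

    def test_two_predictor_closed_form(self, rng):
        n = 60
        r = 0.5
        z = rng.standard_normal((n, 2))
        x1 = z[:, 0]
        x2 = r * z[:, 0] + math.sqrt(1 - r * r) * z[:, 1]
        y = x1 - x2 + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x1, x2])
        res = pp.fit_gls(y, X, np.eye(n), names=["const", "x1", "x2"])
        est, err = pp.partial_sd_standardize(res, X, y, names=["const", "x1", "x2"])
        # formula oracle evaluated by hand
        r_emp = np.corrcoef(x1, x2)[0, 1]
        vif_val = 1.0 / (1.0 - r_emp**2)
        s_y = np.std(y, ddof=1)
        for j, name in ((1, "x1"), (2, "x2")):
            s_star = (
                np.std(X[:, j], ddof=1) / math.sqrt(vif_val) * math.sqrt((n - 1) / (n - 3))
            )
            assert est[name] == pytest.approx(res.params[j] * s_star / s_y, rel=1e-9)
            assert err[name] == pytest.approx(res.bse[j] * s_star / s_y, rel=1e-9)


class TestModelAverage:
    def test_published_importances(self):
        models = [
            CandidateModel(
                predictors=("PR", "CS", "FM"), aicc=0.0, K=5, weight=1.0,
                std_estimates={"PR": -0.280, "CS": -0.272, "FM": -0.238},
                std_errors={"PR": 0.1, "CS": 0.1, "FM": 0.1},
            )
        ]
        avg = pp.model_average(models, predictors=["PR", "CS", "FM"])
        assert avg.loc["PR", "importance"] == pytest.approx(1.00, abs=5e-3)
        assert avg.loc["CS", "importance"] == pytest.approx(0.97, abs=5e-3)
        assert avg.loc["FM", "importance"] == pytest.approx(0.85, abs=5e-3)

    def test_single_model_subset_returns_own_estimates(self):
        m = CandidateModel(
            predictors=("a",), aicc=1.0, K=3, weight=1.0,
            std_estimates={"a": 0.4}, std_errors={"a": 0.1},
        )
        avg = pp.model_average([m], predictors=["a", "b"])
        assert avg.loc["a", "beta"] == pytest.approx(0.4)
        assert avg.loc["a", "importance"] == pytest.approx(1.0)

    def test_absent_predictor_zeroed(self):
        m = CandidateModel(
            predictors=("a",), aicc=1.0, K=3, weight=1.0,
            std_estimates={"a": 0.4}, std_errors={"a": 0.1},
        )
        avg = pp.model_average([m], predictors=["a", "b"])
        assert avg.loc["b", "beta"] == 0.0
        assert avg.loc["b", "importance"] == 0.0

    def test_zero_substitution_weighting(self):
        models = [
            CandidateModel(
                predictors=("a",), aicc=0.0, K=3, weight=0.75,
                std_estimates={"a": 0.4}, std_errors={"a": 0.2},
            ),
            CandidateModel(
                predictors=("b",), aicc=2.0, K=3, weight=0.25,
                std_estimates={"b": -0.8}, std_errors={"b": 0.4},
            ),
        ]
        avg = pp.model_average(models, predictors=["a", "b"])
        assert avg.loc["a", "beta"] == pytest.approx(0.75 * 0.4)
        assert avg.loc["b", "beta"] == pytest.approx(0.25 * -0.8)
        assert avg.loc["a", "SE"] == pytest.approx(0.75 * 0.2)


def test_selection_end_to_end_recovers_generating_predictors(study_fixture):
    """On synthetic data the generating predictors (clutch size and
    provisioning rate) should dominate the averaged importance ranking."""
    result = pp.ModelSelection(
        study_fixture.table,
        "aggression",
        ["clutch_size", "provisioning_rate", "body_mass", "nestling_period"],
        study_fixture.tree,
        max_size=3,
        forbidden_pair=("body_mass", "nestling_period"),
        grid_size=100,
    ).fit()
    assert sum(m.weight for m in result.competitive) == pytest.approx(1.0)
    avg = result.averaged
    top_two = set(avg["importance"].nlargest(2).index)
    assert top_two == {"clutch_size", "provisioning_rate"}
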