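import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import greyhybrid as gh
from greyhybrid.grey import GreyModelError, MODEL_REGISTRY

GEOMETRIC = np.array([2.0, 4.0, 8.0, 16.0, 32.0])
CHINA_TRAIN = np.array(
    [12212, 11805, 14296, 13744, 18128, 27240, 29879, 27420, 26393, 29972], dtype=float
)


def normal_equation_ols(design, response):
    """Independent textbook oracle: explicit (X'X)^-1 X'y."""
    xtx = design.T @ design
    return np.linalg.solve(xtx, design.T @ response)


class TestAccumulation:
    def test_ago_unit_and_hand_sum(self):
        np.testing.assert_array_equal(gh.ago([1, 1, 1]), [1, 2, 3])
        assert gh.ago(CHINA_TRAIN)[1] == 24017  # 12212 + 11805
        np.testing.assert_array_equal(gh.ago([5.0]), [5.0])

    def test_ago_rejects_non_positive(self):
        with pytest.raises(GreyModelError):
            gh.ago([1.0, -1.0])

    def test_iago_inverts_ago(self):
        v = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(gh.iago(gh.ago(v), v[0]), v)
        np.testing.assert_array_equal(gh.iago(np.array([2.0, 6, 14, 30, 62]), 2.0), GEOMETRIC)
        np.testing.assert_array_equal(gh.iago(np.array([7.0]), 7.0), [7.0])

    def test_background_means(self):
        np.testing.assert_array_equal(gh.background([2.0, 4.0]), [3.0])
        assert gh.background(gh.ago(CHINA_TRAIN))[0] == 18114.5
        np.testing.assert_array_equal(gh.background([4.0, 4.0, 4.0]), [4.0, 4.0])
        with pytest.raises(GreyModelError):
            gh.background([1.0])


class TestParameterEstimates:
    """Hand-solved normal equations on the homogeneous exponential (2,4,...,32)."""

    def test_dgm_recovers_ratio_exactly(self):
        m = gh.DiscreteGreyModel().fit(GEOMETRIC)
        assert m.beta1_ == pytest.approx(2.0, abs=1e-10)
        assert m.beta2_ == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(m.fitted_, GEOMETRIC, rtol=1e-10)

    def test_odgm_hand_solved_parameters(self):
        m = gh.OriginalDifferenceGreyModel().fit(GEOMETRIC)
        assert m.a_ == pytest.approx(-0.5, abs=1e-10)
        assert m.b_ == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(m.fitted_, GEOMETRIC, rtol=1e-10)

    def test_edgm_hand_solved_parameters(self):
        m = gh.EvenDifferenceGreyModel().fit(GEOMETRIC)
        assert m.a_ == pytest.approx(-2.0 / 3.0, abs=1e-10)
        assert m.b_ == pytest.approx(4.0 / 3.0, abs=1e-9)
        np.testing.assert_allclose(m.fitted_, GEOMETRIC, rtol=1e-10)

    def test_egm_development_coefficient_matches_ols_oracle(self):
        m = gh.EvenGreyModel().fit(CHINA_TRAIN)
        x1 = np.cumsum(CHINA_TRAIN)
        z = 0.5 * (x1[1:] + x1[:-1])
        a, b = normal_equation_ols(np.column_stack([-z, np.ones(9)]), CHINA_TRAIN[1:])
        assert m.a_ == pytest.approx(a, rel=1e-9)
        assert m.a_ == pytest.approx(-0.1032, abs=5e-5)
        assert m.b_ == pytest.approx(b, rel=1e-9)

    def test_verhulst_parameters_match_ols_oracle(self):
        m = gh.GreyVerhulst().fit(CHINA_TRAIN)
        z = 0.5 * (CHINA_TRAIN[1:] + CHINA_TRAIN[:-1])
        a, b = normal_equation_ols(np.column_stack([-z, z**2]), np.diff(CHINA_TRAIN))
        assert m.a_ == pytest.approx(a, rel=1e-9)
        assert m.b_ == pytest.approx(b, rel=1e-9)
        assert m.capacity_ == pytest.approx(a / b, rel=1e-9)


@st.composite
def exponential_series(draw):
    q = draw(st.floats(0.5, 20.0))
    r = draw(st.floats(0.6, 1.5))
    n = draw(st.integers(4, 12))
    return q * r ** np.arange(n), r


class TestExactness:
    """The difference-form models reproduce homogeneous exponentials exactly."""

    @pytest.mark.parametrize("model_id", ["ODGM", "EDGM", "DGM"])
    @given(case=exponential_series())
    def test_difference_models_exact_on_exponentials(self, model_id, case):
        x0, r = case
        m = gh.fit_grey(model_id, x0)
        np.testing.assert_allclose(m.fitted_, x0, rtol=1e-8)
        future = x0[-1] * r ** np.arange(1, 4)
        np.testing.assert_allclose(m.forecast(3), future, rtol=1e-8)

    def test_egm_not_exact_on_exponentials(self):
        m = gh.EvenGreyModel().fit(GEOMETRIC)
        assert np.max(np.abs(m.fitted_ - GEOMETRIC)) > 1e-6

    @given(case=exponential_series())
    def test_dgm_beta1_recovers_ratio(self, case):
        x0, r = case
        m = gh.DiscreteGreyModel().fit(x0)
        assert m.beta1_ == pytest.approx(r, rel=1e-8)


class TestInvariants:
    @pytest.mark.parametrize("model_id", gh.MODEL_ORDER)
    def test_first_value_anchoring(self, model_id, china_fits):
        fit = china_fits[model_id]
        assert fit.fitted_[0] == fit.x0_[0]

    def test_growth_ratio_identities(self, china_fits):
        for mid, ratio in [
            ("EGM", np.exp(-china_fits["EGM"].a_)),
            ("EDGM", (1 - china_fits["EDGM"].a_ / 2) / (1 + china_fits["EDGM"].a_ / 2)),
            ("ODGM", 1 / (1 + china_fits["ODGM"].a_)),
            ("DGM", china_fits["DGM"].beta1_),
        ]:
            f = china_fits[mid].fitted_
            np.testing.assert_allclose(f[2:] / f[1:-1], ratio, rtol=1e-9, err_msg=mid)

    def test_forecast_prefix_consistency(self, china_fits):
        for fit in china_fits.values():
            one = fit.forecast(1)
            three = fit.forecast(3)
            assert one[0] == pytest.approx(three[0], rel=1e-12)

    def test_verhulst_monotone_saturation(self, china_fits):
        v = china_fits["VERHULST"]
        path = np.concatenate([v.fitted_, v.forecast(10)])
        assert np.all(np.diff(path) > 0)
        assert np.all(path < v.capacity_)

    def test_verhulst_fits_logistic_data(self):
        s = gh.generate_series("logistic", n=12, seed=3, params={"capacity": 500.0, "x1": 30.0})
        m = gh.GreyVerhulst().fit(s.values)
        assert m.capacity_ == pytest.approx(500.0, rel=0.05)
        np.testing.assert_allclose(m.fitted_[1:], s.values[1:], rtol=0.05)


class TestDegenerateInputs:
    def test_even_models_fit_constant_series_exactly(self):
        const = np.full(6, 7.5)
        for cls in (gh.EvenGreyModel, gh.EvenDifferenceGreyModel):
            m = cls().fit(const)
            assert m.a_ == 0.0
            np.testing.assert_allclose(m.fitted_, const, rtol=1e-12)
            np.testing.assert_allclose(m.forecast(2), [7.5, 7.5], rtol=1e-12)

    def test_fit_all_collects_verhulst_rank_error_on_constant(self):
        const = gh.AnnualSeries(2000 + np.arange(6), np.full(6, 3.0))
        fits, errors = gh.fit_all(const)
        assert set(errors) == {"VERHULST"}
        assert set(fits) == {"EGM", "EDGM", "ODGM", "DGM"}

    def test_short_or_negative_series_rejected(self):
        with pytest.raises(GreyModelError):
            gh.fit_grey("EGM", [1.0, 2.0, 3.0])
        with pytest.raises(GreyModelError):
            gh.fit_grey("DGM", [1.0, -2.0, 3.0, 4.0])
        with pytest.raises(GreyModelError):
            gh.fit_grey("nope", GEOMETRIC)


class TestParameterRecovery:
    def test_dgm_recovers_ratio_under_noise(self):
        """Median relative error of beta1 vs the true ratio stays below 5%
        for multiplicative noise with sd 0.05 at n=20, over 100 seeds."""
        r = 1.1
        errs = []
        for seed in range(100):
            s = gh.generate_series(
                "geometric", n=20, seed=seed, noise_sd=0.05, params={"q": 100.0, "r": r}
            )
            m = gh.DiscreteGreyModel().fit(s.values)
            errs.append(abs(m.beta1_ - r) / r)
        assert np.median(errs) < 0.05


class TestReporting:
    def test_fitted_table_shape_and_serialization(self, china_fits, china_split):
        table = gh.fitted_table(china_fits, china_split)
        assert list(table.columns) == ["year", "actual"] + list(gh.MODEL_ORDER)
        assert len(table) == 13
        doc = china_fits["DGM"].to_dict(horizon=3)
        assert doc["model_id"] == "DGM"
        assert len(doc["fitted"]) == 10 and len(doc["forecast"]) == 3
        assert set(doc["params"]) == {"beta1", "beta2"}

    def test_sklearn_param_interface(self):
        m = gh.DiscreteGreyModel()
        assert m.get_params() == {}
        ann = gh.SigmoidNeuralRegressor(hidden_units=3)
        assert ann.get_params()["hidden_units"] == 3
        ann.set_params(decay=1.0)
        assert ann.decay == 1.0
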