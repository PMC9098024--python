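"""Derived economics: elasticities, marginal products, MRTS, validity."""

import numpy as np
import pandas as pd
import pytest

from hospprod import CobbDouglasParams, TranslogParams
from hospprod.economics import (
    UndefinedSubstitutionError,
    UnsupportedFormError,
    economic_profile,
    elasticities,
    fitted_output,
    growth_rates,
    marginal_products,
    mrts,
    percent_substitution,
    returns_to_scale,
    substitution_elasticity,
    validity_flags,
)

CD = CobbDouglasParams(0.0, {"electricity": 0.48, "nurses": 0.2})
MEANS = {"electricity": 10.076, "nurses": 383.63}
MEDIANS = {"electricity": 7.395, "nurses": 189.47}


def _random_translog(rng, names=("beds", "electricity", "nurses")):
    lin = dict(zip(names, rng.uniform(0.05, 0.6, len(names))))
    quad = {}
    for a in range(len(names)):
        for b in range(a, len(names)):
            quad[(names[a], names[b])] = rng.normal(scale=0.03)
    return TranslogParams(rng.normal(), lin, quad)


def _random_point(rng, names):
    return dict(zip(names, rng.uniform(2.0, 500.0, len(names))))


class TestElasticities:
    def test_cd_equals_exponents_everywhere(self):
        for x in (MEANS, MEDIANS, {"electricity": 1.0, "nurses": 1.0}):
            E = elasticities(CD, x)
            assert E["electricity"] == 0.48 and E["nurses"] == 0.2

    def test_translog_with_zero_quad_nests_cd(self):
        tl = TranslogParams(0.0, {"electricity": 0.48, "nurses": 0.2})
        pd.testing.assert_series_equal(elasticities(tl, MEANS),
                                       elasticities(CD, MEANS))

    def test_matches_central_difference_in_logs(self, rng):
        h = 1e-6
        for _ in range(5):
            tl = _random_translog(rng)
            x = _random_point(rng, tl.input_names)
            E = elasticities(tl, x)
            for k in tl.input_names:
                up = dict(x); up[k] = x[k] * (1 + h)
                dn = dict(x); dn[k] = x[k] * (1 - h)
                num = (np.log(fitted_output(tl, up)) - np.log(fitted_output(tl, dn)))
                num /= np.log(up[k]) - np.log(dn[k])
                assert E[k] == pytest.approx(num, abs=1e-6)


class TestMarginalProductsAndGrowth:
    def test_linear_function_has_unit_marginal_product(self):
        p = CobbDouglasParams(0.0, {"beds": 1.0})
        for b in (3.0, 57.0, 599.0):
            assert marginal_products(p, {"beds": b})["beds"] == pytest.approx(1.0)

    def test_reported_pair_consistency_at_means(self):
        """The two marginal products tie together through f(x)/x_i.

        With elasticities (0.48, 0.2), calibrating the output level so the
        electricity marginal product is 3.0993 forces the nurses marginal
        product to (0.2/0.48)*(10.076/383.63)*3.0993 ~ 0.034.
        """
        f = 3.0993 * MEANS["electricity"] / 0.48  # level giving T_elec = 3.0993
        scaled = CobbDouglasParams(
            np.log(f) - 0.48 * np.log(MEANS["electricity"]) - 0.2 * np.log(MEANS["nurses"]),
            {"electricity": 0.48, "nurses": 0.2})
        T = marginal_products(scaled, MEANS)
        assert T["electricity"] == pytest.approx(3.0993, rel=1e-10)
        assert T["nurses"] == pytest.approx(0.034, abs=5e-4)

    def test_matches_central_difference_gradient(self, rng):
        h = 1e-6
        for params_maker in (lambda: _random_translog(rng),
                             lambda: CobbDouglasParams(
                                 rng.normal(), {"beds": rng.uniform(0.1, 0.9),
                                                "nurses": rng.uniform(0.1, 0.9)})):
            params = params_maker()
            x = _random_point(rng, params.input_names)
            T = marginal_products(params, x)
            for k in params.input_names:
                up = dict(x); up[k] = x[k] * (1 + h)
                dn = dict(x); dn[k] = x[k] * (1 - h)
                num = (fitted_output(params, up) - fitted_output(params, dn)) / (up[k] - dn[k])
                assert T[k] == pytest.approx(num, rel=1e-6)

    def test_growth_rate_worked_value(self):
        # E_nurses = 0.2 at the median 189.47 nurse FTEs -> 0.2/189.47
        S = growth_rates(CD, MEDIANS)
        assert S["nurses"] == pytest.approx(0.0010556, abs=1e-6)
        assert round(S["nurses"], 4) == 0.0011

    def test_zero_elasticity_gives_zero_growth(self):
        p = CobbDouglasParams(0.0, {"beds": 0.0, "nurses": 0.5})
        assert growth_rates(p, {"beds": 10.0, "nurses": 10.0})["beds"] == 0.0

    def test_identity_chain(self, rng):
        """T_i = E_i f/x_i = S_i f to 1e-10 relative."""
        for _ in range(5):
            params = _random_translog(rng)
            x = _random_point(rng, params.input_names)
            f = fitted_output(params, x)
            E, T, S = elasticities(params, x), marginal_products(params, x), growth_rates(params, x)
            for k in params.input_names:
                assert T[k] == pytest.approx(E[k] * f / x[k], rel=1e-10)
                assert T[k] == pytest.approx(S[k] * f, rel=1e-10)
                assert S[k] * x[k] == pytest.approx(E[k], rel=1e-10)


class TestReturnsToScale:
    def test_cd_sum_of_exponents(self):
        assert returns_to_scale(CD, MEANS) == pytest.approx(0.68)
        assert returns_to_scale(CD, MEANS) < 1  # decreasing returns

    def test_constant_returns_when_exponents_sum_to_one(self):
        p = CobbDouglasParams(0.2, {"beds": 0.6, "nurses": 0.4})
        assert returns_to_scale(p, {"beds": 9.0, "nurses": 2.0}) == pytest.approx(1.0)

    def test_translog_matches_scale_derivative(self, rng):
        h = 1e-6
        for _ in range(5):
            tl = _random_translog(rng)
            x = _random_point(rng, tl.input_names)
            up = {k: v * (1 + h) for k, v in x.items()}
            dn = {k: v * (1 - h) for k, v in x.items()}
            num = (np.log(fitted_output(tl, up)) - np.log(fitted_output(tl, dn)))
            num /= np.log(1 + h) - np.log(1 - h)
            assert returns_to_scale(tl, x) == pytest.approx(num, abs=1e-6)

    def test_cd_invariant_translog_not(self, rng):
        tl = _random_translog(rng)
        a, b = _random_point(rng, tl.input_names), _random_point(rng, tl.input_names)
        assert returns_to_scale(CD, MEANS) == returns_to_scale(CD, MEDIANS)
        assert returns_to_scale(tl, a) != pytest.approx(returns_to_scale(tl, b))


class TestSubstitution:
    def test_mrts_worked_example_medians(self):
        sig = mrts(CD, MEDIANS, "electricity", "nurses")
        assert sig == pytest.approx((0.48 / 0.2) * (189.47 / 7.395), rel=1e-12)
        assert sig == pytest.approx(61.49, abs=0.01)
        assert 1.0 / sig == pytest.approx(0.016, abs=5e-4)

    def test_mrts_reciprocity(self, rng):
        for _ in range(5):
            tl = _random_translog(rng)
            x = _random_point(rng, tl.input_names)
            s_ij = mrts(tl, x, "beds", "nurses")
            s_ji = mrts(tl, x, "nurses", "beds")
            assert s_ij * s_ji == pytest.approx(1.0, rel=1e-10)

    def test_mrts_translog_three_factor_worked_example(self):
        # elasticities at means: nurses 0.3641, electricity 0.3198
        tl = TranslogParams(0.0, {"nurses": 0.3641, "electricity": 0.3198,
                                  "services": 0.1783})
        x = {"nurses": 383.63, "electricity": 10.076, "services": 160.95}
        assert mrts(tl, x, "nurses", "electricity") == pytest.approx(0.0299, abs=5e-5)

    def test_zero_denominator_elasticity_raises(self):
        p = CobbDouglasParams(0.0, {"beds": 0.5, "nurses": 0.0})
        with pytest.raises(UndefinedSubstitutionError):
            mrts(p, {"beds": 1.0, "nurses": 1.0}, "beds", "nurses")
        with pytest.raises(UndefinedSubstitutionError):
            percent_substitution(p, {"beds": 1.0, "nurses": 1.0}, "beds", "nurses")

    def test_percent_substitution_worked_examples(self):
        tl = TranslogParams(0.0, {"nurses": 0.3641, "electricity": 0.3198,
                                  "services": 0.1783})
        x = {"nurses": 383.63, "electricity": 10.076, "services": 160.95}
        assert percent_substitution(tl, x, "nurses", "services") == pytest.approx(2.04, abs=5e-3)
        assert percent_substitution(CD, MEANS, "nurses", "electricity") == pytest.approx(0.42, abs=5e-3)
        assert percent_substitution(CD, MEANS, "nurses", "nurses") == 1.0

    def test_percent_substitution_reciprocity(self):
        a = percent_substitution(CD, MEANS, "electricity", "nurses")
        b = percent_substitution(CD, MEANS, "nurses", "electricity")
        assert a * b == pytest.approx(1.0, rel=1e-12)

    def test_cd_substitution_elasticity_is_one(self, rng):
        for _ in range(5):
            x = _random_point(rng, ("electricity", "nurses"))
            assert substitution_elasticity(CD, x, "electricity", "nurses") == 1.0

    def test_translog_substitution_elasticity_unsupported(self):
        tl = TranslogParams(0.0, {"a": 0.3, "b": 0.3})
        with pytest.raises(UnsupportedFormError):
            substitution_elasticity(tl, {"a": 1.0, "b": 1.0}, "a", "b")

    def test_isoquant_tracing_confirms_unit_elasticity(self):
        """Numeric oracle: along a CD isoquant, d ln(x2/x1) / d ln(MRTS) = 1."""
        p = CobbDouglasParams(0.3, {"a": 0.6, "b": 0.3})
        y0 = fitted_output(p, {"a": 10.0, "b": 20.0})

        def on_isoquant(a):
            # solve 0.3 + 0.6 ln a + 0.3 ln b = ln y0 for b
            b = np.exp((np.log(y0) - 0.3 - 0.6 * np.log(a)) / 0.3)
            return {"a": a, "b": b}

        pts = [on_isoquant(a) for a in (10.0, 10.0 * 1.001)]
        sig = [mrts(p, x, "a", "b") for x in pts]
        ratio = [x["b"] / x["a"] for x in pts]
        slope = (np.log(ratio[1]) - np.log(ratio[0])) / (np.log(sig[1]) - np.log(sig[0]))
        assert slope == pytest.approx(1.0, abs=1e-4)


class TestValidityAndProfile:
    def test_all_positive_elasticities_valid(self):
        valid, bad = validity_flags(pd.Series({"beds": 0.5, "nurses": 0.1}))
        assert valid and bad == []

    def test_negative_elasticity_flagged(self):
        valid, bad = validity_flags(pd.Series({"doctors": -0.1, "beds": 0.5}))
        assert not valid and bad == ["doctors"]

    def test_cd_negative_exponent_flagged_at_every_point(self, rng):
        p = CobbDouglasParams(0.0, {"beds": 0.5, "doctors": -0.2})
        for _ in range(5):
            x = _random_point(rng, p.input_names)
            prof = economic_profile(p, x)
            assert not prof.valid_production_function
            assert prof.violations == ["doctors"]

    def test_profile_internal_consistency(self):
        prof = economic_profile(CD, MEANS, label="means")
        assert prof.returns_to_scale == pytest.approx(0.68)
        assert prof.substitution_elasticity_cd == 1.0
        assert prof.mrts.loc["electricity", "nurses"] * \
            prof.mrts.loc["nurses", "electricity"] == pytest.approx(1.0)
        assert prof.percent_substitution.loc["nurses", "electricity"] == \
            pytest.approx(0.2 / 0.48)
        d = prof.to_dict()
        assert d["valid_production_function"] is True
        assert "electricity->nurses" in d["mrts"]
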