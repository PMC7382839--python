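"""PAF engines: categorical closed form, dose-response quadrature, combination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paftool.models import (
    ContinuousDistribution,
    ExposureDistribution,
    RelativeRiskSet,
    ValidationError,
)
from paftool.paf import (
    DoseResponseModel,
    combine_pafs,
    paf_categorical,
    paf_continuous,
    rr_at_dose,
)

LEVELS2 = ("ref", "exposed")


def _pair(proportions, rr, levels=None):
    levels = levels or tuple(f"l{i}" for i in range(len(proportions)))
    dist = ExposureDistribution("x", "male", levels, np.asarray(proportions))
    rrset = RelativeRiskSet(
        "x", "site", "male", "categorical", levels=levels, rr=np.asarray(rr)
    )
    return dist, rrset


class TestCategorical:
    def test_population_at_counterfactual_gives_zero(self):
        dist, rr = _pair([1.0, 0.0], [1.0, 5.0])
        assert paf_categorical(dist, rr).paf == 0.0

    def test_null_risk_gives_zero(self):
        dist, rr = _pair([0.2, 0.3, 0.5], [1.0, 1.0, 1.0])
        assert paf_categorical(dist, rr).paf == 0.0

    def test_half_half_doubled_risk(self):
        dist, rr = _pair([0.5, 0.5], [1.0, 2.0])
        assert paf_categorical(dist, rr).paf == pytest.approx(1 / 3, abs=1e-12)

    def test_misaligned_levels_rejected(self):
        dist = ExposureDistribution("x", "male", LEVELS2, [0.5, 0.5])
        rr = RelativeRiskSet(
            "x", "site", "male", "categorical",
            levels=("other", "labels"), rr=[1.0, 2.0],
        )
        with pytest.raises(ValidationError):
            paf_categorical(dist, rr)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValidationError):
            RelativeRiskSet(
                "x", "s", "male", "categorical", levels=LEVELS2, rr=[1.0, 0.0]
            )

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=1.0),
                st.floats(min_value=1.0, max_value=10.0),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_closed_form_equivalence(self, data):
        """The two-sum PAF equals 1 - 1/sum(P_i RR_i) when RR[tmrel]=1."""
        raw_p = np.array([p for p, _ in data])
        p = raw_p / raw_p.sum()
        rr = np.array([r for _, r in data])
        rr[0] = 1.0
        dist, rrset = _pair(p, rr)
        expected = 1.0 - 1.0 / float(np.dot(p, rr))
        assert paf_categorical(dist, rrset).paf == pytest.approx(
            expected, abs=1e-12
        )

    def test_merging_levels_with_equal_rr_is_invariant(self):
        dist, rr = _pair([0.2, 0.3, 0.5], [1.0, 2.5, 2.5])
        merged_dist, merged_rr = _pair([0.2, 0.8], [1.0, 2.5])
        assert paf_categorical(dist, rr).paf == pytest.approx(
            paf_categorical(merged_dist, merged_rr).paf, abs=1e-14
        )

    def test_moving_mass_off_tmrel_increases_paf(self):
        base, rr = _pair([0.6, 0.4], [1.0, 3.0])
        shifted, _ = _pair([0.4, 0.6], [1.0, 3.0])
        assert paf_categorical(shifted, rr).paf > paf_categorical(base, rr).paf


class TestDoseResponse:
    def test_rr_is_one_at_and_below_tmrel(self):
        for model_id in ("log_linear", "log_logit"):
            model = DoseResponseModel(model_id, rr_per_unit=1.2)
            assert rr_at_dose(22.0, model) == pytest.approx(1.0)
            assert rr_at_dose(18.0, model) == pytest.approx(1.0)

    def test_log_linear_power(self):
        model = DoseResponseModel("log_linear", rr_per_unit=1.05)
        assert rr_at_dose(32.0, model) == pytest.approx(1.05**10)

    def test_invalid_model_id_rejected(self):
        with pytest.raises(ValidationError):
            DoseResponseModel("linear", rr_per_unit=1.05)

    def test_curves_nondecreasing(self):
        x = np.linspace(10, 60, 1001)
        for model_id in ("log_linear", "log_logit"):
            rr = rr_at_dose(x, DoseResponseModel(model_id, rr_per_unit=1.15))
            assert np.all(np.diff(rr) >= -1e-12)

    def test_cap_dose_saturates(self):
        model = DoseResponseModel("log_linear", rr_per_unit=1.1, cap_dose=35.0)
        assert rr_at_dose(50.0, model) == pytest.approx(rr_at_dose(35.0, model))


class TestContinuous:
    def test_flat_dose_response_gives_zero(self):
        dist = ContinuousDistribution("high_bmi", "male", 28.0, 4.0)
        model = DoseResponseModel("log_linear", rr_per_unit=1.0)
        assert paf_continuous(dist, model).paf == pytest.approx(0.0, abs=1e-12)

    def test_distribution_equal_to_counterfactual_gives_zero(self):
        dist = ContinuousDistribution("high_bmi", "male", 22.0, 1.0)
        model = DoseResponseModel("log_linear", rr_per_unit=1.2)
        assert paf_continuous(dist, model).paf == pytest.approx(0.0, abs=1e-12)

    def test_grid_refinement_stability(self):
        dist = ContinuousDistribution("high_bmi", "female", 29.62, 5.6)
        model = DoseResponseModel("log_linear", rr_per_unit=1.12)
        coarse = paf_continuous(dist, model, n_nodes=512).paf
        fine = paf_continuous(dist, model, n_nodes=1024).paf
        assert coarse == pytest.approx(fine, abs=1e-8)

    def test_monte_carlo_oracle_agreement(self):
        """Quadrature PAF within 3 MC standard errors of a sampling estimate."""
        from scipy.stats import truncnorm

        rng = np.random.default_rng(202)
        n = 100_000
        for mean, sd, b in [(28.42, 4.0, 1.10), (26.0, 5.0, 1.05)]:
            dist = ContinuousDistribution("high_bmi", "male", mean, sd)
            model = DoseResponseModel("log_linear", rr_per_unit=b)
            paf = paf_continuous(dist, model).paf

            def draw(m, s):
                a, c = (10.0 - m) / s, (60.0 - m) / s
                x = truncnorm.rvs(a, c, loc=m, scale=s, size=n, random_state=rng)
                rr = rr_at_dose(x, model)
                return rr.mean(), rr.std(ddof=1) / np.sqrt(n)

            i_obs, se_obs = draw(mean, sd)
            i_cf, se_cf = draw(22.0, 1.0)
            ratio = i_cf / i_obs
            se = ratio * np.sqrt((se_obs / i_obs) ** 2 + (se_cf / i_cf) ** 2)
            assert abs(paf - (1 - ratio)) < 3 * se

    def test_overflowing_integrand_advises_cap(self):
        dist = ContinuousDistribution("high_bmi", "male", 28.0, 4.0)
        model = DoseResponseModel("log_linear", rr_per_unit=1e12)
        with pytest.raises(ValidationError, match="cap_dose"):
            paf_continuous(dist, model)

    def test_negative_paf_warns_but_returned(self):
        dist = ContinuousDistribution("high_bmi", "male", 20.0, 0.5)
        model = DoseResponseModel("log_linear", rr_per_unit=1.2)
        with pytest.warns(UserWarning, match="negative PAF"):
            value = paf_continuous(dist, model).paf
        assert value < 0


class TestCombine:
    def test_lung_men_combination(self):
        # smoking, low fruits, passive smoking
        combined = combine_pafs([0.907, 0.143, 0.022])
        assert combined == pytest.approx(1 - 0.093 * 0.857 * 0.978, abs=1e-12)
        assert round(combined * 100, 1) == 92.2

    def test_singleton_identity(self):
        assert combine_pafs([0.37]) == pytest.approx(0.37)

    def test_two_halves(self):
        assert combine_pafs([0.5, 0.5]) == pytest.approx(0.75)

    def test_paf_of_one_rejected(self):
        with pytest.raises(ValidationError):
            combine_pafs([0.5, 1.0])

    @given(
        p1=st.floats(min_value=0, max_value=0.99),
        p2=st.floats(min_value=0, max_value=0.99),
        p3=st.floats(min_value=0, max_value=0.99),
    )
    def test_commutative_associative_inclusion_exclusion(self, p1, p2, p3):
        assert combine_pafs([p1, p2]) == pytest.approx(
            combine_pafs([p2, p1]), abs=1e-12
        )
        assert combine_pafs([p1, p2, p3]) == pytest.approx(
            combine_pafs([combine_pafs([p1, p2]), p3]), abs=1e-12
        )
        assert combine_pafs([p1, p2]) == pytest.approx(
            p1 + p2 - p1 * p2, abs=1e-12
        )
        assert combine_pafs([p1, p2, p3]) >= max(p1, p2, p3) - 1e-12
        assert combine_pafs([p1, p2, p3]) < 1
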