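"""Attribution pipeline: subtype dilution, rounding, aggregation, recovery."""

import numpy as np
import pandas as pd
import pytest

from paftool.attribution import (
    aggregate,
    apply_subtype_restriction,
    attributable_count,
    compute_paf_table,
    reproduce_from_paf_table,
    round_half_away,
    round_paf_percent,
)
from paftool.models import ValidationError


def _tidy(rows):
    return pd.DataFrame(rows, columns=["exposure", "site", "sex", "paf", "total"])


LUNG_ROWS = [
    ("smoking", "lung", "male", 0.907, 2163.0),
    ("fruit", "lung", "male", 0.143, 2163.0),
    ("passive_smoking", "lung", "male", 0.022, 2163.0),
    ("smoking", "lung", "female", 0.873, 1708.0),
    ("fruit", "lung", "female", 0.136, 1708.0),
    ("passive_smoking", "lung", "female", 0.016, 1708.0),
]


class TestSubtypeAndRounding:
    def test_subtype_dilution(self):
        # cardia stomach in men: 32% of site counts, subtype PAF 20%
        assert apply_subtype_restriction(0.32, 0.20) == pytest.approx(0.064)

    def test_full_fraction_is_identity(self):
        assert apply_subtype_restriction(1.0, 0.42) == pytest.approx(0.42)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            apply_subtype_restriction(1.2, 0.1)

    def test_attributable_count_unrounded(self):
        # cervix, smoking, women
        assert attributable_count(0.254, 1546) == pytest.approx(392.684)
        assert attributable_count(0.0, 1546) == 0.0
        assert attributable_count(0.873, 1708) == pytest.approx(1491.084)

    @pytest.mark.parametrize(
        "value,expected",
        [(392.684, 393), (0.5, 1), (1.5, 2), (2.5, 3), (-0.5, -1), (392.4, 392)],
    )
    def test_round_half_away_counts(self, value, expected):
        assert round_half_away(value) == expected

    @pytest.mark.parametrize(
        "paf,percent", [(0.915575, 91.6), (0.92205, 92.2), (0.0645, 6.5)]
    )
    def test_round_paf_percent(self, paf, percent):
        assert round_paf_percent(paf) == percent


class TestAggregate:
    def test_lung_combination_per_sex_and_pooled(self):
        result = aggregate(_tidy(LUNG_ROWS), denominator=50320)
        combined = result.combined.set_index(["site", "sex"])
        men = combined.loc[("lung", "male")]
        women = combined.loc[("lung", "female")]
        both = combined.loc[("lung", "both")]
        assert round_paf_percent(men["paf"]) == 92.2
        assert round_paf_percent(women["paf"]) == 89.2
        assert men["attributable"] == pytest.approx(1994.4, abs=0.1)
        assert round_half_away(women["attributable"]) == 1524
        # both-sex PAF is pooled attributable over pooled totals
        assert both["paf"] == pytest.approx(
            (men["attributable"] + women["attributable"]) / 3871.0
        )
        assert min(men["paf"], women["paf"]) <= both["paf"] <= max(
            men["paf"], women["paf"]
        )

    def test_single_row_aggregate_is_identity(self):
        result = aggregate(_tidy([("smoking", "lung", "male", 0.4, 100.0)]))
        combined = result.combined.set_index(["site", "sex"])
        assert combined.loc[("lung", "male"), "paf"] == pytest.approx(0.4)
        assert combined.loc[("lung", "both"), "paf"] == pytest.approx(0.4)
        assert result.overall["attributable"] == pytest.approx(40.0)

    def test_order_invariance(self):
        shuffled = _tidy(LUNG_ROWS).sample(frac=1, random_state=3)
        a = aggregate(_tidy(LUNG_ROWS), denominator=50320)
        b = aggregate(shuffled, denominator=50320)
        pd.testing.assert_frame_equal(
            a.combined.reset_index(drop=True), b.combined.reset_index(drop=True)
        )
        assert a.overall == b.overall

    def test_combined_dominates_components(self):
        result = aggregate(_tidy(LUNG_ROWS))
        combined = result.combined.set_index(["site", "sex"])["paf"]
        per = result.per_exposure
        for _, row in per[per["sex"] != "both"].iterrows():
            assert combined.loc[(row["site"], row["sex"])] >= row["paf"] - 1e-12
        assert (result.combined["paf"] < 1).all()

    def test_empty_table_gives_zero_attribution(self):
        result = aggregate(_tidy([]))
        assert result.overall["attributable"] == 0.0
        assert result.combined.empty

    def test_inconsistent_site_totals_rejected(self):
        rows = [
            ("smoking", "lung", "male", 0.5, 100.0),
            ("fruit", "lung", "male", 0.1, 90.0),
        ]
        with pytest.raises(ValidationError, match="inconsistent"):
            aggregate(_tidy(rows))

    def test_paf_at_least_one_rejected(self):
        with pytest.raises(ValidationError):
            aggregate(_tidy([("smoking", "lung", "male", 1.0, 100.0)]))


class TestReproduce:
    def test_missing_site_in_occurrence_rejected(self):
        paf_df = pd.DataFrame(
            {
                "exposure": ["smoking"],
                "site": ["appendix"],
                "sex": ["male"],
                "total": [10],
                "paf_percent": [5.0],
            }
        )
        occurrence = pd.DataFrame(
            {"site": ["lung"], "sex": ["male"], "cases": [10], "deaths": [5]}
        )
        with pytest.raises(ValidationError, match="appendix"):
            reproduce_from_paf_table(paf_df, occurrence, "cases")

    def test_total_mismatch_rejected(self):
        paf_df = pd.DataFrame(
            {
                "exposure": ["smoking"],
                "site": ["lung"],
                "sex": ["male"],
                "total": [11],
                "paf_percent": [5.0],
            }
        )
        occurrence = pd.DataFrame(
            {"site": ["lung"], "sex": ["male"], "cases": [10], "deaths": [5]}
        )
        with pytest.raises(ValidationError, match="mismatch"):
            reproduce_from_paf_table(paf_df, occurrence, "cases")

    def test_advanced_prostate_totals(self):
        """Advanced prostate cases equal prostate deaths before PAF dilution."""
        from paftool import io

        occ = io.load_occurrence().set_index(["site", "sex"])
        cases = occ.loc[("prostate", "male"), "cases"]
        deaths = occ.loc[("prostate", "male"), "deaths"]
        assert deaths == 2270
        # diluting the mortality-side PAF (8.6%) by deaths/cases gives the
        # printed incidence-side site PAF (3.0%)
        assert round_paf_percent(
            apply_subtype_restriction(deaths / cases, 0.086)
        ) == 3.0


class TestEndToEndRecovery:
    def test_pipeline_recovers_known_pafs(self, small_study):
        """Known-truth synthetic inputs round-trip through the full pipeline.

        Categorical PAFs are recovered to 1e-10 (analytic path) and the
        continuous BMI PAFs to 1e-6 (Gauss-Legendre vs the independent
        trapezoid oracle); combined site PAFs match the oracle combination.
        """
        study = small_study
        categorical, bmi = study.exact_prevalence()
        table = compute_paf_table(
            categorical, bmi, study.rr_sets, study.occurrence, measure="cases"
        )
        for _, row in table.iterrows():
            truth = study.truth.paf[(row["exposure"], row["site"], row["sex"])]
            tol = 1e-6 if row["exposure"] == "high_bmi" else 1e-10
            assert row["paf"] == pytest.approx(truth, abs=tol)
        result = aggregate(table, measure="cases")
        combined = result.combined.set_index(["site", "sex"])["paf"]
        for (site, sex), truth in study.truth.combined.items():
            assert combined.loc[(site, sex)] == pytest.approx(truth, abs=1e-6)

    def test_sampled_prevalence_converges_with_n(self):
        """Survey-noise error in a derived PAF shrinks roughly as 1/sqrt(n)."""
        from paftool.exposure import estimate_prevalence
        from paftool.paf import paf_categorical
        from paftool.synthetic import (
            GeneratorConfig,
            generate_rr_table,
            generate_survey,
            oracle_paf_categorical,
        )

        errors = {}
        for n in (1_000, 100_000):
            config = GeneratorConfig(seed=5, n_records=n)
            records, truth = generate_survey(config)
            rr = next(
                r
                for r in generate_rr_table(config)
                if r.exposure_id == "smoking" and r.sex == "male"
            )
            dist = estimate_prevalence(records, "smoking", "male")
            est = paf_categorical(dist, rr).paf
            true = oracle_paf_categorical(
                list(truth[("smoking", "male")]), list(rr.rr)
            )
            errors[n] = abs(est - true)
        assert errors[100_000] < errors[1_000]
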