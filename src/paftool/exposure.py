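"""Derive categorized exposures and prevalence tables from survey records.

Raw self-reported behaviour is converted to the scales used in the
risk-factor literature (grams of pure alcohol per day, grams of fruits and
vegetables per day, MET-minutes per week of physical activity), binned
into the prevalence bands of the source survey, and summarized as weighted
level proportions by sex.

Band conventions
----------------
Published prevalence tables print overlapping or gapped band labels
("1-12.5", "12.6-49.9"). Internally every scale is partitioned with
half-open intervals so that categorization is total on [0, inf):

* alcohol (g/day): abstainer {0}; light (0, 12.5]; moderate (12.5, 50);
  heavy [50, inf) — the printed "1-12.5" lower bound is read as "any
  positive intake", so (0, 1) g/day is assigned to light;
* fruits+vegetables, fruit-only (g/day) and physical activity
  (MET-min/week): left-closed bands [lower, upper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .models import (
    ACTIVITY_METS,
    ActivityItem,
    ContinuousDistribution,
    ExposureDistribution,
    SurveyRecord,
    ValidationError,
)

#: Grams of pure alcohol assigned to one drink (beer, glass of wine or shot
#: of spirit).
GRAMS_ALCOHOL_PER_DRINK = 12.5

#: Grams assigned to one serving of fruits or vegetables.
GRAMS_PER_SERVING = 80.0


@dataclass(frozen=True)
class Band:
    """A half-open interval [lower, upper) on a nonnegative exposure scale."""

    label: str
    lower: float
    upper: float

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


# Bands are listed TMREL-first (increasing risk with index), matching the
# level order of ExposureDistribution / RelativeRiskSet.
FRUIT_VEG_BANDS = (
    Band(">=400 g/day", 400.0, math.inf),
    Band("300-399 g/day", 300.0, 400.0),
    Band("200-299 g/day", 200.0, 300.0),
    Band("100-199 g/day", 100.0, 200.0),
    Band("0-99 g/day", 0.0, 100.0),
)

FRUIT_BANDS = (
    Band(">=250 g/day", 250.0, math.inf),
    Band("200-249 g/day", 200.0, 250.0),
    Band("150-199 g/day", 150.0, 200.0),
    Band("100-149 g/day", 100.0, 150.0),
    Band("50-99 g/day", 50.0, 100.0),
    Band("0-49 g/day", 0.0, 50.0),
)

ACTIVITY_BANDS = (
    Band(">=8000 MET-min/week", 8000.0, math.inf),
    Band("4000-7999 MET-min/week", 4000.0, 8000.0),
    Band("600-3999 MET-min/week", 600.0, 4000.0),
    Band("<600 MET-min/week", 0.0, 600.0),
)

ALCOHOL_LEVELS = ("abstainer", "light", "moderate", "heavy")

#: Level labels per categorical exposure, TMREL-first.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "alcohol": ALCOHOL_LEVELS,
    "fruit_veg": tuple(b.label for b in FRUIT_VEG_BANDS),
    "fruit": tuple(b.label for b in FRUIT_BANDS),
    "physical_activity": tuple(b.label for b in ACTIVITY_BANDS),
    "passive_smoking": ("no", "yes"),
    "smoking": ("never", "former", "current"),
}

CONTINUOUS_EXPOSURES = ("high_bmi",)

EXPOSURES = tuple(CATEGORICAL_LEVELS) + CONTINUOUS_EXPOSURES


def _require_nonneg(value: float, name: str) -> None:
    if value < 0 or not math.isfinite(value):
        raise ValidationError(f"{name} must be a finite nonnegative number")


def grams_alcohol_per_day(drinks_per_day: float) -> float:
    """Convert drinks/day to grams of pure alcohol per day (12.5 g/drink)."""
    _require_nonneg(drinks_per_day, "drinks_per_day")
    return drinks_per_day * GRAMS_ALCOHOL_PER_DRINK


def categorize_alcohol(g_per_day: float) -> str:
    """Map grams of alcohol per day to an intake band.

    Abstainer is exactly 0 g/day (the TMREL); light covers (0, 12.5],
    moderate (12.5, 50) and heavy everything at or above 50 g/day.
    """
    _require_nonneg(g_per_day, "g_per_day")
    if g_per_day == 0:
        return "abstainer"
    if g_per_day <= GRAMS_ALCOHOL_PER_DRINK:
        return "light"
    if g_per_day < 50.0:
        return "moderate"
    return "heavy"


def fruit_veg_grams_per_day(
    servings_per_day: float, days_per_week: float
) -> float:
    """Weekly-average intake in g/day: servings x 80 g x days/week / 7."""
    _require_nonneg(servings_per_day, "servings_per_day")
    if not 0 <= days_per_week <= 7:
        raise ValidationError("days_per_week must be in [0, 7]")
    return servings_per_day * GRAMS_PER_SERVING * days_per_week / 7.0


def _categorize(value: float, bands: Sequence[Band], name: str) -> str:
    _require_nonneg(value, name)
    for band in bands:
        if band.contains(value):
            return band.label
    raise AssertionError("bands do not partition [0, inf)")  # pragma: no cover


def categorize_fruit_veg(g_per_day: float) -> str:
    """Map combined fruits+vegetables g/day to its intake band."""
    return _categorize(g_per_day, FRUIT_VEG_BANDS, "g_per_day")


def categorize_fruit(g_per_day: float) -> str:
    """Map fruit-only g/day to its intake band."""
    return _categorize(g_per_day, FRUIT_BANDS, "g_per_day")


def met_minutes_per_week(
    items: Iterable[ActivityItem | tuple[str, float, float]]
) -> float:
    """Total physical activity volume in MET-minutes per week.

    Each item contributes MET(domain) x minutes/day x days/week, with the
    GPAQ MET assignments in :data:`paftool.models.ACTIVITY_METS`.
    """
    total = 0.0
    for item in items:
        if not isinstance(item, ActivityItem):
            item = ActivityItem(*item)
        total += (
            ACTIVITY_METS[item.domain]
            * item.minutes_per_day
            * item.days_per_week
        )
    return total


def categorize_activity(met_min_per_week: float) -> str:
    """Map MET-minutes/week to its activity band."""
    return _categorize(met_min_per_week, ACTIVITY_BANDS, "met_min_per_week")


def derive_level(record: SurveyRecord, exposure_id: str) -> str | None:
    """Derive the categorical exposure level of one record.

    Returns ``None`` when the exposure is not defined for the record
    (passive smoking for ever-smokers).
    """
    if exposure_id == "alcohol":
        return categorize_alcohol(grams_alcohol_per_day(record.drinks_per_day))
    if exposure_id == "fruit_veg":
        grams = fruit_veg_grams_per_day(
            record.fruit_servings_per_day, record.fruit_days_per_week
        ) + fruit_veg_grams_per_day(
            record.veg_servings_per_day, record.veg_days_per_week
        )
        return categorize_fruit_veg(grams)
    if exposure_id == "fruit":
        return categorize_fruit(
            fruit_veg_grams_per_day(
                record.fruit_servings_per_day, record.fruit_days_per_week
            )
        )
    if exposure_id == "physical_activity":
        return categorize_activity(met_minutes_per_week(record.activity))
    if exposure_id == "smoking":
        return record.smoking_status
    if exposure_id == "passive_smoking":
        if record.smoking_status != "never":
            return None
        return record.home_smoke_exposure
    raise ValidationError(f"unknown categorical exposure {exposure_id!r}")


def estimate_prevalence(
    records: Sequence[SurveyRecord], exposure_id: str, sex: str
) -> ExposureDistribution | ContinuousDistribution:
    """Weighted prevalence of one exposure for one sex.

    Categorical exposures return an :class:`ExposureDistribution` of
    survey-weighted level proportions (weights normalized within the sex
    stratum); ``high_bmi`` returns a :class:`ContinuousDistribution` with
    the weighted mean and standard deviation of weight/height^2. Passive
    smoking is estimated among never-smokers only. Proportions are
    invariant to uniform rescaling of the weights.
    """
    stratum = [r for r in records if r.sex == sex]
    if not stratum:
        raise ValidationError(f"no records for sex={sex!r}")

    if exposure_id == "high_bmi":
        w = np.array([r.survey_weight for r in stratum])
        x = np.array([r.bmi for r in stratum])
        total_w = w.sum()
        if total_w <= 0:
            raise ValidationError("total survey weight is not positive")
        mean = float(np.sum(w * x) / total_w)
        var = float(np.sum(w * (x - mean) ** 2) / total_w)
        if var <= 0:
            raise ValidationError(
                "cannot estimate a BMI standard deviation from a "
                "degenerate stratum"
            )
        return ContinuousDistribution("high_bmi", sex, mean, math.sqrt(var))

    levels = CATEGORICAL_LEVELS.get(exposure_id)
    if levels is None:
        raise ValidationError(f"unknown exposure {exposure_id!r}")

    weight_by_level = dict.fromkeys(levels, 0.0)
    total_w = 0.0
    for record in stratum:
        level = derive_level(record, exposure_id)
        if level is None:
            continue
        weight_by_level[level] += record.survey_weight
        total_w += record.survey_weight
    if total_w <= 0:
        raise ValidationError(
            f"no eligible records (or zero total weight) for "
            f"{exposure_id}/{sex}"
        )
    proportions = np.array([weight_by_level[lv] for lv in levels]) / total_w
    return ExposureDistribution(exposure_id, sex, levels, proportions)
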