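"""Core domain objects shared across the package.

The objects here mirror the quantities of a comparative risk assessment:
survey records carry raw self-reported behaviour; exposure distributions
carry level prevalences with a designated theoretical-minimum-risk
(TMREL) level; relative-risk sets pair an exposure with a cancer site and
sex; occurrence records carry case and death counts. All objects validate
their structural invariants at construction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SEXES = ("male", "female")
SMOKING_STATUSES = ("never", "former", "current")
MEASURES = ("cases", "deaths")

#: MET values assigned to each GPAQ activity domain (multiples of resting
#: energy expenditure): active transport 4.0; occupational moderate 3.8 and
#: vigorous 7.8; recreational moderate 3.0 and vigorous 6.0.
ACTIVITY_METS = {
    "transport": 4.0,
    "occupational_moderate": 3.8,
    "occupational_vigorous": 7.8,
    "recreational_moderate": 3.0,
    "recreational_vigorous": 6.0,
}


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


def _check_sex(sex: str) -> None:
    if sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")


@dataclass(frozen=True)
class ActivityItem:
    """One GPAQ-style activity report: a domain, days/week and minutes/day."""

    domain: str
    days_per_week: float
    minutes_per_day: float

    def __post_init__(self) -> None:
        if self.domain not in ACTIVITY_METS:
            raise ValidationError(
                f"unknown activity domain {self.domain!r}; "
                f"expected one of {sorted(ACTIVITY_METS)}"
            )
        if not 0 <= self.days_per_week <= 7:
            raise ValidationError("days_per_week must be in [0, 7]")
        if self.minutes_per_day < 0:
            raise ValidationError("minutes_per_day must be >= 0")


@dataclass
class SurveyRecord:
    """One survey respondent's self-reported behaviour.

    Fields follow the structure of a national health-survey questionnaire:
    drinks of alcohol on a regular day, weight and height for BMI, servings
    and weekly frequency of fruits and vegetables, GPAQ activity items,
    smoking status, and home smoke exposure. ``home_smoke_exposure`` is
    only interpreted for never-smokers (passive smoking is defined among
    never-smokers).
    """

    sex: str
    age: float
    drinks_per_day: float
    weight: float  # kg
    height: float  # m
    fruit_servings_per_day: float
    fruit_days_per_week: float
    veg_servings_per_day: float
    veg_days_per_week: float
    activity: tuple[ActivityItem, ...] = ()
    smoking_status: str = "never"
    home_smoke_exposure: str = "no"
    survey_weight: float = 1.0

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.height <= 0 or self.weight <= 0:
            raise ValidationError("height and weight must be positive")
        if self.drinks_per_day < 0:
            raise ValidationError("drinks_per_day must be >= 0")
        for name in ("fruit_days_per_week", "veg_days_per_week"):
            if not 0 <= getattr(self, name) <= 7:
                raise ValidationError(f"{name} must be in [0, 7]")
        for name in ("fruit_servings_per_day", "veg_servings_per_day"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.smoking_status not in SMOKING_STATUSES:
            raise ValidationError(
                f"smoking_status must be one of {SMOKING_STATUSES}"
            )
        if self.home_smoke_exposure not in ("yes", "no"):
            raise ValidationError("home_smoke_exposure must be 'yes' or 'no'")
        if self.survey_weight <= 0:
            raise ValidationError("survey_weight must be positive")
        self.activity = tuple(
            it if isinstance(it, ActivityItem) else ActivityItem(*it)
            for it in self.activity
        )

    @property
    def bmi(self) -> float:
        """Body mass index (kg/m^2) from self-reported weight and height."""
        return self.weight / self.height**2


@dataclass
class ExposureDistribution:
    """Level proportions of one categorical exposure for one sex.

    ``levels`` are ordered from the theoretical-minimum-risk level (TMREL,
    index ``tmrel_index``, conventionally 0) toward increasing risk.
    Proportions must sum to 1 within 1e-9; use :meth:`from_rounded` for
    tables whose printed proportions carry rounding error.
    """

    exposure_id: str
    sex: str
    levels: tuple[str, ...]
    proportions: np.ndarray
    tmrel_index: int = 0

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        self.levels = tuple(self.levels)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.levels) == 0:
            raise ValidationError(f"{self.exposure_id}: no exposure levels")
        if self.proportions.shape != (len(self.levels),):
            raise ValidationError(
                f"{self.exposure_id}/{self.sex}: {len(self.levels)} levels "
                f"but {self.proportions.size} proportions"
            )
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValidationError(
                f"{self.exposure_id}/{self.sex}: proportions outside [0, 1]"
            )
        total = float(self.proportions.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.exposure_id}/{self.sex}: proportions sum to "
                f"{total:.6f}, expected 1"
            )
        if not 0 <= self.tmrel_index < len(self.levels):
            raise ValidationError(
                f"{self.exposure_id}/{self.sex}: tmrel_index out of range"
            )

    @classmethod
    def from_rounded(
        cls,
        exposure_id: str,
        sex: str,
        levels: Sequence[str],
        proportions: Sequence[float],
        tmrel_index: int = 0,
        tol: float = 0.02,
    ) -> "ExposureDistribution":
        """Build from printed (rounded) proportions, renormalizing exactly.

        Printed prevalence tables routinely sum to 0.999 or 1.001; sums
        within ``tol`` of 1 are renormalized, anything further off is an
        error.
        """
        p = np.asarray(proportions, dtype=float)
        total = float(p.sum())
        if abs(total - 1.0) > tol:
            raise ValidationError(
                f"{exposure_id}/{sex}: proportions sum to {total:.4f}; "
                f"more than {tol} away from 1"
            )
        return cls(exposure_id, sex, tuple(levels), p / total, tmrel_index)


@dataclass
class ContinuousDistribution:
    """Mean/sd summary of a continuous exposure (BMI) plus its counterfactual.

    The counterfactual is the TMREL distribution: by default Normal(22, 1)
    on the kg/m^2 scale.
    """

    exposure_id: str
    sex: str
    mean: float
    sd: float
    cf_mean: float = 22.0
    cf_sd: float = 1.0

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.sd <= 0 or self.cf_sd <= 0:
            raise ValidationError(
                f"{self.exposure_id}/{self.sex}: sd and cf_sd must be > 0"
            )


@dataclass
class RelativeRiskSet:
    """Relative risks for one exposure-cancer-sex pair.

    ``form`` is ``"categorical"`` (one RR per exposure level, aligned with
    an :class:`ExposureDistribution`, RR exactly 1 at the TMREL level) or
    ``"per_unit"`` (RR per 1 kg/m^2 increase for the continuous BMI
    pathway, interpreted through a dose-response model).
    """

    exposure_id: str
    cancer_site: str
    sex: str
    form: str
    levels: tuple[str, ...] | None = None
    rr: np.ndarray | None = None
    tmrel_index: int = 0
    rr_per_unit: float | None = None
    dose_response: str = "log_linear"
    subtype: str | None = None

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.form == "categorical":
            if self.levels is None or self.rr is None:
                raise ValidationError(
                    f"{self.exposure_id}->{self.cancer_site}: categorical "
                    "RR set needs levels and rr"
                )
            self.levels = tuple(self.levels)
            self.rr = np.asarray(self.rr, dtype=float)
            if self.rr.shape != (len(self.levels),):
                raise ValidationError(
                    f"{self.exposure_id}->{self.cancer_site}: rr length "
                    "does not match levels"
                )
            if np.any(self.rr <= 0):
                raise ValidationError(
                    f"{self.exposure_id}->{self.cancer_site}: all RR must "
                    "be > 0"
                )
            if not 0 <= self.tmrel_index < len(self.levels):
                raise ValidationError("tmrel_index out of range")
            if abs(self.rr[self.tmrel_index] - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.exposure_id}->{self.cancer_site}: RR at the "
                    f"TMREL level is {self.rr[self.tmrel_index]}, must be 1"
                )
            self.rr[self.tmrel_index] = 1.0
        elif self.form == "per_unit":
            if self.rr_per_unit is None or self.rr_per_unit <= 0:
                raise ValidationError(
                    f"{self.exposure_id}->{self.cancer_site}: per-unit RR "
                    "must be a positive number"
                )
            if self.rr_per_unit < 1.0:
                warnings.warn(
                    f"{self.exposure_id}->{self.cancer_site}/{self.sex}: "
                    f"rr_per_unit={self.rr_per_unit} < 1 implies a "
                    "protective dose-response",
                    stacklevel=2,
                )
        else:
            raise ValidationError(
                f"form must be 'categorical' or 'per_unit', got {self.form!r}"
            )


@dataclass
class OccurrenceRecord:
    """Case and death counts for one cancer site and sex."""

    cancer_site: str
    sex: str
    cases: int
    deaths: int

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        for name in ("cases", "deaths"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(
                    f"{self.cancer_site}/{self.sex}: {name} must be a "
                    "nonnegative integer"
                )
        self.cases = int(self.cases)
        self.deaths = int(self.deaths)


@dataclass
class SubtypeSplit:
    """Fraction of a site's counts belonging to one subtype.

    ``rule`` is ``"fixed"`` (use ``fraction`` as printed) or
    ``"cases_equal_deaths"`` (the subtype's case count is taken to equal
    the site's death count, e.g. advanced prostate cancer).
    """

    cancer_site: str
    sex: str
    subtype: str
    fraction: float | None = None
    rule: str = "fixed"

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.rule not in ("fixed", "cases_equal_deaths"):
            raise ValidationError(f"unknown subtype rule {self.rule!r}")
        if self.rule == "fixed":
            if self.fraction is None or not 0 <= self.fraction <= 1:
                raise ValidationError(
                    f"{self.cancer_site}/{self.subtype}: fixed subtype "
                    "split needs a fraction in [0, 1]"
                )


@dataclass
class PafValue:
    """One exposure-site-sex-measure population attributable fraction."""

    exposure_id: str
    cancer_site: str
    sex: str
    measure: str
    paf: float

    def __post_init__(self) -> None:
        if self.paf >= 1.0:
            raise ValidationError("a PAF must be strictly below 1")
        if self.paf < -1e-9:  # ignore quadrature-level negative zero
            warnings.warn(
                f"negative PAF {self.paf:.4f} for {self.exposure_id}->"
                f"{self.cancer_site}/{self.sex}: the exposure pattern is "
                "protective relative to the counterfactual",
                stacklevel=2,
            )
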