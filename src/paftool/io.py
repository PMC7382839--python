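"""File formats, bundled fixtures, and validated loading.

All tabular interchange is plain CSV with documented headers; nested
results and ground truth use JSON. The bundled fixtures transcribe the
point estimates of a published national risk-factor/cancer-burden
analysis for Chile 2018:

* ``table1_prevalence.csv`` — exposure level proportions by sex
  (columns: exposure, sex, level, proportion, is_tmrel);
* ``table1_bmi.csv`` — BMI mean by sex with the Normal(22, 1)
  counterfactual. The survey's population standard deviation is not
  printed in the source table; the bundled values are package-chosen
  plausible values inferred from the survey's precision and documented in
  the methods note;
* ``table2_cases.csv`` / ``table3_deaths.csv`` — per exposure-site-sex
  totals and PAF columns (exposure, site, sex, total, paf_percent,
  attributable_printed);
* ``occurrence_totals.csv`` — cases/deaths per site and sex plus the
  all-cancer denominators (site ``all_sites``, sex ``both``);
* ``subtype_splits.csv`` — subtype fractions of site counts;
* ``site_exposure_map.csv`` — which exposures act on which sites.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exposure import CATEGORICAL_LEVELS
from .models import (
    ActivityItem,
    ContinuousDistribution,
    ExposureDistribution,
    OccurrenceRecord,
    RelativeRiskSet,
    SubtypeSplit,
    SurveyRecord,
    ValidationError,
)

logger = logging.getLogger("paftool")

_ACTIVITY_DOMAINS = (
    "transport",
    "occupational_moderate",
    "occupational_vigorous",
    "recreational_moderate",
    "recreational_vigorous",
)


def fixture_path(name: str) -> Path:
    """Absolute path of a bundled fixture file."""
    path = Path(str(resources.files("paftool") / "fixtures" / name))
    if not path.exists():
        raise FileNotFoundError(f"no bundled fixture named {name!r}")
    return path


def file_checksum(path: str | Path) -> str:
    """SHA-256 checksum of a file (logged for provenance)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path.name}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing required column(s) {missing}"
        )
    logger.debug("read %s (sha256=%s)", path, file_checksum(path))
    return df


def load_prevalence(
    path: str | Path | None = None,
) -> dict[tuple[str, str], ExposureDistribution]:
    """Load categorical prevalence distributions keyed by (exposure, sex).

    Proportions printed with rounding error (sums within 0.02 of 1) are
    renormalized; anything further off raises naming the exposure and sex.
    The TMREL level is flagged by ``is_tmrel``.
    """
    path = fixture_path("table1_prevalence.csv") if path is None else path
    df = _read_csv(path, ["exposure", "sex", "level", "proportion", "is_tmrel"])
    out: dict[tuple[str, str], ExposureDistribution] = {}
    for (exposure, sex), grp in df.groupby(["exposure", "sex"], sort=False):
        tmrel = np.flatnonzero(grp["is_tmrel"].to_numpy().astype(int))
        if tmrel.size != 1:
            raise ValidationError(
                f"{exposure}/{sex}: exactly one TMREL level required"
            )
        out[(exposure, sex)] = ExposureDistribution.from_rounded(
            exposure,
            sex,
            tuple(grp["level"]),
            grp["proportion"].to_numpy(dtype=float),
            tmrel_index=int(tmrel[0]),
        )
    return out


def load_bmi(
    path: str | Path | None = None,
) -> dict[str, ContinuousDistribution]:
    """Load the continuous BMI distributions keyed by sex."""
    path = fixture_path("table1_bmi.csv") if path is None else path
    df = _read_csv(path, ["exposure", "sex", "mean", "sd", "cf_mean", "cf_sd"])
    return {
        row["sex"]: ContinuousDistribution(
            row["exposure"],
            row["sex"],
            float(row["mean"]),
            float(row["sd"]),
            float(row["cf_mean"]),
            float(row["cf_sd"]),
        )
        for _, row in df.iterrows()
    }


def load_paf_table(
    measure: str = "cases", path: str | Path | None = None
) -> pd.DataFrame:
    """Load a published per exposure-site-sex PAF table (reproduction path)."""
    if path is None:
        name = {
            "cases": "table2_cases.csv",
            "deaths": "table3_deaths.csv",
        }.get(measure)
        if name is None:
            raise ValidationError("measure must be 'cases' or 'deaths'")
        path = fixture_path(name)
    df = _read_csv(path, ["exposure", "site", "sex", "total", "paf_percent"])
    if (df["paf_percent"] >= 100).any():
        raise ValidationError("paf_percent must be below 100")
    return df


def load_occurrence(path: str | Path | None = None) -> pd.DataFrame:
    """Load occurrence counts (site, sex, cases, deaths)."""
    path = fixture_path("occurrence_totals.csv") if path is None else path
    df = _read_csv(path, ["site", "sex", "cases", "deaths"])
    if (df[["cases", "deaths"]] < 0).to_numpy().any():
        raise ValidationError("occurrence counts must be nonnegative")
    return df


def occurrence_records(df: pd.DataFrame) -> list[OccurrenceRecord]:
    """Typed occurrence records, excluding the all-cancer denominator row."""
    body = df[df["site"] != "all_sites"]
    return [
        OccurrenceRecord(r["site"], r["sex"], int(r["cases"]), int(r["deaths"]))
        for _, r in body.iterrows()
    ]


def load_subtype_splits(path: str | Path | None = None) -> list[SubtypeSplit]:
    """Load subtype split fractions of site counts."""
    path = fixture_path("subtype_splits.csv") if path is None else path
    df = _read_csv(path, ["site", "sex", "subtype", "fraction", "rule"])
    return [
        SubtypeSplit(
            r["site"],
            r["sex"],
            r["subtype"],
            None if pd.isna(r["fraction"]) else float(r["fraction"]),
            r["rule"],
        )
        for _, r in df.iterrows()
    ]


def load_site_exposure_map(path: str | Path | None = None) -> pd.DataFrame:
    """Load the exposure -> cancer-site eligibility map."""
    path = fixture_path("site_exposure_map.csv") if path is None else path
    df = _read_csv(path, ["exposure", "site", "sexes", "subtype"])
    bad = set(df["sexes"]) - {"both", "male", "female"}
    if bad:
        raise ValidationError(f"site map 'sexes' must be both/male/female, got {bad}")
    return df


# ---------------------------------------------------------------------------
# Survey records


SURVEY_COLUMNS = (
    ["sex", "age", "drinks_per_day", "weight_kg", "height_m",
     "fruit_servings_per_day", "fruit_days_per_week",
     "veg_servings_per_day", "veg_days_per_week"]
    + [f"{d}_{suffix}" for d in _ACTIVITY_DOMAINS
       for suffix in ("days_per_week", "min_per_day")]
    + ["smoking_status", "home_smoke_exposure", "survey_weight"]
)


def write_survey_csv(records: Sequence[SurveyRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_COLUMNS)
        for r in records:
            activity = {d: (0.0, 0.0) for d in _ACTIVITY_DOMAINS}
            for item in r.activity:
                days, minutes = activity[item.domain]
                activity[item.domain] = (
                    item.days_per_week,
                    minutes + item.minutes_per_day,
                )
            row = [
                r.sex, r.age, r.drinks_per_day, r.weight, r.height,
                r.fruit_servings_per_day, r.fruit_days_per_week,
                r.veg_servings_per_day, r.veg_days_per_week,
            ]
            for d in _ACTIVITY_DOMAINS:
                row.extend(activity[d])
            row.extend([r.smoking_status, r.home_smoke_exposure, r.survey_weight])
            writer.writerow(row)


def read_survey_csv(path: str | Path) -> list[SurveyRecord]:
    df = _read_csv(path, SURVEY_COLUMNS)
    records = []
    for _, r in df.iterrows():
        activity = tuple(
            ActivityItem(
                d,
                float(r[f"{d}_days_per_week"]),
                float(r[f"{d}_min_per_day"]),
            )
            for d in _ACTIVITY_DOMAINS
            if float(r[f"{d}_days_per_week"]) * float(r[f"{d}_min_per_day"]) > 0
        )
        records.append(
            SurveyRecord(
                sex=r["sex"],
                age=float(r["age"]),
                drinks_per_day=float(r["drinks_per_day"]),
                weight=float(r["weight_kg"]),
                height=float(r["height_m"]),
                fruit_servings_per_day=float(r["fruit_servings_per_day"]),
                fruit_days_per_week=float(r["fruit_days_per_week"]),
                veg_servings_per_day=float(r["veg_servings_per_day"]),
                veg_days_per_week=float(r["veg_days_per_week"]),
                activity=activity,
                smoking_status=r["smoking_status"],
                home_smoke_exposure=r["home_smoke_exposure"],
                survey_weight=float(r["survey_weight"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Relative-risk tables


RR_COLUMNS = ("exposure", "site", "sex", "form", "level", "rr", "subtype")


def write_rr_csv(rr_sets: Sequence[RelativeRiskSet], path: str | Path) -> None:
    rows = []
    for rr in rr_sets:
        if rr.form == "categorical":
            for level, value in zip(rr.levels, rr.rr):
                rows.append(
                    [rr.exposure_id, rr.cancer_site, rr.sex, rr.form,
                     level, value, rr.subtype or ""]
                )
        else:
            rows.append(
                [rr.exposure_id, rr.cancer_site, rr.sex, rr.form,
                 "per_unit", rr.rr_per_unit, rr.subtype or ""]
            )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RR_COLUMNS)
        writer.writerows(rows)


def read_rr_csv(path: str | Path) -> list[RelativeRiskSet]:
    df = _read_csv(path, RR_COLUMNS)
    out = []
    for (exposure, site, sex, form), grp in df.groupby(
        ["exposure", "site", "sex", "form"], sort=False
    ):
        subtype = grp["subtype"].iloc[0]
        subtype = None if pd.isna(subtype) or subtype == "" else str(subtype)
        if form == "categorical":
            levels = tuple(grp["level"])
            expected = CATEGORICAL_LEVELS.get(exposure)
            if expected is not None and levels != expected:
                raise ValidationError(
                    f"{exposure}->{site}/{sex}: RR levels {levels} do not "
                    f"match the exposure's level order {expected}"
                )
            out.append(
                RelativeRiskSet(
                    exposure, site, sex, "categorical",
                    levels=levels,
                    rr=grp["rr"].to_numpy(dtype=float),
                    subtype=subtype,
                )
            )
        else:
            out.append(
                RelativeRiskSet(
                    exposure, site, sex, "per_unit",
                    rr_per_unit=float(grp["rr"].iloc[0]),
                    subtype=subtype,
                )
            )
    return out


def write_prevalence_csv(
    distributions: Sequence[ExposureDistribution], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["exposure", "sex", "level", "proportion", "is_tmrel"])
        for dist in distributions:
            for i, (level, p) in enumerate(zip(dist.levels, dist.proportions)):
                writer.writerow(
                    [dist.exposure_id, dist.sex, level, repr(float(p)),
                     int(i == dist.tmrel_index)]
                )
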