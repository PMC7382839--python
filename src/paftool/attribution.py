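"""Attribution pipeline: PAFs -> attributable counts -> aggregates.

Orchestrates per exposure-site-sex PAFs into attributable cases or deaths,
applies subtype restrictions (e.g. BMI acts on cardia stomach cancer only;
alcohol on esophageal squamous cell carcinoma only; advanced prostate
cancer cases are taken to equal prostate deaths), combines risk factors
within a site under independence, and aggregates to both-sex, per-exposure
and overall totals.

Two entry points:

* :func:`compute_paf_table` — the estimation path: prevalence
  distributions + relative-risk sets + occurrence counts -> tidy PAF table;
* :func:`reproduce_from_paf_table` — the reproduction path: a published
  per-exposure PAF table + occurrence totals -> the full attribution
  surface, bypassing RR inputs entirely.

All arithmetic is carried unrounded; presentation rounding (PAF to 0.1
percentage point, counts to integers, both half away from zero) is applied
only in :meth:`AttributionResult.presentation`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    ContinuousDistribution,
    ExposureDistribution,
    OccurrenceRecord,
    PafValue,
    RelativeRiskSet,
    SubtypeSplit,
    ValidationError,
)
from .paf import DoseResponseModel, combine_pafs, paf_categorical, paf_continuous

PAF_TABLE_COLUMNS = ("exposure", "site", "sex", "paf", "total")


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places.

    Presentation rounding for PAF percentages (1 digit) and attributable
    counts (0 digits). Uses decimal arithmetic on the shortest repr so
    that printed-scale ties (e.g. 91.55) round up as a reader expects.
    """
    q = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(rounded) if ndigits > 0 else int(rounded)


def round_paf_percent(paf: float) -> float:
    """Presentation PAF: fraction -> percentage rounded to 0.1 pp."""
    return round_half_away(paf * 100.0, 1)


def attributable_count(paf: float, total: float) -> float:
    """Unrounded attributable count ``paf * total`` (total >= 0)."""
    if total < 0:
        raise ValidationError("total count must be >= 0")
    return paf * total


def apply_subtype_restriction(
    subtype_fraction: float, paf_subtype: float
) -> float:
    """Dilute a subtype-specific PAF to the whole site.

    The attributable count is computed on the subtype share of the site's
    counts but reported against the whole-site total, so the site-level
    PAF is ``fraction x subtype PAF``.
    """
    if not 0 <= subtype_fraction <= 1:
        raise ValidationError("subtype fraction must be in [0, 1]")
    return subtype_fraction * paf_subtype


def combine_within_site(pafs: Sequence[float]) -> float:
    """Combined PAF of the exposures acting on one site and sex."""
    return combine_pafs(pafs)


@dataclass
class AttributionResult:
    """Tidy attribution tables for one measure (cases or deaths).

    Attributes
    ----------
    per_exposure:
        one row per exposure-site-sex (including derived ``"both"`` rows)
        with unrounded ``paf``, ``attributable`` and ``total``.
    combined:
        one row per site-sex (including ``"both"``) for the combined PAF
        of all exposures acting on that site.
    exposure_totals:
        attributable counts summed over sites per exposure and sex;
        ``share_percent`` is the share of the all-cancer denominator
        (both sexes only, on the percent scale).
    overall:
        dict with the summed combined attributable count, the all-cancer
        denominator and their ratio ``paf``.
    """

    measure: str
    per_exposure: pd.DataFrame
    combined: pd.DataFrame
    exposure_totals: pd.DataFrame
    overall: dict

    def presentation(self) -> dict[str, pd.DataFrame]:
        """Tables with printed-style rounding (0.1 pp PAF, integer counts)."""
        per_exp = self.per_exposure.copy()
        per_exp["paf_percent"] = per_exp["paf"].map(round_paf_percent)
        per_exp["attributable"] = per_exp["attributable"].map(round_half_away)
        combined = self.combined.copy()
        combined["paf_percent"] = combined["paf"].map(round_paf_percent)
        combined["attributable"] = combined["attributable"].map(round_half_away)
        totals = self.exposure_totals.copy()
        totals["attributable"] = totals["attributable"].map(round_half_away)
        return {
            "per_exposure": per_exp.drop(columns=["paf"]),
            "combined": combined.drop(columns=["paf"]),
            "exposure_totals": totals,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize with full float precision; round-trips via from_json."""
        payload = {
            "measure": self.measure,
            "per_exposure": self.per_exposure.to_dict(orient="list"),
            "combined": self.combined.to_dict(orient="list"),
            "exposure_totals": self.exposure_totals.to_dict(orient="list"),
            "overall": self.overall,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AttributionResult":
        if isinstance(source, Path):
            text = source.read_text()
        elif str(source).lstrip().startswith("{"):
            text = str(source)
        else:
            text = Path(str(source)).read_text()
        payload = json.loads(text)
        return cls(
            measure=payload["measure"],
            per_exposure=pd.DataFrame(payload["per_exposure"]),
            combined=pd.DataFrame(payload["combined"]),
            exposure_totals=pd.DataFrame(payload["exposure_totals"]),
            overall=payload["overall"],
        )

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_exposure.to_csv(outdir / "per_exposure.csv", index=False)
        self.combined.to_csv(outdir / "combined_by_site.csv", index=False)
        self.exposure_totals.to_csv(
            outdir / "exposure_totals.csv", index=False
        )
        (outdir / "overall.json").write_text(json.dumps(self.overall, indent=1))
        tables = self.presentation()
        tables["per_exposure"].to_csv(
            outdir / "per_exposure_rounded.csv", index=False
        )
        tables["combined"].to_csv(
            outdir / "combined_by_site_rounded.csv", index=False
        )


def _validate_paf_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PAF_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"PAF table is missing column(s) {missing}")
    df = df.loc[:, list(PAF_TABLE_COLUMNS)].copy()
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValidationError(
            f"PAF table sexes must be male/female, got {sorted(bad_sex)}"
        )
    if (df["paf"] >= 1).any():
        raise ValidationError("PAF table contains PAF >= 1")
    if (df["total"] < 0).any():
        raise ValidationError("PAF table contains negative totals")
    dup = df.duplicated(subset=["exposure", "site", "sex"])
    if dup.any():
        raise ValidationError(
            "duplicate exposure-site-sex rows: "
            f"{df.loc[dup, ['exposure', 'site', 'sex']].values.tolist()}"
        )
    inconsistent = (
        df.groupby(["site", "sex"])["total"].nunique(dropna=False) > 1
    )
    if inconsistent.any():
        raise ValidationError(
            "inconsistent site totals for "
            f"{inconsistent[inconsistent].index.tolist()}"
        )
    return df


def aggregate(
    paf_table: pd.DataFrame,
    *,
    measure: str = "cases",
    denominator: float | None = None,
) -> AttributionResult:
    """Aggregate a tidy per exposure-site-sex PAF table.

    Both-sex PAFs are always derived from sex-specific attributable counts
    divided by pooled totals — never by combining the two PAFs directly.
    ``denominator`` is the all-cancer total used for exposure shares and
    the overall proportion; when omitted, the sum of the distinct site
    totals in the table is used.
    """
    df = _validate_paf_table(paf_table)
    empty = pd.DataFrame(
        columns=["exposure", "site", "sex", "paf", "attributable", "total"]
    )
    if df.empty:
        return AttributionResult(
            measure=measure,
            per_exposure=empty,
            combined=empty.drop(columns=["exposure"]),
            exposure_totals=pd.DataFrame(
                columns=["exposure", "sex", "attributable", "share_percent"]
            ),
            overall={"attributable": 0.0, "total": denominator, "paf": None},
        )

    df["attributable"] = df["paf"] * df["total"]

    # Per-exposure "both" rows: pooled attributable over pooled totals.
    both = (
        df.groupby(["exposure", "site"], as_index=False)
        .agg(attributable=("attributable", "sum"), total=("total", "sum"))
        .assign(sex="both")
    )
    both["paf"] = both["attributable"] / both["total"].where(both["total"] > 0)
    both["paf"] = both["paf"].fillna(0.0)
    per_exposure = pd.concat(
        [
            df[["exposure", "site", "sex", "paf", "attributable", "total"]],
            both[["exposure", "site", "sex", "paf", "attributable", "total"]],
        ],
        ignore_index=True,
    ).sort_values(["exposure", "site", "sex"], ignore_index=True)

    # Combined PAF per site and sex, then pooled over sexes.
    combined_rows = []
    for (site, sex), grp in df.groupby(["site", "sex"]):
        paf = combine_within_site(grp["paf"].tolist())
        total = float(grp["total"].iloc[0])
        combined_rows.append(
            {
                "site": site,
                "sex": sex,
                "paf": paf,
                "attributable": paf * total,
                "total": total,
            }
        )
    combined = pd.DataFrame(combined_rows)
    combined_both = (
        combined.groupby("site", as_index=False)
        .agg(attributable=("attributable", "sum"), total=("total", "sum"))
        .assign(sex="both")
    )
    combined_both["paf"] = combined_both["attributable"] / combined_both[
        "total"
    ].where(combined_both["total"] > 0)
    combined_both["paf"] = combined_both["paf"].fillna(0.0)
    combined = pd.concat(
        [combined, combined_both[combined.columns]], ignore_index=True
    ).sort_values(["site", "sex"], ignore_index=True)

    # Per-exposure totals across sites, by sex and pooled.
    totals_sex = (
        df.groupby(["exposure", "sex"], as_index=False)["attributable"].sum()
    )
    totals_both = (
        df.groupby("exposure", as_index=False)["attributable"]
        .sum()
        .assign(sex="both")
    )
    exposure_totals = pd.concat(
        [totals_sex, totals_both[totals_sex.columns]], ignore_index=True
    ).sort_values(["exposure", "sex"], ignore_index=True)

    if denominator is None:
        denominator = float(
            df.drop_duplicates(subset=["site", "sex"])["total"].sum()
        )
    exposure_totals["share_percent"] = np.where(
        exposure_totals["sex"] == "both",
        exposure_totals["attributable"] / denominator * 100.0,
        np.nan,
    )

    overall_attr = float(
        combined.loc[combined["sex"] != "both", "attributable"].sum()
    )
    overall = {
        "attributable": overall_attr,
        "total": float(denominator),
        "paf": overall_attr / denominator if denominator else None,
    }
    return AttributionResult(
        measure=measure,
        per_exposure=per_exposure,
        combined=combined,
        exposure_totals=exposure_totals,
        overall=overall,
    )


def reproduce_from_paf_table(
    paf_df: pd.DataFrame | None = None,
    occurrence_df: pd.DataFrame | None = None,
    measure: str = "cases",
) -> AttributionResult:
    """Reproduction path: published PAF columns + occurrence totals.

    ``paf_df`` needs columns exposure, site, sex, total, paf_percent (the
    layout of the bundled burden-table fixtures); ``occurrence_df`` needs
    site, sex, cases, deaths plus an ``all_sites`` row carrying the
    all-cancer denominators. Defaults to the bundled fixtures. Site totals
    are cross-checked against the occurrence counts; a site present in the
    PAF table but absent from the occurrence table is an error.
    """
    from . import io  # local import to avoid a cycle

    if measure not in ("cases", "deaths"):
        raise ValidationError("measure must be 'cases' or 'deaths'")
    if paf_df is None:
        paf_df = io.load_paf_table(measure)
    if occurrence_df is None:
        occurrence_df = io.load_occurrence()

    required = {"exposure", "site", "sex", "total", "paf_percent"}
    missing = required - set(paf_df.columns)
    if missing:
        raise ValidationError(f"PAF fixture is missing column(s) {sorted(missing)}")

    occ = occurrence_df.set_index(["site", "sex"])[measure]
    denominator = None
    if ("all_sites", "both") in occ.index:
        denominator = float(occ.loc[("all_sites", "both")])

    for _, row in paf_df.iterrows():
        key = (row["site"], row["sex"])
        if key not in occ.index:
            raise ValidationError(
                f"site {row['site']!r}/{row['sex']} appears in the PAF "
                "table but not in the occurrence table"
            )
        if int(occ.loc[key]) != int(row["total"]):
            raise ValidationError(
                f"total mismatch for {key}: PAF table has {row['total']}, "
                f"occurrence table has {int(occ.loc[key])}"
            )

    tidy = paf_df.rename(columns={"paf_percent": "paf"}).copy()
    tidy["paf"] = tidy["paf"] / 100.0
    return aggregate(
        tidy[list(PAF_TABLE_COLUMNS)],
        measure=measure,
        denominator=denominator,
    )


def _subtype_fraction(
    split: SubtypeSplit, occurrence: OccurrenceRecord, measure: str
) -> float:
    if split.rule == "cases_equal_deaths":
        # The subtype's case count equals the site's death count (advanced
        # prostate cancer); for the mortality measure the subtype covers
        # all of the site's deaths.
        if measure == "deaths":
            return 1.0
        if occurrence.cases == 0:
            return 0.0
        return occurrence.deaths / occurrence.cases
    return float(split.fraction)


def compute_paf_table(
    prevalence: Mapping[tuple[str, str], ExposureDistribution],
    bmi: Mapping[str, ContinuousDistribution],
    rr_sets: Sequence[RelativeRiskSet],
    occurrence: Sequence[OccurrenceRecord],
    splits: Sequence[SubtypeSplit] = (),
    *,
    measure: str = "cases",
    dose_response: DoseResponseModel | None = None,
) -> pd.DataFrame:
    """Estimation path: prevalences + RR sets + occurrence -> tidy PAF table.

    Each RR set names an exposure-site-sex pair (optionally restricted to
    a subtype); the matching prevalence feeds the categorical or
    continuous PAF engine, subtype PAFs are diluted to the site level, and
    the occurrence counts supply the totals. The result feeds
    :func:`aggregate`.
    """
    if measure not in ("cases", "deaths"):
        raise ValidationError("measure must be 'cases' or 'deaths'")
    occ_index = {(o.cancer_site, o.sex): o for o in occurrence}
    split_index = {(s.cancer_site, s.sex, s.subtype): s for s in splits}
    rows = []
    for rr in rr_sets:
        key = (rr.cancer_site, rr.sex)
        if key not in occ_index:
            raise ValidationError(
                f"no occurrence counts for {rr.cancer_site!r}/{rr.sex}"
            )
        occ = occ_index[key]
        total = occ.cases if measure == "cases" else occ.deaths

        if rr.form == "categorical":
            dist = prevalence.get((rr.exposure_id, rr.sex))
            if dist is None:
                raise ValidationError(
                    f"no prevalence distribution for "
                    f"{rr.exposure_id!r}/{rr.sex}"
                )
            paf = paf_categorical(dist, rr, measure).paf
        else:
            dist_c = bmi.get(rr.sex)
            if dist_c is None:
                raise ValidationError(f"no BMI distribution for sex {rr.sex}")
            # The dose_response argument is a shape template (model id,
            # TMREL, cap); the slope always comes from the RR set.
            if dose_response is None:
                model = DoseResponseModel(
                    model_id=rr.dose_response, rr_per_unit=rr.rr_per_unit
                )
            else:
                model = DoseResponseModel(
                    model_id=dose_response.model_id,
                    rr_per_unit=rr.rr_per_unit,
                    tmrel=dose_response.tmrel,
                    cap_dose=dose_response.cap_dose,
                    saturation_span=dose_response.saturation_span,
                    logistic_scale=dose_response.logistic_scale,
                )
            paf = paf_continuous(
                dist_c, model, measure, cancer_site=rr.cancer_site
            ).paf

        if rr.subtype is not None:
            split = split_index.get((rr.cancer_site, rr.sex, rr.subtype))
            if split is None:
                raise ValidationError(
                    f"RR for {rr.exposure_id!r} is specific to subtype "
                    f"{rr.subtype!r} of {rr.cancer_site!r}/{rr.sex} but no "
                    "subtype split was provided"
                )
            paf = apply_subtype_restriction(
                _subtype_fraction(split, occ, measure), paf
            )

        rows.append(
            {
                "exposure": rr.exposure_id,
                "site": rr.cancer_site,
                "sex": rr.sex,
                "paf": paf,
                "total": float(total),
            }
        )
    return pd.DataFrame(rows, columns=list(PAF_TABLE_COLUMNS))
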