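"""Synthetic survey, relative-risk and occurrence generators.

Every stage of the attribution pipeline is testable without external data:
the generator draws survey-style records whose derived categories follow
known level proportions, relative-risk tables with RR = 1 at the TMREL and
monotone risk across levels, and Poisson occurrence counts — together
with a :class:`GroundTruth` of analytically computed PAFs.

The default configuration reproduces the study conditions of the bundled
prevalence tables (a Chilean national health survey: six lifestyle
exposures by sex) and their site roster.

The ground-truth PAF arithmetic is deliberately implemented here a second
time (plain loops and trapezoid integration rather than the vectorized
closed forms and Gauss-Legendre quadrature of :mod:`paftool.paf`) so that
it can serve as an independent cross-check of the engine.

Diet coupling
-------------
Fruit-only intake and combined fruits+vegetables intake are derived from
shared raw fields, so their categories cannot be drawn independently. The
generator draws the combined band exactly at its configured proportions,
then draws the fruit band from its configured proportions restricted to
bands feasible given the combined total (fruit <= total), renormalized.
The achieved fruit marginal is therefore a slightly reweighted version of
the configured one; :func:`coupled_fruit_marginal` computes it exactly and
it is what :class:`GroundTruth` reports for the fruit exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import io
from .exposure import (
    ACTIVITY_BANDS,
    CATEGORICAL_LEVELS,
    FRUIT_BANDS,
    FRUIT_VEG_BANDS,
    GRAMS_ALCOHOL_PER_DRINK,
    GRAMS_PER_SERVING,
)
from .models import (
    ACTIVITY_METS,
    ActivityItem,
    ContinuousDistribution,
    ExposureDistribution,
    OccurrenceRecord,
    RelativeRiskSet,
    SurveyRecord,
    ValidationError,
)

# Upper caps used when sampling inside an unbounded top band.
_FRUIT_CAP = 500.0
_FV_CAP = 800.0
_MET_CAP = 16000.0
_ALCOHOL_BANDS = (  # (label, lower, upper) on the gram scale for sampling
    ("abstainer", 0.0, 0.0),
    ("light", 1e-6, GRAMS_ALCOHOL_PER_DRINK),
    ("moderate", GRAMS_ALCOHOL_PER_DRINK + 1e-6, 50.0),
    ("heavy", 50.0, 100.0),
)

_ACTIVITY_DOMAINS = (
    "transport",
    "occupational_moderate",
    "occupational_vigorous",
    "recreational_moderate",
    "recreational_vigorous",
)

# Mean adult heights (m) used to back out weight from BMI.
_HEIGHT = {"male": (1.71, 0.07), "female": (1.59, 0.065)}


def _default_proportions() -> dict[tuple[str, str], tuple[float, ...]]:
    return {
        key: tuple(dist.proportions)
        for key, dist in io.load_prevalence().items()
    }


def _default_bmi() -> dict[str, tuple[float, float]]:
    return {
        sex: (dist.mean, dist.sd) for sex, dist in io.load_bmi().items()
    }


@dataclass
class GeneratorConfig:
    """Reproducible configuration of the synthetic-data generator.

    Defaults mirror the bundled survey conditions: per-sex sample size of
    a national health survey (~2900 respondents per sex), the published
    level proportions and BMI means, log-uniform categorical RRs in
    [1.2, 3.0], per-unit BMI RRs in [1.02, 1.25], Poisson site counts with
    mean 1000 cases and binomial death thinning at 0.55 (the observed
    deaths:cases ratio). Identical seeds give identical outputs.
    """

    seed: int = 0
    n_records: int = 2900  # per sex
    proportions: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=_default_proportions
    )
    bmi_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_bmi
    )
    rr_range: tuple[float, float] = (1.2, 3.0)
    bmi_rr_range: tuple[float, float] = (1.02, 1.25)
    dirichlet_concentration: float | None = None
    occurrence_mean_cases: float = 1000.0
    death_fraction: float = 0.55
    exposures: tuple[str, ...] | None = None
    sites: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")
        if not 0 <= self.death_fraction <= 1:
            raise ValidationError("death_fraction must be in [0, 1]")
        for key, props in self.proportions.items():
            p = np.asarray(props, dtype=float)
            if p.size == 0:
                raise ValidationError(f"{key}: empty level proportions")
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValidationError(
                    f"{key}: level proportions must be nonnegative and sum to 1"
                )


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, stream])


def resolved_proportions(
    config: GeneratorConfig,
) -> dict[tuple[str, str], np.ndarray]:
    """Level proportions actually used by the generator.

    With ``dirichlet_concentration`` set, proportions are drawn once per
    exposure and sex from a Dirichlet centred on the configured values
    (concentration x proportion per level); otherwise the configured
    values are used as-is. Deterministic in the seed.
    """
    rng = _rng(config, 1)
    out = {}
    for key in sorted(config.proportions):
        p = np.asarray(config.proportions[key], dtype=float)
        if config.dirichlet_concentration is not None:
            alpha = np.maximum(config.dirichlet_concentration * p, 1e-3)
            p = rng.dirichlet(alpha)
        out[key] = p
    return out


def coupled_fruit_marginal(
    p_fruit: np.ndarray, p_total: np.ndarray
) -> np.ndarray:
    """Achieved fruit-band marginal under the fruit<=total coupling.

    The combined fruits+vegetables total ``T`` is uniform within its band
    (top band capped); the fruit band is then drawn from ``p_fruit``
    restricted to bands whose lower edge lies below ``T``. Because the
    feasible set only changes at fruit-band lower edges, the expectation
    over ``T`` is an exact finite sum over segments.
    """
    p_fruit = np.asarray(p_fruit, dtype=float)
    p_total = np.asarray(p_total, dtype=float)
    lowers = [b.lower for b in FRUIT_BANDS]
    out = np.zeros(len(FRUIT_BANDS))
    for band, q in zip(FRUIT_VEG_BANDS, p_total):
        lo = band.lower
        hi = band.upper if math.isfinite(band.upper) else _FV_CAP
        cuts = sorted({lo, hi} | {l for l in lowers if lo < l < hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            feasible = [j for j, l in enumerate(lowers) if l <= a]
            w = p_fruit[feasible]
            if w.sum() > 0:
                w = w / w.sum()
            else:
                w = np.full(len(feasible), 1.0 / len(feasible))
            frac = (b - a) / (hi - lo)
            for j, wj in zip(feasible, w):
                out[j] += q * frac * wj
    return out


def true_prevalence(
    config: GeneratorConfig,
) -> dict[tuple[str, str], np.ndarray]:
    """Ground-truth level proportions, with the fruit coupling applied."""
    resolved = resolved_proportions(config)
    out = dict(resolved)
    for sex in ("male", "female"):
        key_f, key_t = ("fruit", sex), ("fruit_veg", sex)
        if key_f in out and key_t in out:
            out[key_f] = coupled_fruit_marginal(out[key_f], out[key_t])
    return out


def _sample_in(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def _sample_fruit_given_total(
    rng: np.random.Generator, p_fruit: np.ndarray, total: float
) -> float:
    lowers = [b.lower for b in FRUIT_BANDS]
    feasible = [j for j, l in enumerate(lowers) if l < total]
    if not feasible:
        return 0.0
    w = p_fruit[feasible]
    if w.sum() > 0:
        w = w / w.sum()
    else:
        w = np.full(len(feasible), 1.0 / len(feasible))
    j = int(rng.choice(feasible, p=w))
    band = FRUIT_BANDS[j]
    hi = min(band.upper if math.isfinite(band.upper) else _FRUIT_CAP, total)
    return _sample_in(rng, band.lower, hi)


def generate_survey(
    config: GeneratorConfig,
) -> tuple[list[SurveyRecord], dict[tuple[str, str], np.ndarray]]:
    """Draw survey records whose derived categories follow known truth.

    Returns the records and the ground-truth prevalence proportions
    (including the coupling-adjusted fruit marginal). Raw fields are
    back-generated so that the derivation operations of
    :mod:`paftool.exposure` reproduce the drawn categories exactly.
    """
    rng = _rng(config, 0)
    resolved = resolved_proportions(config)
    records: list[SurveyRecord] = []
    for sex in ("male", "female"):
        n = config.n_records
        alc_idx = rng.choice(4, size=n, p=resolved[("alcohol", sex)])
        fv_idx = rng.choice(
            len(FRUIT_VEG_BANDS), size=n, p=resolved[("fruit_veg", sex)]
        )
        act_idx = rng.choice(
            len(ACTIVITY_BANDS), size=n, p=resolved[("physical_activity", sex)]
        )
        smoke_idx = rng.choice(3, size=n, p=resolved[("smoking", sex)])
        p_passive_yes = resolved[("passive_smoking", sex)][1]
        bmi_mean, bmi_sd = config.bmi_params[sex]
        bmis = np.clip(rng.normal(bmi_mean, bmi_sd, size=n), 12.0, 65.0)
        h_mean, h_sd = _HEIGHT[sex]
        heights = np.clip(rng.normal(h_mean, h_sd, size=n), 1.3, 2.2)
        ages = rng.uniform(20.0, 80.0, size=n)
        weights = rng.gamma(20.0, 1.0 / 20.0, size=n)
        p_fruit = resolved[("fruit", sex)]

        for i in range(n):
            _, lo, hi = _ALCOHOL_BANDS[alc_idx[i]]
            drinks = _sample_in(rng, lo, hi) / GRAMS_ALCOHOL_PER_DRINK

            band = FRUIT_VEG_BANDS[fv_idx[i]]
            total = _sample_in(
                rng,
                band.lower,
                band.upper if math.isfinite(band.upper) else _FV_CAP,
            )
            fruit = _sample_fruit_given_total(rng, p_fruit, total)
            veg = total - fruit

            aband = ACTIVITY_BANDS[act_idx[i]]
            met = _sample_in(
                rng,
                aband.lower,
                aband.upper if math.isfinite(aband.upper) else _MET_CAP,
            )
            activity: tuple[ActivityItem, ...] = ()
            if met > 0:
                domain = _ACTIVITY_DOMAINS[int(rng.integers(5))]
                activity = (
                    ActivityItem(domain, 7.0, met / (ACTIVITY_METS[domain] * 7.0)),
                )

            status = ("never", "former", "current")[smoke_idx[i]]
            home_smoke = (
                "yes" if rng.uniform() < p_passive_yes else "no"
            )

            records.append(
                SurveyRecord(
                    sex=sex,
                    age=float(ages[i]),
                    drinks_per_day=drinks,
                    weight=float(bmis[i] * heights[i] ** 2),
                    height=float(heights[i]),
                    fruit_servings_per_day=fruit / GRAMS_PER_SERVING,
                    fruit_days_per_week=7.0,
                    veg_servings_per_day=veg / GRAMS_PER_SERVING,
                    veg_days_per_week=7.0,
                    activity=activity,
                    smoking_status=status,
                    home_smoke_exposure=home_smoke,
                    survey_weight=float(weights[i]),
                )
            )
    return records, true_prevalence(config)


def _roster(
    config: GeneratorConfig,
) -> list[tuple[str, str, str]]:
    """(exposure, site, sex) triples to emulate, from the bundled map."""
    site_map = io.load_site_exposure_map()
    triples = []
    for _, row in site_map.iterrows():
        if config.exposures is not None and row["exposure"] not in config.exposures:
            continue
        if config.sites is not None and row["site"] not in config.sites:
            continue
        sexes = (
            ("male", "female") if row["sexes"] == "both" else (row["sexes"],)
        )
        for sex in sexes:
            triples.append((row["exposure"], row["site"], sex))
    return triples


def generate_rr_table(config: GeneratorConfig) -> list[RelativeRiskSet]:
    """Draw monotone RR sets for the configured exposure-site-sex roster.

    Categorical RRs are log-uniform in ``rr_range``, sorted so risk is
    non-decreasing away from the TMREL (whose RR is exactly 1); the BMI
    exposure gets a per-unit log-linear RR from ``bmi_rr_range``.
    """
    rng = _rng(config, 2)
    out = []
    for exposure, site, sex in _roster(config):
        if exposure == "high_bmi":
            lo, hi = config.bmi_rr_range
            rr_unit = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            out.append(
                RelativeRiskSet(
                    exposure, site, sex, "per_unit", rr_per_unit=rr_unit
                )
            )
        else:
            levels = CATEGORICAL_LEVELS[exposure]
            lo, hi = config.rr_range
            draws = np.exp(
                rng.uniform(np.log(lo), np.log(hi), size=len(levels) - 1)
            )
            rr = np.concatenate([[1.0], np.sort(draws)])
            out.append(
                RelativeRiskSet(
                    exposure, site, sex, "categorical", levels=levels, rr=rr
                )
            )
    return out


def generate_occurrence(config: GeneratorConfig) -> list[OccurrenceRecord]:
    """Poisson case counts per site and sex, deaths by binomial thinning."""
    rng = _rng(config, 3)
    seen = []
    for exposure, site, sex in _roster(config):
        if (site, sex) not in seen:
            seen.append((site, sex))
    out = []
    for site, sex in seen:
        cases = int(rng.poisson(config.occurrence_mean_cases))
        deaths = int(rng.binomial(cases, config.death_fraction)) if cases else 0
        out.append(OccurrenceRecord(site, sex, cases, deaths))
    return out


# ---------------------------------------------------------------------------
# Independent PAF oracles (duplicate arithmetic, different code path)


def oracle_paf_categorical(
    proportions: Sequence[float], rr: Sequence[float], tmrel_index: int = 0
) -> float:
    """Loop-based categorical PAF: (sum p r - r_tmrel) / sum p r."""
    observed = 0.0
    for p, r in zip(proportions, rr):
        observed += p * r
    counterfactual = rr[tmrel_index]
    return (observed - counterfactual) / observed


def oracle_paf_continuous(
    mean: float,
    sd: float,
    rr_per_unit: float,
    cf_mean: float = 22.0,
    cf_sd: float = 1.0,
    tmrel: float = 22.0,
    support: tuple[float, float] = (10.0, 60.0),
    n_grid: int = 20001,
) -> float:
    """Trapezoid-rule continuous PAF for a log-linear dose-response."""
    lo, hi = support
    x = np.linspace(lo, hi, n_grid)
    rr = rr_per_unit ** np.clip(x - tmrel, 0.0, None)

    def mean_rr(m: float, s: float) -> float:
        dens = np.exp(-0.5 * ((x - m) / s) ** 2)
        return float(np.trapezoid(rr * dens, x) / np.trapezoid(dens, x))

    observed = mean_rr(mean, sd)
    counterfactual = mean_rr(cf_mean, cf_sd)
    return (observed - counterfactual) / observed


def oracle_combine(pafs: Sequence[float]) -> float:
    """Loop-based combined PAF: 1 - prod(1 - p)."""
    remaining = 1.0
    for p in pafs:
        remaining *= 1.0 - p
    return 1.0 - remaining


@dataclass
class GroundTruth:
    """Analytic truth for a synthetic study, from generator parameters."""

    prevalence: dict[tuple[str, str], np.ndarray]
    bmi: dict[str, tuple[float, float]]
    paf: dict[tuple[str, str, str], float]
    combined: dict[tuple[str, str], float]
    attributable: dict[tuple[str, str, str], float]


@dataclass
class SyntheticStudy:
    """Everything one pipeline run needs, plus its ground truth."""

    config: GeneratorConfig
    records: list[SurveyRecord]
    rr_sets: list[RelativeRiskSet]
    occurrence: list[OccurrenceRecord]
    truth: GroundTruth

    def exact_prevalence(
        self,
    ) -> tuple[
        dict[tuple[str, str], ExposureDistribution],
        dict[str, ContinuousDistribution],
    ]:
        """Prevalence objects built from the truth (no sampling noise)."""
        categorical = {
            key: ExposureDistribution(
                key[0], key[1], CATEGORICAL_LEVELS[key[0]], props
            )
            for key, props in self.truth.prevalence.items()
        }
        bmi = {
            sex: ContinuousDistribution("high_bmi", sex, mean, sd)
            for sex, (mean, sd) in self.truth.bmi.items()
        }
        return categorical, bmi


def ground_truth(
    config: GeneratorConfig,
    rr_sets: Sequence[RelativeRiskSet],
    occurrence: Sequence[OccurrenceRecord] = (),
) -> GroundTruth:
    """Compute true PAFs for generated RR sets via the independent oracles."""
    prevalence = true_prevalence(config)
    paf: dict[tuple[str, str, str], float] = {}
    for rr in rr_sets:
        key = (rr.exposure_id, rr.cancer_site, rr.sex)
        if rr.form == "categorical":
            props = prevalence[(rr.exposure_id, rr.sex)]
            paf[key] = oracle_paf_categorical(
                list(props), list(rr.rr), rr.tmrel_index
            )
        else:
            mean, sd = config.bmi_params[rr.sex]
            paf[key] = oracle_paf_continuous(mean, sd, rr.rr_per_unit)
    combined: dict[tuple[str, str], float] = {}
    by_site_sex: dict[tuple[str, str], list[float]] = {}
    for (exposure, site, sex), value in paf.items():
        by_site_sex.setdefault((site, sex), []).append(value)
    for key, values in by_site_sex.items():
        combined[key] = oracle_combine(values)
    attributable: dict[tuple[str, str, str], float] = {}
    for occ in occurrence:
        key = (occ.cancer_site, occ.sex)
        if key in combined:
            attributable[(occ.cancer_site, occ.sex, "cases")] = (
                combined[key] * occ.cases
            )
            attributable[(occ.cancer_site, occ.sex, "deaths")] = (
                combined[key] * occ.deaths
            )
    return GroundTruth(
        prevalence=prevalence,
        bmi=dict(config.bmi_params),
        paf=paf,
        combined=combined,
        attributable=attributable,
    )


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate records, RR sets and occurrence counts with ground truth."""
    records, _ = generate_survey(config)
    rr_sets = generate_rr_table(config)
    occurrence = generate_occurrence(config)
    truth = ground_truth(config, rr_sets, occurrence)
    return SyntheticStudy(config, records, rr_sets, occurrence, truth)
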