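"""Population attributable fraction (PAF) engines.

Three estimators make up the comparative-risk-assessment core:

* :func:`paf_categorical` — the categorical PAF
  ``(sum_i P_i RR_i - sum_i P*_i RR_i) / sum_i P_i RR_i`` where ``P*`` is a
  point mass at the TMREL level, which reduces to ``1 - 1/sum_i P_i RR_i``;
* :func:`paf_continuous` — the continuous PAF
  ``(int RR(x) P(x) dx - int RR(x) P*(x) dx) / int RR(x) P(x) dx`` with the
  observed exposure density ``P`` and the counterfactual TMREL density
  ``P*`` (BMI: Normal(22, 1) kg/m^2), evaluated by deterministic
  Gauss-Legendre quadrature;
* :func:`combine_pafs` — the combined PAF ``1 - prod_i (1 - PAF_i)`` under
  independence of risk factors.

Dose-response models for the continuous pathway are log-linear
(``RR(x) = rr_per_unit**(x - tmrel)`` above the TMREL) and a log-logit
saturation alternative; both clamp ``RR = 1`` below the TMREL so that no
protective credit is given for exposure under the counterfactual level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .models import (
    ContinuousDistribution,
    ExposureDistribution,
    PafValue,
    RelativeRiskSet,
    ValidationError,
)

DOSE_RESPONSE_MODELS = ("log_linear", "log_logit")


def paf_categorical(
    dist: ExposureDistribution,
    rr: RelativeRiskSet,
    measure: str = "cases",
) -> PafValue:
    """Categorical PAF for one exposure-site-sex pair.

    ``dist`` and ``rr`` must describe the same exposure with identically
    ordered levels and the same TMREL level. The counterfactual places the
    whole population at the TMREL level, so its risk-weighted sum is
    exactly ``RR[tmrel] = 1``.
    """
    if rr.form != "categorical":
        raise ValidationError(
            "paf_categorical needs a categorical RelativeRiskSet"
        )
    if dist.exposure_id != rr.exposure_id:
        raise ValidationError(
            f"exposure mismatch: {dist.exposure_id!r} vs {rr.exposure_id!r}"
        )
    if tuple(dist.levels) != tuple(rr.levels) or dist.tmrel_index != rr.tmrel_index:
        raise ValidationError(
            f"{dist.exposure_id}: exposure levels of the distribution and "
            "the RR set are not aligned"
        )
    observed = float(np.dot(dist.proportions, rr.rr))
    counterfactual = float(rr.rr[dist.tmrel_index])
    paf = (observed - counterfactual) / observed
    return PafValue(dist.exposure_id, rr.cancer_site, rr.sex, measure, paf)


@dataclass
class DoseResponseModel:
    """Dose-response RR curve for a continuous exposure (BMI, kg/m^2).

    Parameters
    ----------
    model_id:
        ``"log_linear"``: ``ln RR(x) = ln(rr_per_unit) * d`` with dose
        ``d = max(x - tmrel, 0)``.
        ``"log_logit"``: a logistic saturation of ``ln RR`` in dose,
        ``ln RR = A * [sigma((d - D/2)/s) - sigma(-D/(2s))]`` with
        saturation span ``D = saturation_span`` and scale ``s``. With the
        default ``s = D/4`` and amplitude ``A = ln(rr_per_unit) * D``, the
        curve's steepest slope (at dose ``D/2``) equals the log-linear
        slope ``ln(rr_per_unit)``; the offset enforces ``RR(tmrel) = 1``.
        The published risk-assessment literature cites a log-logit shape
        without printing its formula, so this is an explicitly labelled
        interpretation — log-linear is the default model.
    rr_per_unit:
        RR per 1 kg/m^2 increase above the TMREL.
    tmrel:
        theoretical-minimum-risk exposure level, default 22 kg/m^2.
    cap_dose:
        optional BMI value beyond which RR stops increasing (dose
        saturation for extreme exposures).
    """

    model_id: str = "log_linear"
    rr_per_unit: float = 1.10
    tmrel: float = 22.0
    cap_dose: float | None = None
    saturation_span: float = 25.0
    logistic_scale: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in DOSE_RESPONSE_MODELS:
            raise ValidationError(
                f"unknown dose-response model {self.model_id!r}; "
                f"expected one of {DOSE_RESPONSE_MODELS}"
            )
        if self.rr_per_unit <= 0:
            raise ValidationError("rr_per_unit must be positive")
        if self.cap_dose is not None and self.cap_dose <= self.tmrel:
            raise ValidationError("cap_dose must exceed the TMREL")
        if self.saturation_span <= 0:
            raise ValidationError("saturation_span must be positive")
        if self.logistic_scale is None:
            self.logistic_scale = self.saturation_span / 4.0


def rr_at_dose(x, model: DoseResponseModel):
    """Relative risk at exposure value(s) ``x`` under a dose-response model.

    Clamped to ``RR = 1`` for ``x <= tmrel`` (no protective extrapolation
    below the counterfactual level). Accepts scalars or arrays and returns
    the matching shape.
    """
    arr = np.asarray(x, dtype=float)
    dose = np.maximum(arr - model.tmrel, 0.0)
    if model.cap_dose is not None:
        dose = np.minimum(dose, model.cap_dose - model.tmrel)
    log_rr_unit = math.log(model.rr_per_unit)
    if model.model_id == "log_linear":
        log_rr = log_rr_unit * dose
    else:  # log_logit
        span = model.saturation_span
        scale = model.logistic_scale
        offset = expit(-span / (2.0 * scale))
        amplitude = log_rr_unit * span
        log_rr = amplitude * (expit((dose - span / 2.0) / scale) - offset)
    with np.errstate(over="ignore"):  # overflow is diagnosed by the caller
        result = np.exp(log_rr)
    return float(result) if np.isscalar(x) else result


def paf_continuous(
    dist: ContinuousDistribution,
    model: DoseResponseModel,
    measure: str = "cases",
    *,
    n_nodes: int = 512,
    support: tuple[float, float] = (10.0, 60.0),
    cancer_site: str = "",
) -> PafValue:
    """Continuous PAF by deterministic quadrature of the dose-response curve.

    The observed density is Normal(mean, sd) and the counterfactual is
    Normal(cf_mean, cf_sd), both truncated to ``support`` (default
    [10, 60] kg/m^2, covering plausible human BMI) and renormalized.
    Integrals use Gauss-Legendre quadrature with ``n_nodes`` nodes
    (default 512), which is reproducible to well below 1e-8 across grid
    refinements for the smooth integrands that arise here.
    """
    lo, hi = support
    if not lo < hi:
        raise ValidationError("support must be an increasing interval")
    # The dose-response curve has derivative kinks at the TMREL (clamp to
    # RR = 1) and at cap_dose; splitting the panel there keeps the
    # quadrature spectrally accurate.
    breaks = sorted(
        {lo, hi}
        | {
            b
            for b in (model.tmrel, model.cap_dose)
            if b is not None and lo < b < hi
        }
    )
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    xs, ws = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        xs.append(0.5 * (b - a) * nodes + 0.5 * (b + a))
        ws.append(0.5 * (b - a) * weights)
    x = np.concatenate(xs)
    w = np.concatenate(ws)
    rr = rr_at_dose(x, model)
    if not np.all(np.isfinite(rr)):
        raise ValidationError(
            "dose-response RR overflows on the integration range; set "
            "cap_dose to saturate the curve at a finite dose"
        )

    def mean_rr(mean: float, sd: float) -> float:
        mass = norm.cdf(hi, mean, sd) - norm.cdf(lo, mean, sd)
        if mass <= 0:
            raise ValidationError(
                "the exposure density has no mass on the integration "
                "support; widen `support`"
            )
        return float(np.sum(w * rr * norm.pdf(x, mean, sd)) / mass)

    observed = mean_rr(dist.mean, dist.sd)
    counterfactual = mean_rr(dist.cf_mean, dist.cf_sd)
    paf = (observed - counterfactual) / observed
    return PafValue(dist.exposure_id, cancer_site, dist.sex, measure, paf)


def combine_pafs(pafs: Iterable[float]) -> float:
    """Combined PAF of independent risk factors: ``1 - prod(1 - PAF_i)``.

    Order-invariant; for nonnegative inputs the result is at least the
    largest component and strictly below 1.
    """
    values = [float(p) for p in pafs]
    if not values:
        raise ValidationError("combine_pafs needs at least one PAF")
    complement = 1.0
    for p in values:
        if p >= 1.0:
            raise ValidationError(f"PAF {p} >= 1 cannot be combined")
        complement *= 1.0 - p
    return 1.0 - complement
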