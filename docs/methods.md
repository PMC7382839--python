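# Methods

## Scope and model

`paftool` implements a comparative risk assessment of cancer burden: the
share of cancer cases and deaths attributable to six lifestyle risk
factors, computed as population attributable fractions (PAFs) against
theoretical-minimum-risk counterfactuals and converted to attributable
counts by site, sex and measure.

Three estimators form the core:

1. **Categorical PAF.** With level proportions `P_i` and relative risks
   `RR_i` (TMREL level fixed at `RR = 1`), the counterfactual places all
   mass at the TMREL, so `Σ P*_i RR_i = 1` and
   `PAF = (Σ P_i RR_i − 1) / Σ P_i RR_i = 1 − 1/Σ P_i RR_i`.
2. **Continuous PAF (BMI).** The observed exposure is modelled as
   Normal(mean, sd) and the counterfactual as Normal(22, 1) kg/m², both
   truncated to [10, 60] kg/m² (plausible human BMI) and renormalized.
   `PAF = (E[RR(X)] − E*[RR(X)]) / E[RR(X)]` with both expectations
   evaluated by Gauss–Legendre quadrature (512 nodes per smooth panel;
   the integration interval is split at the TMREL and at any dose cap,
   where the dose–response curve has derivative kinks, preserving
   spectral accuracy — results are stable to well below 1e-8 under grid
   refinement).
3. **Combined PAF.** `1 − Π (1 − PAF_i)` across risk factors acting on a
   site, assuming independence (no statistical interaction).

Attribution rules:

* attributable count = PAF × site total, carried unrounded;
* both-sex quantities are always pooled sex-specific attributable counts
  divided by pooled totals (combining printed both-sex PAFs
  multiplicatively does not reproduce the published oral-cavity value;
  pooling does);
* subtype restrictions dilute a subtype PAF to the site:
  site PAF = subtype share × subtype PAF (stomach cardia 32%/22% of
  male/female counts for BMI; esophageal adenocarcinoma 15%/14% for BMI
  and squamous cell carcinoma 85%/86% for alcohol). Advanced prostate
  cancer uses a count rule instead of a fixed share: its case count is
  set equal to the site's death count, so the incidence-side share is
  deaths/cases and the mortality-side share is 1;
* risk-factor combination happens on site-level per-exposure PAFs (the
  published per-site combined values are reproduced this way); a
  subtype-level combination is possible in principle but is not the
  default because the published tables are printed at site level.

## Dose–response models

* `log_linear` (default): `ln RR(x) = ln(rr_per_unit) · d`, dose
  `d = max(x − 22, 0)`, optionally capped at `cap_dose`.
* `log_logit`: a logistic saturation of `ln RR` in dose,
  `ln RR = ln(rr_per_unit) · D · [σ((d − D/2)/s) − σ(−D/(2s))]` with
  saturation span `D` (default 25 kg/m²) and scale `s = D/4`. The offset
  enforces `RR = 1` at the TMREL, and with `s = D/4` the curve's
  steepest slope — at the midpoint dose `D/2` — equals the log-linear
  slope `ln(rr_per_unit)`. Slope-matching exactly *at* the TMREL is not
  attainable in this family (the logistic centred at `D/2` is nearly
  flat at zero dose), so the midpoint convention is used and documented;
  the log-logit form in the source literature is cited without a printed
  formula, and this implementation is an explicitly labelled
  interpretation.

Both models clamp `RR = 1` below the TMREL: no protective credit for
exposure under the counterfactual level. Negative PAFs (genuinely
protective exposure patterns) are returned as-is with a warning, never
clamped to zero.

## Exposure derivation

Raw survey fields are converted as: alcohol 12.5 g of pure alcohol per
drink; fruits/vegetables servings × 80 g × days-per-week / 7 (weekly
average); physical activity Σ MET × minutes/day × days/week with GPAQ
MET values 4.0 (active transport), 3.8/7.8 (moderate/vigorous
occupational), 3.0/6.0 (moderate/vigorous recreational); BMI =
self-reported weight/height² with no correction. Passive smoking is
defined among never-smokers only.

Band boundaries: printed prevalence bands overlap or leave gaps
("1–12.5", "12.6–49.9" g/day), so the gram/MET scales are partitioned
with half-open intervals — alcohol: abstainer {0}, light (0, 12.5],
moderate (12.5, 50), heavy [50, ∞), with (0, 1) g/day assigned to light
(the printed "1–" lower bound is read as "any positive intake");
fruits/vegetables and MET bands are left-closed `[lower, upper)`. This
makes categorization total on [0, ∞), which is property-tested.

Prevalence estimation uses simple survey-weighted proportions (weights
normalized within the sex stratum; invariant to uniform rescaling). The
source survey's multistage sampling design, nonresponse adjustment and
design-effect variances are out of scope — the published analysis uses
point prevalences only.

## Bundled fixtures

The fixtures transcribe in-table point estimates: level prevalences by
sex, per exposure–site–sex PAF columns with site totals for cases and
deaths, occurrence counts per site/sex with the all-cancer denominators
(50,320 cases; 28,010 deaths), subtype splits, and the exposure→site
eligibility map. Printed proportions that sum to 0.999/1.001 are
renormalized at load time (tolerance 0.02, then exact renormalization).

The BMI *population* standard deviation is not printed in the source
table (only the mean with its confidence interval); the bundled values
(6.0 kg/m² men, 5.6 kg/m² women) were chosen once as plausible adult
values consistent with the printed precision of the means at the
survey's sample size. They matter only for the estimation path — the
reproduction path and all published-aggregate checks consume the printed
PAF columns directly.

Physical activity is associated with colon cancer in the exposure table
but reported against colorectum totals in the burden tables; the package
follows the burden-table convention (colorectum totals). This
inconsistency in the source is flagged here rather than resolved.

## Synthetic data generator

The generator emulates the study conditions: per-sex samples of a
national health survey (default 2,900 records per sex, matching the
survey's ~5,800 adult respondents), level proportions and BMI means
defaulting to the bundled prevalence tables, log-uniform categorical RRs
in [1.2, 3.0] and per-unit BMI RRs in [1.02, 1.25] (typical magnitudes
in the cancer risk-factor literature), Poisson site counts with mean
1,000 cases and binomial death thinning at 0.55 (the observed
deaths:cases ratio). Raw survey fields are back-generated so that the
derivation operations reproduce the drawn categories exactly; identical
seeds give identical outputs.

Fruit-only and combined fruit+vegetable intakes share raw fields, so
their categories cannot be drawn independently: the combined band is
drawn exactly at its configured proportions, the fruit band is then
drawn from its configured proportions restricted to feasible bands
(fruit ≤ total), renormalized. The achieved fruit marginal is a slightly
reweighted mixture, computed exactly by `coupled_fruit_marginal` (the
feasible set changes only at fruit-band lower edges, so the expectation
over the uniform within-band total is a finite sum), and that adjusted
marginal is what the ground truth reports.

The ground-truth PAF oracle is deliberately a second implementation
(plain loops; trapezoid integration on a 20,001-point grid with an
explicitly coded normal density) so that it is independent of the
engine's vectorized closed form and Gauss–Legendre quadrature. Agreement
is exact (≈1e-16) for the categorical path and below 1e-6 for the
continuous path.

What the generator does **not** emulate: clustered/multistage sampling,
nonresponse, within-person correlation between exposures (each exposure
is drawn independently), age structure, or reporting biases of
self-reported behaviour. Passing the recovery tests therefore shows the
pipeline's arithmetic is right under the modelled conditions, not that
real survey estimates are unbiased.

## Numerical conventions

* All pipeline arithmetic is unrounded; presentation rounding (PAF to
  0.1 percentage point, counts to integers) rounds half away from zero
  via decimal arithmetic on the shortest float repr.
* Quadrature: Gauss–Legendre, 512 nodes per panel, panels split at
  dose–response kinks; truncated-normal masses from the normal CDF.
* An RR curve that overflows on the integration range (extreme
  `rr_per_unit` without a cap) raises with advice to set `cap_dose`.
* Degenerate inputs (empty strata, zero total weight, zero-level
  distributions, misaligned level vectors, subtype RRs without a split)
  raise `ValidationError` naming the offending stratum or column.

## Reproduction accuracy and known limitations

Because the published per-exposure PAFs are printed rounded to 0.1
percentage point, aggregates recomputed from them carry a small
propagation error. The package reproduces the headline per-site combined
PAFs (lung 90.9%, larynx 91.6%, oral cavity/pharynx 79.6%, esophagus
71.8% both sexes; lung 92.2%/89.2% by sex), smoking's 9232 attributable
cases (18.3% of all cases; 24.5% of deaths) and high BMI's shares (8.7%
of cases; 9.2% of deaths) exactly at printed precision. The two grand
totals (15,097 attributable cases; 10,155 deaths) come out ≈0.02% high
when recomputed from the printed site-level PAFs — the published totals
evidently used unrounded internal values — and are asserted only within
2%.

Confidence intervals on PAFs and attributable counts are out of scope
(the source analysis reports none), as is age-stratified attribution
(all inputs are aligned by sex only) and retrieval of the relative risks
behind the published PAF columns (cited to prior meta-analyses but not
printed; the estimation path treats RRs as input data).
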