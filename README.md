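# paftool

Population attributable fractions (PAFs) of cancer for lifestyle risk
factors — a comparative-risk-assessment toolkit for epidemiologists who
want to quantify how much of a population's cancer burden is attributable
to modifiable exposures (alcohol consumption, high body mass index, low
fruit and vegetable consumption, lack of physical activity, tobacco
smoking, passive smoking).

The bundled data transcribe the point estimates of a published national
assessment for Chile in 2018 (exposure prevalences from the 2016–2017
national health survey; cancer occurrence from GLOBOCAN 2018), so the
package reproduces that study's burden tables out of the box, and every
stage can also be run on your own prevalence, relative-risk and
occurrence inputs or on synthetic data with known ground truth.

## The model

For a categorical exposure with level proportions `P_i`, relative risks
`RR_i`, and a counterfactual `P*_i` that places the whole population at
the theoretical-minimum-risk exposure level (TMREL, where `RR = 1`):

```
PAF = ( Σ_i P_i RR_i − Σ_i P*_i RR_i ) / Σ_i P_i RR_i  =  1 − 1 / Σ_i P_i RR_i
```

For the continuous exposure (BMI), with observed density `P(x)` =
Normal(mean, sd), counterfactual `P*(x)` = Normal(22, 1) kg/m², and a
dose–response curve `RR(x)` (log-linear by default, clamped to 1 below
the TMREL of 22 kg/m²):

```
PAF = ( ∫ RR(x) P(x) dx − ∫ RR(x) P*(x) dx ) / ∫ RR(x) P(x) dx
```

Independent risk factors acting on the same cancer site combine as

```
PAF_combined = 1 − Π_i (1 − PAF_i)
```

Attributable counts are `PAF × total` per site, sex and measure
(cases or deaths); both-sex PAFs are always pooled attributable counts
over pooled totals, never products of printed both-sex PAFs. Subtype
restrictions dilute a subtype-specific PAF to the whole site (e.g. BMI
acts on cardia stomach cancer only: site PAF = cardia share × subtype
PAF; advanced prostate cancer cases are taken to equal prostate deaths).

## Worked example

Reproduce the incidence burden tables from the bundled fixtures:

```python
from paftool import reproduce_from_paf_table, round_paf_percent

result = reproduce_from_paf_table(measure="cases")
combined = result.combined.set_index(["site", "sex"])
print(round_paf_percent(combined.loc[("lung", "both"), "paf"]))    # 90.9
print(round_paf_percent(combined.loc[("larynx", "both"), "paf"]))  # 91.6
totals = result.exposure_totals.set_index(["exposure", "sex"])
print(round(totals.loc[("smoking", "both"), "attributable"]))      # 9232
print(round(totals.loc[("smoking", "both"), "share_percent"], 1))  # 18.3
print(round(100 * result.overall["paf"], 1))                       # 30.0
```

That is: 90.9% of lung cancer cases and 91.6% of larynx cancer cases in
both sexes combined are attributable to the six lifestyle factors
jointly; smoking alone accounts for 9232 cases, 18.3% of the 50,320
adult cancer cases, and the six factors together for 30.0%.

Or from a shell:

```sh
paftool reproduce --measure both --out results/
paftool simulate --seed 1 --n 10000 --out sim/        # synthetic study + ground truth
paftool derive --survey sim/survey_records.csv --out prevalence.csv
paftool compute --prevalence sim/prevalence.csv --rr sim/relative_risks.csv \
    --occurrence sim/occurrence.csv --measure cases --out attribution/
```

The estimation path (`compute`) runs prevalence + relative-risk inputs
through the PAF engines; published relative risks are not printed in the
source tables, so RR inputs are user-supplied or synthetic.

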