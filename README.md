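# circalux

Wearable light dosimetry and wrist-temperature circadian phase analysis.

People living in modern built environments largely replace the natural
solar light cycle with indoor light by day and electric light at night.
`circalux` is an analysis pipeline for quantifying that replacement from
wearable loggers and measuring its physiological consequence: it takes raw
time-stamped illuminance (lux) and wrist-temperature (°C) series, computes
light-exposure metrics on 17.00-anchored *observation days*, extracts each
day's circadian phase as the timing of the wrist-temperature maximum, maps
joint light/temperature structure with a bivariate local Moran's I, and
fits the phase-timing regression that asks: **does light at night delay the
circadian clock, and does morning light advance it?**

It is aimed at chronobiologists and environmental-health researchers
working with HOBO-style lux loggers and iButton-style skin-temperature
loggers, and ships a seeded synthetic cohort generator with a known
light → phase mechanism so every stage is testable end to end without
participant data.

## The model

Light exposure is the trapezoidal area under the log10-transformed lux
series (unit: log10lux·min), with a 10 lux detection floor mapped to
0 log10lux. For each participant *i* and season *s*, daily standardized
night-time (21.00–02.00) and morning (04.00–11.59) exposures and daily
maximum-temperature timings are averaged, and the phase readout
φ̄ᵢₛ (decimal hours after 17.00) is modelled by ordinary least squares:

```
φ̄ᵢₛ = β₀ + β_night · AUC̄_night,is + β_morning · AUC̄_morning,is + γ_s + εᵢₛ
```

with winter the reference season. Candidate term sets (all subsets of
{morning, night, season}) are ranked by AICc, k counting coefficients plus
the error variance. A positive β_night delays the temperature peak; a
negative β_morning advances it.

Supporting machinery, all in-package and oracle-tested: NOAA solar
position equations for sunrise/sunset-referenced windows; strict
biological-range masking (29.5–38.5 °C) and a strict <28% missingness day
filter; predictive-mean-matching imputation; a Reinsch natural cubic
smoothing spline with GCV-chosen penalty; cumulative order-8 queen
contiguity weights and the conditional-permutation LISA test; Tukey–Kramer
seasonal comparisons.

## Worked example

One command generates a cohort under the default study conditions
(18/16/15/12 participants across summer→spring, 7 days each, two outdoor
reference sites) and runs everything:

```sh
circalux run --seed 0 --outdir scratch/run
circalux report --outdir scratch/run
```

Equivalently, the numbered drivers under `analysis/` run the stages with
narrative output. On the default cohort (seed 0) they print:

```
day attrition: 427 in -> 349 kept (82%)
share of daily maxima between 00.00 and 03.00 clock: 51%

term                        estimate      s.e.   t-value    Pr(>|t|)
(intercept)                   7.6709    0.8881     8.637    0.0000 ***
mean night-time light         0.0051    0.0010     5.062    0.0000 ***
mean morning light           -0.0041    0.0016    -2.570    0.0129 *
...
coefficient recovery vs generator truth:
  night:   fitted +0.00507  true +0.00560
  morning: fitted -0.00407  true -0.00420

worked substitution examples (negative = earlier peak):
  +45 min of 5 log10lux morning light: -0.92 h
  -1 h of 3 log10lux night light (to darkness): -0.91 h
```

Reading this: roughly a fifth of temperature days are lost to
device-removal artifacts; the surviving peaks cluster after midnight; the
fitted coefficients recover the generator's true mechanism (night light
delays the peak ~0.005 h per log10lux·min, morning light advances it
~0.004 h per log10lux·min); and translating the coefficients into
daily-life terms, swapping 45 dim morning minutes for bright outdoor light,
or cutting an hour of bright indoor light at night, each moves the
temperature peak about an hour earlier.

Small summary tables from these runs live in `results/`; bulky per-day
tables and the generated sensor files go to `scratch/`.

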