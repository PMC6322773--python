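# tapeweight

Virtual validation of tape-based paediatric weight estimation.

When a young child cannot be weighed — during emergency care, or in settings
without a scale — weight must be estimated to dose drugs safely. The most
accurate bedside systems are length-based tapes, optionally refined by a
habitus (body-build) indicator such as mid-arm circumference (MAC). A
*virtual* study evaluates such systems by applying their lookup rules to a
database of measured anthropometry (weight, length, MAC) instead of to
children directly.

`tapeweight` is a toolkit for running such studies end to end on cohorts of
children aged 6–59 months:

* **Estimators** — calibration-table-driven lookups for the PAWPER XL-MAC
  tape (length segment → MAC cut-off → weight), two Broselow tape editions
  (length segment → weight), and the Ralston three-tape method (MAC band
  <115 mm / 115–125 mm / >125 mm selects one of three length tapes).
  Calibrations are pluggable, validated JSON files.
* **Growth reference** — LMS (Box-Cox power, median, coefficient of
  variation) z-scoring with the WHO-style restricted adjustment beyond
  ±3 SD, interpolation, and the standard wasting/stunting/BMI-for-age bins.
* **Accuracy statistics** — for percentage error PE = 100·(est − actual)/actual:
  mean percentage error (MPE, bias), Bland–Altman 95% limits of agreement
  LOA = MPE ± 1.96·SD (precision), RMSPE = √(ΣPE²/n), and p10/p20 (the
  percentage of estimates within ±10%/±20% of measured weight). Includes the
  normal-integral imputation of p10/p20 from a published (MPE, LOA) pair,
  McNemar paired tests with matched odds ratios, and paired t-tests.
* **Pipeline** — indicator derivation, estimation, subgroup stratification
  (sex, age, weight, BMI-for-age, weight-for-height, region), paired method
  comparisons, and the acceptability rule p10 ≥ 70% and p20 ≥ 95%.
* **Simulator** — synthetic cohorts with the marginal structure of pooled
  nutritional surveys from low- and middle-income countries (HAZ ~ N(−1.5, 1.5),
  WHZ ~ N(−0.6, 1.2), MAC mean 14.2 cm), so everything runs offline.

The shipped growth tables and tape calibrations are **synthetic fixtures**
(clearly flagged `clinical: false`): they are shaped like the real artifacts
so the full toolchain is exercised, but they are not the WHO standards nor
the published clinical tapes, and must not be used on real children.

## Worked example

```sh
tapeweight simulate --n 20000 --seed 42 --out cohort.csv
tapeweight report --cohort cohort.csv --seed 42 --out-dir out/
```

or through the library:

```python
import tapeweight as tw
from tapeweight.io import read_cohort, assign_regions

df = assign_regions(read_cohort("cohort.csv"))
ref = tw.fixture_reference()
df, _ = tw.derive_indicators(df, ref)
cals = tw.fixture_calibrations(ref)
df, _ = tw.apply_estimators(df, cals)
report = tw.run_subgroups(df, list(cals))
```

which, for this seed, yields the overall table

```
method            MPE (LOA)            RMSPE  p10   p20   acceptable
pawper_xl_mac      2.3 (-18.1, 22.6)  10.6  66.6  94.0  False
broselow_2007B     5.5 (-15.8, 26.7)  12.1  60.2  89.9  False
broselow_2011A     9.9 (-12.2, 32.1)  15.1  48.4  81.2  False
ralston            3.9 (-15.3, 23.2)  10.6  65.9  93.9  False
```

MPE is the mean signed percentage error (bias; negative = underestimation),
the LOA bracket 95% of individual errors, and p10/p20 are the share of
estimates within ±10%/±20% of measured weight. Here the MAC-using tape is
the least biased and most accurate, the 2011A length-only edition
overestimates most (its fixture reads half a z-unit heavier, mirroring the
documented recalibration between editions), and no method reaches the
acceptability bar under the deliberately coarse fixture calibrations —
the fixtures exist to exercise the machinery, not to certify a tape.
Paired contrasts follow the same pattern, e.g.

```
p10 vs broselow_2011A: 66.6 vs 48.4, rel diff 38%, OR 2.18 (2.09, 2.27), p=1.77e-296
```

## Re-analysing a real dataset

The cohort reader ingests any CSV with columns
`country, year, sex, age_months, weight_kg, height_cm, mac_cm` and optional
pre-computed survey z-scores (`waz, haz, whz, baz`), which pass through
untouched by default. Large open anthropometric survey compilations
distribute in exactly this shape; to re-run a full-scale validation, point
`tapeweight report` at such a file together with real calibration JSONs and
a real LMS reference CSV (`indicator, sex, axis_value, L, M, S`). Neither
the external dataset nor clinical calibrations are required by — or included
in — this package or its tests.

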