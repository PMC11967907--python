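# stillbirth-trends

Trend testing and demographic decomposition for national stillbirth
surveillance built on aggregated registry tables.

## The problem

Stillbirth rates in Europe have stalled — or risen — in several countries
over the last decade, while two demographic risk factors moved in opposite
directions: mothers have become older (stillbirth risk is J-shaped in
maternal age, rising steeply after 34) and multiple births (≈3× the
singleton risk) have declined in most countries. Surveillance teams working
with aggregated counts — stillbirths and live births per country, year and
stratum (maternal-age band or multiplicity), never individual records and
never fully cross-tabulated — need to answer two questions:

1. **Is a national rate trending, breaking, or spiking?**
2. **How much of a rate change (over time, or relative to other countries)
   is explained by population composition rather than by within-stratum
   risk?**

This package implements the full analytical battery for those questions,
plus the table repair that registry data requires and a synthetic registry
generator with exact ground truth, so the whole pipeline is testable
without confidential data.

## Methods at the core

* **Rates.** r = 1000 · SB / (SB + LB), stillbirths per 1000 *total* births.
* **Table repair.** Births with unknown stratum are redistributed
  proportionally over the known strata (separately for stillbirths and live
  births, conserving totals exactly); disclosure-suppressed cells ("< k")
  are imputed with a seeded uniform draw over {0, …, k−1}.
* **Mann–Kendall trend test** with tie-corrected Var(S) and the Hamed–Rao
  autocorrelation correction (rank-based variance inflation, significant
  lags only, continuity-corrected normal p-value).
* **Segmented regression.** A score-type test of an added hinge covariate,
  maximised over a grid of candidate knots with a Davies-bound adjusted
  p-value, decides between a single OLS slope and a continuous one-knot
  broken line (knot by profile least squares).
* **Robust anomaly detection.** For designated years (e.g. 2020/2021) a
  Theil–Sen trend is fitted to all *other* years and the target's residual
  is standardized by a calibrated robust scale built on 1.4826·MAD;
  `robust_z > 2` flags an unusually high year (one-sided).
* **Kitagawa decomposition.** For populations A and B with stratum shares
  C_i and stratum rates M_i,

  Δ = Σᵢ (C_iB − C_iA)·(M_iB + M_iA)/2 + Σᵢ (M_iB − M_iA)·(C_iB + C_iA)/2,

  an exact split of the crude-rate difference into a **composition
  effect** (counterfactual change from stratum shares alone) and a **rate
  effect** (within-stratum rates alone). Applied over time within a
  country and against a birth-weighted pooled multi-country reference.

## Worked example

`examples/03_decomposition.py` builds a country whose mothers age while
within-age risks improve, then decomposes the 2010→2021 rate change:

```
rate 2010: 3.490  rate 2021: 3.252 per 1000
total change       -0.238 per 1000
  composition part +0.242  (aging of mothers alone)
  rate part        -0.479  (within-age risk change alone)
stratum  composition    rate
  25-34      -0.0795 -0.1605
    35+       0.6760 -0.3440
    <25      -0.3550  0.0250
```

Reading: the national rate fell by 0.24 per 1000, but the shift toward
advanced maternal age alone would have *raised* it by 0.24; improving
within-age risks (−0.48) more than offset the demographic headwind. The
two parts add to the total exactly, overall and stratum by stratum.

The other examples cover table repair and rate series
(`01_repair_and_rates.py`), the trend battery — MK test, breakpoint
detection, anomaly flags (`02_trend_battery.py`) — and the full
24-country pipeline (`04_full_pipeline.py`).

A thin CLI wraps the same pipeline:

```bash
stillbirth-trends simulate --seed 5 --out world.csv
stillbirth-trends run --input world.csv --axis both --seed 5 --out report/
```

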