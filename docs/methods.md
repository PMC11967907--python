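# Methods

This note documents the statistical procedures, their assumptions, the
parameters that matter, the synthetic-data design, and the numerical and
design choices made where the recipe was genuinely open.

## Data model

The unit of analysis is an aggregated count cell: (country, year, axis,
stratum) → (stillbirths, live births). Two stratification axes exist —
maternal-age bands and multiplicity — released as *separate marginal
tables*; registries do not release the age × multiplicity cross-table, so
all analyses treat the axes separately. Default age bands are `<20, 20-24,
25-29, 30-34, 35-39, 40+` (closed-open on completed years) but every
routine treats stratum labels as opaque, so any banding works. Counts may
be fractional after repair. The stillbirth rate is always per 1000 *total*
births (stillbirths + live births).

Per-country metadata carries two flags: `first_year` (series may begin
after the nominal study start; all routines use each country's native
span) and `includes_top` (stillbirth counts that cannot exclude
terminations of pregnancy — an interpretation caveat only; no numerical
adjustment is made or attempted).

## Table repair

**Unknown strata.** Unknown-stratum counts are redistributed
proportionally over known strata, separately for stillbirths and live
births within each (country, year, axis). Each known cell is multiplied by
(1 + unknown/known-total), which conserves group totals to machine
precision and preserves known-stratum proportions exactly. Fractional
results are kept — rounding would break conservation and bias small
strata. The implicit assumption is missing-at-random within the group; a
positive unknown count with an all-zero known margin is unresolvable and
raises an error rather than guessing.

**Suppressed cells.** A cell reported as "< k" is stored as a placeholder
count 0 with `suppressed_bound = k` (keeping the CSV schema numeric and
round-trippable) and imputed with a uniform draw over {0, …, k−1} from a
seeded generator. Uniform is the maximum-entropy choice given only the
bound; the mandatory seed makes repair reproducible. The bound is a
required input — there is no safe default for a disclosure rule.

## Mann–Kendall test with autocorrelation correction

S = Σ_{i<j} sign(x_j − x_i); Var(S) uses the standard tie correction
n(n−1)(2n+5)/18 − Σ_t t(t−1)(2t+5)/18. The z statistic applies the ±1
continuity correction; p is two-sided normal. A constant series returns
S = 0, p = 1 (no trend, not an error). n ≥ 4 required.

Serial dependence inflates the variance of S. The correction multiplies
Var(S) by the Hamed–Rao factor

n/n* = 1 + 2/(n(n−1)(n−2)) · Σ_i (n−i)(n−i−1)(n−i−2) ρ_i,

with ρ_i the lag-i autocorrelation of the *ranks* of the Sen-detrended
series, summing only lags whose |ρ_i| exceeds the two-sided 10% white-noise
bound z₀.₉₅/√n. Two numerical decisions matter on the short (n ≈ 12)
series this package targets:

* **The factor is floored at 1.** The correction exists to guard against
  positive serial dependence; on short series, spuriously "significant"
  negative rank autocorrelations otherwise shrink Var(S) below its iid
  value and roughly double the test's size (empirically ~0.09 at nominal
  0.05, n = 12). With the floor the white-noise size is 0.037–0.049.
* **Screening at 10%** rather than a stricter level: the white-noise bound
  1.64/√12 ≈ 0.47 is already severe at n = 12; stricter screening makes the
  correction essentially never fire, defeating its purpose under genuine
  AR(1) dependence.

`n_eff_ratio` in the result reports the applied factor (1 = no
correction).

## Linear and segmented trend fits

The headline annual change is an OLS slope (per 1000 per year) with 95%
mean-prediction intervals (t quantiles, df = n − parameters).

A single slope change is tested with a score-type statistic: for each
candidate knot ψ on a grid, the hinge covariate (x − ψ)₊ is projected
orthogonal to [1, x] and correlated with the linear-fit residuals, giving
a t-like process Z(ψ). The decision statistic is M = max|Z(ψ)|; because ψ
is not identified under the null, the p-value uses the Davies upper bound

p ≤ 2·P(t_{n−3} > M) + V·exp(−M²/2)/√(8π),

where V is the total variation of Z over the grid. The bound is
conservative by construction; simulated pure-line data yields a segmented
classification in ~2.5% of replicates at α = 0.05. A perfect straight line
(zero residual variance) short-circuits to p = 1.

If p < α the continuous one-knot broken line y = β₀ + β₁x + β₂(x − ψ)₊ is
fitted by profile least squares: grid search at 0.1-year resolution
between the min_segment-th and (n − min_segment)-th observations
(min_segment = 3 by default, so each segment keeps ≥ 3 points), refined by
bounded scalar minimisation between the neighbouring grid points. Reported
slopes are (β₁, β₁ + β₂). At most one breakpoint is considered.

## Robust anomaly detection for designated years

To ask whether designated years (defaults 2020 and 2021) are unusually
high, a Theil–Sen line (median of pairwise slopes; intercept
median(y) − slope·median(x)) is fitted to all *non-target* years — the
leave-target-out design prevents an anomalous year from dragging the
reference trend toward itself. Each target year's residual is divided by a
robust scale and flagged one-sidedly at robust_z > 2 (threshold
configurable).

The default (`calibrated=True`) scale is 1.4826·MAD of the reference
residuals times three finite-sample factors:

* √(1 + 1/n + (x₀ − x̄)²/Sxx) — the out-of-sample prediction factor; target
  years sit at the end of the span, where the trend line is extrapolated
  and its error is dominated by slope uncertainty;
* √(n/(n−2)) — residual degrees of freedom of the two-parameter fit;
* n/(n − 0.8) — the Croux–Rousseeuw small-sample MAD consistency factor.

Without them the z > 2 flag fires on ~12–16% of null series at n = 12
(10 reference years); with them the null rate is ~6%, close to the
nominal tail. `calibrated=False` gives the plain residual/(1.4826·MAD)
statistic for comparability with the simpler recipe. A zero MAD with a
nonzero residual reports ±∞ as a sentinel. At least 5 reference years are
required.

## Kitagawa decomposition

For two populations with shares C_i and stratum rates M_i per 1000,

Δ = Σᵢ (C_iB − C_iA)(M_iB + M_iA)/2 + Σᵢ (M_iB − M_iA)(C_iB + C_iA)/2.

The identity is exact, overall and per stratum; the implementation checks
shares sum to 1 (tolerance 10⁻⁶ on input, with components reported to
better than 10⁻⁹ additivity). Conventions:

* A stratum present on one side only enters with share 0 on the absent
  side and the rate copied from the present side — it then contributes
  only through the composition channel, avoiding an undefined 0/0 rate
  while preserving exact additivity.
* A stratum with births but no stillbirths has rate 0; no smoothing or
  continuity corrections anywhere.
* Over-time comparisons default to each country's first available year →
  2021; both years are run-time arguments (e.g. for an early-window
  sensitivity run such as 2010→2015).
* The multi-country reference is built by summing stratum counts across
  countries *before* computing shares and rates (birth-weighted pooling,
  not the mean of national rates), and includes the index country by
  default (`exclude_self` exists but is off). Positive Δ means the
  reference exceeds the country; reports also carry the negation
  (country minus average) since "above/below average" is the natural
  reading.
* Age and multiplicity are decomposed separately, never jointly — the
  cross-table is not available in real releases.

## Synthetic registry generator

The generator emulates the structure of a European multi-country registry
extract so that every stage has a ground-truth oracle:

* 24 countries, annual totals log-uniform in 4·10³–8·10⁵ births,
  interpolated linearly over 2010–2021 with mild growth/decline;
* age-share vectors interpolating from younger toward older structures
  (three templates spanning the observed range of maternal-age profiles);
* multiple-birth shares starting in 2.4–5.4% and mostly declining;
* J-shaped age-specific stillbirth probabilities (≈4.2, 3.2, 2.8, 3.0,
  4.5, 7.5 per 1000 at span start), with the 35+ bands improving the most
  by span end and the youngest band worsening slightly — national crude
  rates land in roughly 2–5.5 per 1000;
* relative risk 3 for multiple births (configurable), optional positive
  age–multiplicity coupling (off by default: analyses use marginals);
* label missingness (default 2% in the preset), suppression of stillbirth
  cells below a bound (default 3), four countries with late series starts,
  optional per-country multiplicative rate shocks for pandemic scenarios.

Births are multinomial over the age × multiplicity cross-table and
stillbirths binomial per cell; the cross-table is then marginalised into
the two released axis tables, whose totals therefore agree exactly before
missingness injection. `sampling=False` emits expected (fractional)
counts — the infinite-population limit used as a construction oracle. The
ground-truth object carries the exact expected national rates, the
designed decomposition components between first and last year (computed
from the expected populations), and the shock map.

What the generator does **not** emulate: real fertility dynamics
(migration, parity, cohort effects), gestational-age composition,
reporting-threshold differences between countries, and correlated
measurement error. Passing tests therefore demonstrate the *statistical
machinery* — conservation, calibration, unbiased recovery of designed
effects — not epidemiological validity of any particular country estimate.

## Problem sizes in the test suite

The statistical acceptance checks run at the scale the procedures are
designed for: series length 12; 2000 replicates for test-size checks; 200
replicates at 100 000 births/year for decomposition recovery; 100 seeds at
500 000 births/year for anomaly power; 1000 randomized tables for the
exact-conservation and exact-additivity properties. The full suite runs in
about a minute on one CPU.

## Known limitations

* The Davies bound is an upper bound: the breakpoint test is conservative,
  trading a little power for guaranteed size control on short series.
* The MK correction can only inflate variance; genuinely negatively
  autocorrelated series are tested slightly conservatively.
* Anomaly detection assumes a locally linear reference trend; a series
  with strong curvature can mis-assign trend misfit to the target years.
* The decomposition is purely arithmetical: components carry no
  uncertainty intervals, and a composition effect is a counterfactual
  under the strong assumption that stratum rates would not react to a
  changed composition.
* Only one breakpoint is modelled; multi-break series will report the
  dominant change.
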