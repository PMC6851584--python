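# Methods

This note records the models, conventions and numerical choices behind
`winterclim`, and what the synthetic test bed does and does not establish.

## Data model and units

Daily records carry tmin/tmax (°C), precipitation (mm liquid equivalent),
snowfall and snow depth (mm), with NaN for missing. Input CSVs declare
column names, unit scale (e.g. tenths) and missing sentinel (default
−9999) through a dialect; everything downstream sees one internal
convention. Rows with tmin > tmax are quarantined (both temperatures set
missing) rather than swapped — swapping would fabricate data. Duplicate
dates are reported and downstream operations refuse the series; the
package never guesses which duplicate report is right. The calendar is the
real proleptic Gregorian calendar: 29 February is an ordinary winter day,
so winters have 212 or 213 days.

## Winter definition and indicator counting

Winter is 1 November–31 May — the dormant season, deliberately wider than
meteorological winter so early/late frost and snow events are counted — and
is labeled by its ending calendar year (Nov 2000–May 2001 → 2001); that
label is the trend time axis. All indicator inequalities are strict, so a
day with tmax exactly 0 °C is neither a thaw day nor an ice day. The
windowed snowmaking counts use strictly-before 25 December and
through-28-February-inclusive (29 February excluded); both cutoff dates are
configurable because the original boundary conventions are not knowable.

A day is *undefined* for an indicator when any required input is missing
(tmax for thaw/ice; tmin for the cold thresholds; modeled SWE for snow
status; both the rain component and SWE for rain-on-snow; tmax and SWE for
the compound indicators). Undefined days leave both the count and that
indicator's valid-day denominator, so a winter with no usable tmin reports
a missing frost count, never zero. Counts are raw day counts — rescaling to
a standard winter length would distort Sen slopes. A winter failing
completeness QC for a variable has all indicators needing that variable
masked; the others survive.

## Completeness screening and snow gap-filling

A winter is valid for temperature (precipitation) when its missing
fraction over the full 212/213-day calendar window is ≤ 10 %; a station
passes when at least `min_valid_winters` (default 90) winters are valid
for temperature and/or precipitation. Both thresholds are configuration,
not constants: 10 % is a common climatological completeness rule, and the
90-winter default operationalizes "about a century of usable record" while
tolerating a handful of bad winters. Winters truncated at the record edges
count uncovered days as missing.

Snow records from cooperative observers have two well-known pathologies:
snowfall left blank on days with no precipitation, and snow depth left
blank instead of recorded as zero when no snow is on the ground. Gap
filling repairs exactly these, conservatively: (a) missing snowfall
becomes 0 when precipitation was 0, or when precipitation is unreported
but tmax > 2 °C (any precipitation would have been rain); (b) interior
depth gaps of ≤ k days (default 7) flanked by observed zeros become 0;
(c) such gaps flanked by positive observations are linearly interpolated.
Mixed flanks (one zero, one positive) are left missing — no stated rule
covers them and inventing a snowmelt date would bias snow-cover
indicators. Gap-filling never alters an observed value, flags every fill
as imputed, and is idempotent. Filled depth serves only snow-model
validation; indicator snow status always comes from modeled SWE.

## Degree-day snow model

State: frozen pack (SWE, mm) plus a small retained-liquid store. Each day,
driven by tavg = (tmin + tmax)/2:

1. precipitation splits linearly between all-snow at/below t_snow = 0 °C
   and all-rain at/above t_rain = 2 °C; snow adds to the pack;
2. melt = ddf · max(0, tavg − t_melt), capped at the pack, with
   ddf = 2.5 mm·°C⁻¹·d⁻¹ and t_melt = 0 °C;
3. melt plus rain enters the liquid store up to retain_frac = 0.05 of the
   pack; the excess is runoff;
4. refreeze = min(store, refreeze_factor · max(0, t_melt − tavg)) returns
   liquid to the pack (refreeze_factor = 1 mm·°C⁻¹·d⁻¹).

Mass is conserved exactly at every step (Δ(swe + liquid) = snow + rain −
runoff; verified to < 10⁻⁹ mm over 10⁴ randomized steps) and SWE is
non-negative by construction. The parameter defaults are central
literature values for daily temperature-index models; a grid-search
calibration against observed snow presence (fraction of days agreeing on
depth > 0 vs SWE > 0, ties broken toward the defaults) is provided for
records with usable depth. The pack is re-initialized empty every
1 August, so winters are independent of record start and no phantom pack
survives a snow-free summer. Days with missing forcing carry the state
forward and are flagged undefined; "snow covered" means SWE strictly
above a trace threshold whose default is 0 mm.

Deliberately out of scope: energy-balance physics, sublimation, and any
depth/density conversion (SWE is used directly).

## Trend statistics

Mann-Kendall S = Σ_{i<j} sign(x_j − x_i) with tie-corrected variance
[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18, continuity-corrected
z = (S ∓ 1)/√var(S) (z = 0 when S = 0), and a two-sided normal p value.
The normal approximation is used throughout — series here have ~100
points, where exact small-sample tables are irrelevant; n ≥ 4 non-missing
values are required, and missing winters drop out pairwise *on the true
year axis*, so slopes keep their days-per-decade scaling across gaps.
Sen's slope is the median of all pairwise slopes, ×10 for days/decade.
The regional test sums S and var(S) across station blocks (no cross-block
covariance assumed) and pools all within-block pairwise slopes into one
median — the pooled convention, chosen over a median-of-block-medians
because it is the standard in regional-Kendall implementations and
reduces exactly to the site test for a single block. Subregion boundaries
put −87° in central and −78° in east (a declared tie rule; the boundary
assignment convention is otherwise arbitrary).

The autocorrelation screen computes sample acf to lag 30 (one climate
normal) and flags any coefficient outside ±1.96/√n. The flag is advisory:
it is reported alongside the trend, but no prewhitening is applied — the
procedure this package implements checks independence and proceeds when
the screen is clean, and silently prewhitening would change the estimand.
No multiple-testing correction is applied across the twelve indicators,
matching the procedure's design; users comparing many indicators should
bear that in mind.

## Synthetic weather generator

The generator emulates a mid-latitude station: daily mean temperature
follows mean_temp − amplitude · cos(2π(t − coldest_doy)/365.25) evaluated
on real calendar dates (the 365.25-day period keeps the coldest day
aligned across leap years), plus AR(1) noise shared by tmin and tmax —
perfectly correlated deviations preserve tmin ≤ tmax without rejection
sampling, which is adequate for testing threshold counters. `noise_sd` is
the *marginal* (stationary) SD of that noise; innovations are scaled by
√(1 − ar1²). tmin/tmax sit ± diurnal_range/2 around the mean, each with
its own linear trend in °C/decade. Precipitation is Bernoulli(p_wet)
occurrence with Gamma(shape, scale) amounts, independent of temperature
except through phase partitioning; recorded snowfall is the snow fraction
of the amount. Output is quantized to 0.1 units — the reporting resolution
of real station records — which also makes generator-written CSVs
round-trip bit-identically through the reader.

Defaults (100 years from 1916, mean 6 °C, amplitude 15 °C, coldest day
20 January, diurnal range 10 °C, noise SD 4 °C, ar1 0.7, p_wet 0.35,
Gamma(0.75, 9 mm)) describe a cold-temperate station of the northeastern
North American forest belt with ~3 mm/day mean precipitation; they were
fixed once from climatological plausibility. Missingness is injected in
geometric-length blocks (mean 3 days) to a target fraction, exactly
truncated; the `unreported_zero_snow` flag blanks every true-zero depth
day, the limiting case of the observer pathology described above.

To inject a *Frost-Day* trend stated in days/decade, the equivalent tmin
trend is derived analytically: the expected frost count per winter under
a uniform tmin offset δ is F(δ) = Σ_d Φ((0 − μ_d − δ)/σ) over the winter
window (μ_d the seasonal-mean tmin, σ the marginal noise SD), and the
trend T solves the secant condition F(T · n_decades) − F(0) =
target · n_decades. The secant, rather than the tangent at δ = 0, absorbs
the curvature of F over a century.

What the generator does *not* emulate: spatial correlation between
stations, temperature–precipitation occurrence coupling, teleconnection
modes, heavy-tailed temperature extremes, inhomogeneities (station moves,
instrument changes). Passing tests therefore demonstrate that the
pipeline's mechanics are correct under known structure — not that real
archives are homogeneous or that the statistical assumptions hold for any
particular real station.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 500 random short
series (n ≤ 12, with ties) for oracle equivalence; 2000 replicates of
n = 100 for the type-I error rate; 200 replicates (plus 200 × 5-station
regional replicates) of 100-winter records for trend recovery; 10⁴
randomized steps for snow mass balance; 1000 synthetic winters for the
count identities; and 200 seeds of the nine-station subregion experiment.
The trend-recovery and subregion experiments evaluate Frost Days, which
need only the temperature path; the snow path is exercised by its own
dedicated checks and by the end-to-end pipeline tests.

## Known limitations

- The completeness thresholds and snow-model parameters are scientific
  defaults, not values fitted to any particular archive; real studies
  should calibrate the snow model against local depth records.
- The regional test assumes independence between stations; in dense
  networks spatial correlation inflates the regional z.
- Indicator counts from partially missing winters are raw counts over the
  valid days; two winters with different coverage are compared as-is once
  both pass QC.
- The CLI reads whole stations into memory; century-scale daily records
  are small, so no chunking is implemented.
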