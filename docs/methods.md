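# Methods

## Scope and data model

`heatband` implements a climate-to-health-indicator chain: bias correction of
gridded daily ensemble fields, daily maximum apparent temperature, annual
threshold-exceedance counts, and trend characterization. All gridded data are
xarray objects on dims `(time, lat, lon)` with integer day index plus
`year`, `month`, `dayofyear` auxiliary coordinates on a **365-day no-leap
calendar** — the standard climate-model convention; it makes every year the
same length so annual counts are directly comparable, at the cost of not
representing real leap days. Latitudes ascend south→north, longitudes lie in
[−180, 180), year ranges are inclusive on both ends. Files are NetCDF3
classic (xarray scipy backend), which caps integers at 32 bits; counts and
year coordinates are stored as int32.

## Synthetic ensemble generator

The generator emulates the statistical surface of a downscaled regional
ensemble, not any model's dynamics. Per member, daily maximum temperature is

    t_base(lat) + A·cos(2π(doy − peak)/365) + trend(lat,lon)·elapsed/100
    + bias_t[month] + η_t

with `peak` in mid-January south of the equator and mid-July north of it,
`elapsed` the fractional years since the record start (so the trend accrues
within years), and η an optional AR(1) process (default white). Relative
humidity is `(rh_base + rh_trend·elapsed/100)·bias_rh[month] + η_rh`, clipped
to [0, 100] %; wind is `max(wind_mean + η_w, 0)` with no bias and no trend
(only temperature and humidity are bias-corrected downstream, so only they
carry biases). Members get independent child RNGs spawned from one seed:
the set is reproducible and members are mutually independent.

Default conditions: 6 members, 1961–2100, a 10×10 grid at 6°×4° spacing
covering an Africa-like domain, seasonal amplitude 6 °C, warming
3 °C/century, day-to-day noise 1 °C (temperature) and 5 % (humidity), mean
wind 3 m/s. Baselines `t_base` and `rh_base` default to smooth
latitude-dependent profiles (warm humid equator, cooler drier subtropics);
all three spatial fields accept scalars, latitude profiles or full grids.

The reference climatology is the generator's own bias-free, noise-free
monthly means over the baseline period — the known truth the bias correction
should restore, which is what makes correction exactness testable.

What the generator does **not** emulate: topography, weather systems and
spatial noise correlation, humidity–temperature anticorrelation, non-uniform
warming within the year, and extreme-value tail behaviour. Passing tests
therefore demonstrate correctness of the *computational chain* — correction
algebra, counting, trend statistics — not fidelity of any real projection.

## Bias correction

Mean matching per calendar month (12 values per cell per variable): additive
for maximum temperature, multiplicative for relative humidity, derived from
baseline-period (default 1961–1990) climatologies and applied across the full
record. Design points:

* **Monthly granularity, no smoothing across month edges.** Corrections
  change stepwise at month boundaries; day-of-year interpolation was
  deliberately not added, keeping the correction identical to its definition
  and the baseline round-trip exact.
* **Regrid first, then correct.** When model and reference grids differ, the
  model is bilinearly interpolated (`xarray.interp`) to the reference grid
  before climatologies are formed; cells outside the source hull are missing.
* **Numerical exactness.** Climatologies accumulate in float64 even when
  daily fields are stored float32, so that for additive corrections
  `clim(apply(field)) == ref` to ~1e−12 (the algebraic identity
  mean(x + c) = mean(x) + c survives floating point at this tolerance).
  For multiplicative corrections the identity holds wherever no clipping
  occurred; the clipped fraction is logged as a QC metric.
* Zero model climatology makes a multiplicative factor undefined: those
  month-cells are flagged missing, and affected days become missing with a
  logged warning rather than infinities.
* No quantile mapping or variance scaling: the method is mean matching only,
  so only the monthly-mean bias is removed — variance and tail biases remain.

## Apparent temperature

`AT = Ta + 0.33·e − 0.70·ws − 4.00` (°C, hPa, m/s), the non-radiation
Australian BoM index. Vapour pressure comes from relative humidity via the
Magnus form `e_s = 6.105·exp(17.27·Ta/(237.7 + Ta))`, the formulation
published alongside this index; the three constants are named once in
`apparent.py`. Daily maximum AT is formed from same-day daily fields with
`e` evaluated at the daily maximum temperature. Upstream model output rarely
states whether daily humidity is a daily mean or Tmax-coincident; evaluating
at Tmax is a documented convention of this package (it maximizes AT for the
given daily fields), not a physical claim. Negative AT values are retained.
Temperatures outside (−60, 60) °C are rejected as implausible.

## Hot-day counting

Thresholds are inclusive on the left (≥ 27, 32, 39, 51 °C), which resolves
the touching printed band ranges ("27–32", "32–39") in favour of the
inequality definitions; band upper edges are exclusive, and the top band is
read as ≥ 51 °C. Counts use calendar years. A year with any missing or
absent day at any cell is excluded entirely (with a warning) rather than
rescaled — the default eligibility is 100 % completeness. Conservation
(`Hda1 + Hda2 = 365`, `ΣBands = Hda2`) and nesting
(`Hda2 ≥ Hda3 ≥ Hda4 ≥ Hda5`) are asserted for every cell-year on every
call, so a violation is an immediate hard failure, not a silent bias.
Ensemble aggregation averages per-member time-slice means (mean of member
means), never pooled daily data. Consecutive-day (heat-wave) metrics and any
health dose-response quantification are out of scope.

## Trends

* **Smoothing:** centered unweighted 11-year moving average; no output where
  the window is incomplete, so 1961–2100 input yields centers 1966–2095.
* **Average rate:** end-minus-start of the smoothed series divided by the
  span of center years. Two denominator conventions are exposed:
  `inclusive` (130 for centers 1966–2095) — the default, matching the
  convention of counting both endpoint years — and `difference` (129), which
  recovers the generating slope exactly on linear input. The choice shifts
  rates by under 1 %; it is a flag because readers of rate maps should know
  which was used.
* **Ensemble envelope:** per-year 10th/50th/90th percentiles across members
  with linear interpolation between order statistics (fixed because six
  members make the outer percentiles interpolation-sensitive); the envelope
  ordering p10 ≤ median ≤ p90 holds by construction.
* **Significance:** the trend statistic is the OLS slope against year —
  chosen for transparency and closed-form oracles. The null is a value
  bootstrap: resample the series values with replacement (destroying order),
  recompute the slope, repeat (default 1000×), and compare one-sided
  (increasing); significance at level L requires the observed slope to
  strictly exceed the L-th percentile of the null slopes, so ties count
  against rejection. A two-sided variant and a moving-block bootstrap
  (`block_length`) are available. The iid value bootstrap ignores the strong
  autocorrelation that 11-year smoothing induces and is therefore
  **anti-conservative on smoothed series** — on smoothed stationary noise it
  rejects far above the nominal rate. It is nevertheless the default because
  it is the literal method being reproduced; calibration claims (type-I error
  ≈ nominal) are made, and tested, on raw iid series only.
* **Trend maps** apply smoothing → rate → test cell-wise to the
  ensemble-median series. Cells whose smoothed series is constant (already
  365 days/year, or never above threshold) admit no trend under value
  resampling and are flagged `−1` ("no trend possible") — distinct from
  "tested, not significant". Each cell draws an independent child RNG from
  the map seed, so results are independent of traversal order. No
  field-significance or multiple-testing correction is applied across cells;
  flags are per-cell marginal statements.

## Pipeline and reproducibility

`run_pipeline` chains synth → bias-correct → ATmax → counts → slices/changes
→ trends (stages selectable), persisting every product as NetCDF and writing
a manifest with the configuration hash (covering all convention flags), the
seed, the package version and a SHA-256 checksum of each output variable's
raw bytes. Identical config + seed gives byte-identical variables; this is
tested. City series are extracted by nearest cell with ties broken toward
the lower index; out-of-bounds points are reported and skipped, never fatal.

## Problem sizes

The test suite and the acceptance script run on deliberately small problems —
grids of 4–100 cells, 15–140 years, ensembles of 1–6 members — chosen so the
statistical checks (bootstrap calibration at 500 replicates, trend-field
recovery over a 0–4 °C/century grid) still have the power they need while
the whole suite completes in seconds. All synthetic inputs are generated at
run time from seeds; no data files ship with the package.

## Known limitations

* Mean-matching correction only; no quantile mapping.
* The Magnus/AT constants are fixed; no alternative saturation formulas.
* The iid bootstrap default is anti-conservative on smoothed series (see
  above); use `block_length` for honest inference on smoothed data.
* 365-day calendar only; Gregorian daily data must be converted first.
* Bilinear regridding is not conservative (not flux-preserving), which is
  acceptable for state variables like temperature and humidity.
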