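# Methods

`aqhia` implements a pandemic-style emission-perturbation assessment as a
fully synthetic, reproducible pipeline: activity-scaled emission inventories,
paired-scenario gridded concentration fields, regulatory exposure metrics,
emission-versus-meteorology attribution, a satellite-style column comparison,
and a log-linear attributable-mortality health impact assessment.  This note
records the models, the parameters that matter, and the design choices made
where more than one defensible convention exists.

## The scenario model

Three emission scenarios are compared on one grid: **BAU** (business-as-usual
baseline-year emissions), **COV** (pandemic-reduced emissions), and **REB**
(rebounded emissions).  The assessment year runs April through the following
March, matching the period over which pandemic perturbations persisted.

The synthetic hourly ozone field is

    O3(t, x) = B + S·cos(2π(doy−196)/365) + D·cos(2π(hour−15)/24)
             + E(x)·(1 − r[month(t)]) + ε(t, x),   clipped at 0,

with background `B` (default 30 ppb), seasonal amplitude `S` (10 ppb, peaking
mid-July), diurnal amplitude `D` (8 ppb, peaking 15:00 local), a spatial
anthropogenic enhancement `E(x)` (mean 12 ppb; Gaussian urban plumes or
uniform), a monthly emission-reduction vector `r`, and stationary AR(1) noise
`ε` (marginal SD 5 ppb, lag-1 correlation 0.6).  Daily PM2.5 is a log-normal
meteorological draw (median 7 µg m⁻³, GSD 1.6) whose anthropogenic share
(default 50%) is scaled by `1 − r[month]`.

**Random-stream split.**  Meteorological noise is seeded by `(seed,
met_year)` only; the emission term is deterministic given the scenario.  Two
scenarios sharing a seed and meteorology year therefore differ *exactly* by
the emission term, which is what makes the paired-run attribution
decomposition exact — the synthetic analogue of chemistry-model runs driven
by identical meteorology.  The spatial autocorrelation of the meteorological
noise is not pinned down by any reference value, so it is exposed as a
parameter (`noise_spatial_corr`, default 0 = independent cells) rather than
fixed.

**Default reduction conditions.**  In the full pipeline the COV monthly
reduction is not set by hand: it is minus the national monthly fractional
change of the gas-phase precursors (mean of CO, NOx, VOC, SO2) of the scaled
inventory, so the emissions accounting drives the concentration scenarios.
With the default activity profiles this yields roughly 18–20% reductions in
April–June decaying to a few percent by the following spring, i.e. annual
precursor reductions near 10%, consistent with the scale of the 2020
perturbation.

## Emissions accounting

Inventories are tidy tables of mass per (species, sector, state, month) for
the six tracked species (CO, NOx, VOC, SO2, NH3, PM2.5).  Activity series
scale each (sector, month); sectors with no activity proxy — agricultural NH3
and fugitive dust — are declared unscaled and pass through, reflecting the
absence of activity data for them.  The default pandemic profiles anchor on a
40% April trough in gasoline activity, with shallower troughs and sector-
specific rebound rates elsewhere (diesel 20%, nonroad 30%, point 15%, oil and
gas 20% troughing in May, volatile chemical products 25% with a fast
rebound).  These are fixed study conditions, not tuning knobs.

Fractional changes are **mass-weighted aggregates**, `Σ scaled / Σ reference
− 1`, never averages of per-entry fractions — that is what a national total
change means, and it is why a single dominant state can pull the national
value outside the 20th–80th percentile band of state-level changes.
Percentiles interpolate linearly between closest ranks (the convention must
be stated because none is implied by the quantity itself).  Period means
weight months by reference mass; the quoted ±1σ spread is the SD of
per-state period fractions with states weighted equally (a flagged choice —
mass-weighting the states is arguably defensible too, but equal weighting is
the plainer reading of "state variability"; single-state tables get SD 0 by
convention).

## Exposure metrics

**MDA8** (daily maximum 8-hour average ozone) uses the long-standing
regulatory convention: all 24 start hours are candidates, windows run into
the next day, a window is valid with ≥ 6 of 8 present hourly values (mean
over the present values), and a day is valid with ≥ 13 valid windows.  The
newer variant restricting start hours to 7:00–23:00 is available via
`start_hours=(7, 23)`.  Window sums are computed by shifted adds in index
order, so the vectorized result is bit-identical to an explicit window scan —
the equivalence is asserted, not approximated, in the tests.

The annual ozone design metric is the 4th-highest MDA8; the health metric is
the annual mean MDA8 (for ozone) and the annual mean 24-h PM2.5.  Any
windowed mean with < 75% coverage is missing, never extrapolated.  Cells
with fewer valid days than the requested order statistic are missing with a
warning.

Population weighting is `Σ p·x / Σ p`; the quoted SD is population-weighted
by default and a plain cell SD is available (`sd_weights="uniform"`), since
either reading of "± SD" is plausible.  Monitor sites sample the nearest
cell center — a monitor sits inside one model cell; bilinear smoothing would
blur exactly the model-versus-point discrepancy being quantified.

**Attribution** uses the paired-scenario triple (met A, BAU), (met B, BAU),
(met B, COV) with the (met B, BAU) pivot:

    emission_effect = f(B,COV) − f(B,BAU),   met_effect = f(B,BAU) − f(A,BAU),

so `met + emission = total` telescopes exactly with zero interaction
residual.

The ozone-regime indicator is the formaldehyde-to-NO2 column ratio (FNR),
computed as the ratio of period means (not the mean of per-overpass ratios —
the two differ, and indicator thresholds are calibrated on period means).
Regime bounds are inclusive: FNR below the low bound is VOC-limited, within
the bounds transition, above NOx-limited.  Defaults (3.0, 4.5) with the Los
Angeles-style alternative (4.1, 5.0) available per call.

## Health impact assessment

Attributable deaths per cell follow the log-linear model

    deaths = P · BR · (1 − exp(−β·ΔX)),   β = ln(RR) / increment,

with population `P`, baseline annual all-cause mortality rate `BR`, and
`ΔX = max(0, X − TMREL)` the annual exposure above the no-excess-risk
threshold.  Defaults: ozone RR 1.02 (95% CI 1.01–1.04) per 10 ppb annual-mean
MDA8, TMREL 26.7 ppb; PM2.5 RR 1.06 (95% CI 1.04–1.08) per 10 µg m⁻³ annual
mean, TMREL 2.8 µg m⁻³ (long-term all-cause cohort coefficients).  At
`ΔX = increment` the attributable fraction is exactly `1 − 1/RR`; this
closed-form identity and the second-order Taylor bound on the linearized
model are pinned in the tests.

Design choices: β is the standard log-linear slope `ln(RR)/increment` (the
only dimensionally consistent reading of the relation between RR and β);
clamping at the TMREL happens **after** annual aggregation, not per day;
confidence intervals re-run the whole chain at the RR interval endpoints (no
Monte Carlo over population or baseline rates — matching how such totals are
usually quoted); cells with zero population contribute zero deaths and are
excluded from the per-100k rate surface.  Averted deaths are reported as the
BAU-minus-COV total and as an integer percent of the BAU total.

## Satellite-style comparison

Retrieval pixels carry a tropospheric vertical column, the original air-mass
factor (AMF), per-layer scattering weights, and the retrieval's a priori
profile.  For a like-for-like model comparison the AMF is recomputed with
the model profile, `AMF_m = Σ(sw·m)/Σ(m)` over tropospheric layers, and the
column re-derived holding the slant column fixed: `vcd' = vcd·AMF₀/AMF_m`.
Scattering-weight and shape-factor products reduce to the same formula.  Two
invariants pin the implementation: the implied slant column is preserved
exactly, and a model profile proportional to the a priori leaves the column
unchanged.  Vertical interpolation of model profiles to pixel layers, where
needed, must conserve partial columns; the synthetic scenes generate both on
a shared layering so no interpolation error enters the tests.

Default quality filters keep pixels with qa ≥ 0.75, cloud fraction ≤ 0.3
and solar zenith angle ≤ 70° — common L2 user-guide practice, config-exposed
since no single set of thresholds is canonical.

Source regions follow a dominance rule: a cell is urban / point /
oil-and-gas when that sector contributes at least 60% (inclusive) of its NOx
emissions, else "other"; with any threshold above 50% the label is unique.

**Orthogonal distance regression.**  Year-2 columns are regressed on year-1
columns assuming equal error variance on both axes, for which the exact
minimizer of summed squared perpendicular distances is the total-least-
squares line (the major axis of the 2×2 covariance).  The closed form is
implemented directly: the iterative ODRPACK solver converges only to ~2×10⁻⁷
relative on this problem, short of the 10⁻⁸ agreement the test oracle
demands, so it serves as an independent cross-check instead.  The slope CI
is a leave-one-out jackknife SE with a normal 95% interval — a stated
choice, since no canonical construction exists for this quantity; exact-fit
data yields a zero-width interval.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the methods care about:
diurnal/seasonal ozone cycles with autocorrelated meteorological noise,
log-normal PM2.5, clustered log-normal population normalized to a national
total, county-blocked mortality rates (rectangular county tiling, one
truncated-normal rate per county), pandemic-shaped activity dips, inventory
mass dominated by a few states, and retrieval pixels whose stored AMF is
self-consistent with their a priori profile.

They deliberately do **not** emulate: chemistry and transport (ozone responds
linearly to the enhancement reduction; real ozone production is nonlinear in
NOx, which is why VOC-limited urban cores can see ozone *increase* under NOx
cuts — the FNR diagnostics exist precisely to flag that regime), PM2.5
component speciation, spatially correlated emission errors, retrieval slant-
column fitting, or row anomalies.  Passing tests therefore demonstrate the
correctness of the accounting, metrics, attribution algebra, AMF handling and
mortality arithmetic — not the realism of any particular concentration
response.

## Numerical choices and problem sizes

Default grid 40×60 cells (a desk-scale stand-in for a ~12-km continental
grid), 365-day non-leap year in local standard time starting April 1, three
scenario field sets, 4,000 pixels per satellite scene.  The full pipeline
runs in well under a minute on one CPU; the test suite uses smaller grids
(6×8 to 10×15) and 20-seed ensembles for the stochastic recovery checks.
Ties in order statistics keep duplicates (the 4th-highest of five equal
values is that value); degenerate ODR inputs (all points identical) and
zero-reference emission groups raise errors rather than returning NaN.  All
generators are bit-reproducible given (seed, parameters); every file writer
has a reader that reproduces in-memory values exactly (CSV floats are
written at full precision and parsed with round-trip parsing).

## Known limitations

* Linear scenario response: no chemistry, no ozone-production nonlinearity,
  no aerosol thermodynamics.
* One pollutant-metric pairing per assessment (annual-mean MDA8, annual
  PM2.5); no age stratification, cause-specific rates, or nonlinear
  exposure-response curves.
* CI propagation ignores uncertainty in population, baseline rates and
  exposure fields; intervals reflect the RR interval only.
* County blocks are axis-aligned rectangles — the simplest structure that
  still exercises the county-to-grid mapping.
* The jackknife slope CI is asymptotic; very small samples (n < ~10) get
  optimistic intervals.
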