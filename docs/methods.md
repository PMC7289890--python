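# Methods

## Flux assembly

The half-hourly net ecosystem exchange (NEE, µmol CO₂ m⁻² s⁻¹, uptake
negative) is the sum of the turbulent flux through the measurement plane
and the storage change in the air column below the sensor. The turbulent
flux is ρ_air·mean(w′c′) over a 30-min block of high-frequency vertical
wind w (m s⁻¹) and CO₂ mixing ratio c (µmol mol⁻¹ dry air), with
**population (1/N) normalisation** of the covariance — a fixed, documented
convention, since the two normalisations differ by O(1/N) at N = 18,000.
Wind coordinates are aligned per block by **double rotation** (yaw into the
mean wind, pitch to zero the mean vertical velocity); blocks with zero mean
horizontal wind cannot be rotated and are flagged instead. The rotation
conserves the per-sample wind-vector magnitude.

The storage term uses the discrete single-height approach, which treats
the canopy air column as well mixed:

    Sc = ΔC·z / ((R·T_a/P_a)·Δt)

with ΔC the change of column-mean CO₂ **mixing ratio (µmol mol⁻¹)**
between consecutive half hours, z the measurement height (default 11 m),
R = 8.314 J mol⁻¹ K⁻¹, T_a in K, P_a in Pa and Δt = 1800 s. The mixing-ratio
unit for ΔC is the only dimensionally consistent choice for this
expression; the worked check (ΔC = 10 µmol mol⁻¹, z = 11 m, T_a = 300 K,
P_a = 101325 Pa) gives 2.4826 µmol m⁻² s⁻¹.

Spectral, WPL-density and sonic-temperature corrections are out of scope:
they belong to the instrument-specific preprocessing that precedes this
package's inputs.

## Quality control

**Despiking.** Each flux series is split into a smooth part — a centred
moving median over 49 half hours — and a residual part. Residuals more than
`z_threshold` (default 7) robust standard deviations from the local
residual median are spikes; the robust scale is 1.4826 × the moving MAD of
the residuals, so the threshold reads as Gaussian sigmas. Flagged records
become missing (later gap-filled, never interpolated), and the filter
iterates to a fixed point (default cap 10 passes), making it idempotent.
Windows with zero MAD flag nothing, so constant stretches are safe. On
default synthetic years the false-positive rate is ≈ 1.3% — the cost of a
filter sharp enough to catch 10-MAD spikes inside the noisy daytime regime.

**Nighttime definition.** R_g < 10 W m⁻² (configurable). At ~6.6° S this
yields a 45–55% nighttime fraction year-round.

**u\* filtering.** Nighttime records with weak turbulence under-measure the
true efflux. The moving point test estimates one threshold per season:
valid nighttime records are split into 6 air-temperature quantile classes,
each into 20 u\* quantile classes; a temperature class's threshold is the
mean u\* of the lowest u\* class whose mean NEE reaches 95% of the mean NEE
of all higher classes, and the season threshold is the median over
temperature classes, floored at 0.05 m s⁻¹. Class counts, the 95% ratio
and the floor are configurable; seasons with fewer than 200 valid nights
fall back to a configurable default (0.25 m s⁻¹) with a warning. Only
nighttime NEE is ever rejected; daytime records pass through untouched.

## Gap-filling (marginal distribution sampling)

For each missing NEE, in order: (i) with R_g, T_a and VPD known at the gap,
donors are valid fluxes within **50 W m⁻²** (capped at 20% of the gap's own
R_g), **2.5 °C** and **5 hPa** of the gap's drivers inside a ±7-day window;
(ii) with only R_g known, donors match radiation alone; (iii) with no
drivers, donors are records at the same clock time ±1 h on adjacent days.
If a window yields fewer than 2 donors (configurable) the search widens
along the ladder 7, 14, 28, 56, … days (1, 2, 4, … for the diurnal rule),
extended automatically until the whole series is reachable; if a
driver-matched search exhausts the ladder (possible at dawn, where the
20%-of-R_g cap is tight), the diurnal rule is the terminal fallback.
Filled values carry grades — A: full-driver ≤ 14 d; B: full-driver > 14 d
or radiation-only ≤ 14 d; C: otherwise — and observed values are returned
bit-identical. Meteorological drivers are themselves filled first by the
diurnal rule (variables missing > 20% fall back to the whole-series diurnal
climatology with a warning). The tolerances follow the method's customary
values; the ladder steps, donor minimum and grade boundaries are this
package's documented scheme. VPD is stored in kPa and the hPa tolerance is
converted at exactly one boundary (`MdsTolerances.vpd_tol_kpa`).

## Partitioning

Nighttime NEE is respiration by definition (photosynthesis off in the
dark), so the Lloyd–Taylor model

    R_eco(T_a) = R_ref · exp(E₀ · (1/(T_ref − T₀) − 1/(T_a − T₀)))

is fitted to nighttime data with T_ref = 15 °C and T₀ = −42.02 °C, both in
°C throughout (a guard rejects Kelvin-scale inputs). T₀ is configurable;
the value used here is the one adopted for the target site class rather
than the more common −46.02 °C. The temperature sensitivity E₀ (K) is
fitted together with R_ref on 15-day periods sliding by 5 days; periods
need ≥ 6 records spanning ≥ 5 °C, estimates outside 30–450 K or with
unusable covariance are discarded, and survivors combine by
inverse-variance weighting into one annual E₀. With E₀ fixed, R_ref is
re-estimated on 4-day windows by the closed-form origin regression
Σ(NEE·f)/Σ(f²) (f the fixed-shape response), floored at 0.05 µmol m⁻² s⁻¹
and linearly interpolated to every half hour — tracking slow changes in
substrate and canopy state.

The partition enforces NEE = R_eco − GPP **exactly at every record** with
GPP ≡ 0 at night. Consequently nighttime R_eco equals the (gap-filled)
nighttime NEE, which under noise can dip negative at a few records; these
are counted and reported rather than altered, because repairing them would
break either the identity or GPP's non-negativity. The smooth model
extrapolation is kept alongside as `reco_model`. Daytime records where the
modelled respiration falls below NEE would imply negative GPP; they are
clipped to GPP = 0 (respiration set to NEE) with a reported count.

The light response fit (rectangular hyperbola, scipy least squares) uses
data-driven starting values (slope −0.03, saturation from the most negative
NEE decile, offset from the low-light median), requires ≥ 30 daytime pairs
spanning ≥ 300 W m⁻², and raises on non-convergence or an implausible
saturation (|β| ≥ 100) — never silent defaults.

## Aggregation and statistics

Fluxes convert to carbon mass with 12.011 g mol⁻¹ (flux · Δt · 12.011e-6
g µmol⁻¹). Timestamps are end-of-interval local standard time, so the
record stamped 00:00 closes the previous day; daily sums group by interval
midpoint. Incomplete days are prorated (×48/n) with a logged count. The
season calendar defaults to wet Jan 15 – May 31, wet–dry Jun 1 – Jul 31,
dry Aug 1 – Nov 30, dry–wet Dec 1 – Jan 14 (wrapping the year end); any
non-overlapping full cover is accepted, and seasonal sums partition the
annual sum exactly. Carbon-use efficiency is NEP/GPP = (−NEE)/(−GPP) on
signed sums, reported to 2 decimals. Window means (midday 10:00–12:00,
nighttime 22:00–00:00 by default — both configurable, since conventions
for the nighttime window differ) select records whose interval midpoint
falls in the clock window. Confidence intervals are percentile bootstrap
(default 1,000 resamples, 95%), seeded and reproducible; significance
between seasons is read from CI overlap. Correlations are pairwise Pearson
r with two-sided p-values on pairwise-complete observations (≥ 10), with
zero-variance pairs flagged undefined.

## Synthetic site emulation

The generator emulates a semiarid SDTF tower site statistically, not
mechanistically: solar geometry at 6.58° S with clear-sky transmissivity
0.75 and daily cloud modulation; rain days drawn with monthly weights
peaking Feb–Apr and event sizes Gamma(0.8, 12), rescaled to the annual
target (default 513 mm); air temperature with mean 29 °C, diurnal
amplitude 5.5 °C peaking at 14:00, a small seasonal cycle peaking pre-wet
season, and rain-day cooling; humidity from a dewpoint anchored to the
daily minimum temperature, with VPD from the Magnus formula
es(T) = 0.6112·exp(17.62·T/(243.12 + T)) kPa; a vegetation-state
(greenness) index as a first-order filter of daily rainfall (time constant
30 days) rescaled into 0.16–0.42.

True respiration is the Lloyd–Taylor response (defaults R_ref = 1.7,
E₀ = 150 K) scaled by the vegetation index relative to the mid-range;
true GPP is the rectangular hyperbola (α = −0.05, β = −20) under the same
vegetation scaling, damped above a critical VPD and by an afternoon
stomatal-depression ramp (to 20% of morning uptake by 15:00) — the
mechanism that lets a sharp midday uptake peak coexist with moderate daily
totals, as observed at semiarid sites. GPP is exactly zero wherever
R_g = 0, and observed NEE = R_eco − GPP + Gaussian noise (default sd
1 µmol m⁻² s⁻¹, optional flux-proportional term). These defaults were set
once so a default year lands in the site-like regime — midday NEE near
−10 (wet) and −5 (dry) µmol m⁻² s⁻¹, nighttime near +2.5, annual NEE
within −250…−100 g C m⁻², ~500 mm rain — and are documented rather than
asserted; the two printed anchors (deep midday peak vs. small annual sum)
are mutually tight, and the defaults favour the annual band.

Degradation injects, with its own seed: random singleton gaps plus
contiguous blocks (default 10% of records in total), spikes of at least
`spike_magnitude` (default 10) series-MADs, and calm nights — a fraction of
nights re-drawn with u\* below the calm threshold (0.25 m s⁻¹), with all
sub-threshold nighttime NEE linearly suppressed toward zero, the artefact
u\*-filtering exists to remove. Every defect position is recorded in a
ledger so tests can assert exact recovery. The 10 Hz block generator draws
c as a linear response to w plus independent noise, so the population
covariance delivers the requested flux exactly.

What the generator does **not** emulate: storm-scale rainfall structure,
soil moisture memory beyond the greenness filter, advection, sensor drift,
heteroscedastic open-path noise in rain, or footprint variability. Passing
tests therefore demonstrate the correctness of the algorithms under a
plausible statistical regime, not instrument-level realism.

## Problem sizes and numerical choices

The parameter-recovery experiments run one synthetic year (17,520 records)
per seed; the test suite uses 100 seeds for the recovery medians, the
acceptance script 20 (its per-seed medians are stable well below the 15%
criterion). The covariance oracle comparison uses 1,000 random blocks of
2–64 samples. Optimisations use `scipy.optimize.curve_fit` with bounded
parameters for E₀ (R_ref ∈ [1e-6, 50], E₀ ∈ [1, 1000]); degenerate inputs
(isothermal periods, zero-variance windows, all-missing series) raise
explicit errors or are skipped with warnings, never silently defaulted.
All random draws flow through `numpy.random.Generator` with explicit
seeds; reruns are bit-identical.
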