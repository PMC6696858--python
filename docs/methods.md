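# Methods

This note documents the models, the numerical and design choices, and what
the synthetic-data generator does and does not emulate.

## Doubly labeled water kinetics

Single-pool, first-order washout for both tracers. For each isotope series
the elimination rate and zero-time intercept come from unweighted OLS of
ln(excess enrichment) on elapsed days; two-sided 95% CIs on k follow OLS
theory. Baseline is the mean of all pre-dose samples (a single baseline is
allowed). At least three post-dose samples above baseline are required; a
post-dose value at or below baseline is an error naming the sample.

**Enrichment units.** Inputs may be δ per-mil vs VSMOW (standard ratios
²H/¹H = 155.76 ppm, ¹⁸O/¹⁶O = 2005.20 ppm) or ppm atom-fraction excess.
Internally both are normalized to *tracer mol per mol of body water* (atom
fraction × atom sites per water: 2 for H, 1 for O). With that convention the
dilution space is N = (excess tracer mol in dose)/(zero-time excess) for
both isotopes. Dose excess moles interpolate the labeled-water molar mass
between the light and heavy species and subtract natural abundance.

**Pools to energy.** The dilution-space ratio N_d/N_o is flagged (never
fatal) outside a configurable window, default (1.015, 1.060). TBW is the
mean of N_d/1.041 and N_o/1.007. CO₂ production uses
rCO₂ = 0.4554·TBW·(1.007 k_o − 1.041 k_d) (fractionation in breath water
only); a non-positive rate is flagged, not raised. Conversion to L/day uses
a molar volume of 22.414 L/mol by default (22.26 also circulates in the DLW
literature; it is a constructor argument). TEE applies the food-quotient
Weir form 1.1·rCO₂ + 3.9·rCO₂/FQ with FQ restricted to [0.7, 1.0].

Open choice, documented: the zero-time-intercept (dose-dilution) pool-size
method is implemented; plateau-normalized variants exist but are not
recoverable from a washout series alone.

## Chamber calorimetry

VO₂/VCO₂ per minute from inlet/outlet volume fractions and the measured
outlet flow. The Haldane nitrogen balance (inlet flow =
outlet·N₂_out/N₂_in) is the default; without it, RER ≠ 1 biases VO₂ by
roughly (1−RER)·F_O₂in ≈ 3%. Minutes with negative VO₂ beyond rounding or
RER outside (0.6, 1.3) are flagged and clipped from energy integration, not
dropped silently. Energy uses classic Weir (3.941, 1.106; no urinary
nitrogen term) — the coefficients are a frozen dataclass, replaceable for
sensitivity analyses. BMR is the supine-window mean (≥ 30 min required)
times 1440. The chamber day is one 24-h record starting 09:00; clock times
are minutes from record start, and an entry whose end equals its start
spans the full day.

The protocol summary is the time-weighted MET mean over a gap-checked 24-h
timetable; predicted PAEE uses net METs (MET − 1) by default — gross METs
would count resting metabolism as activity — at 1 MET = 1 kcal/kg/h. Meal
energy assumes intake at 1.6 × BMR split over three meals.

The packaged timetable assigns compendium-informed MET values per activity
class (sleep 0.95, sedentary activities 1.0–1.3, housework 2.0–2.3, treadmill
slots blended with their 5-min rest at 2.7 and 3.8), averaging 1.375 METs
over the day. MET assignment is deliberately an input: different compendium
code choices are accommodated by editing one CSV.

## Device reduction

PAEE_dev = TEE_dev − BMR_dev − 0.1·TEE_dev, with three profile-driven
exceptions: devices whose stationary-day TEE already contains diet-induced
thermogenesis subtract only BMR; devices reporting PAEE directly bypass the
subtraction; devices publishing only a body-surface-area rule use
BSA·coefficient·24 with the Fujimoto surface area
(0.008883·wt^0.444·ht^0.663) by default and an age/sex coefficient table as
input. The DIT fraction 0.1 is a named constant. Valid days require wear
strictly above 600 min (so 600 is invalid), except days with sleep strictly
above 14 h; the free-living value is the mean over valid days with at least
10 required. Non-wear imputation is Σ MET·h·kg, net METs by default (the
25–35 kcal/day magnitudes typical of logged bathing/showering are only
reproduced by net METs); both modes are exposed.

## Agreement statistics

Dunnett many-to-one: pooled-variance t statistics for each device against
the criterion; family-wise two-sided p-values from the equicoordinate
distribution of k correlated t variates (correlation
λ_iλ_j, λ_i = √(n_i/(n_i+n_0)); 0.5 balanced), evaluated by seeded Monte
Carlo, 10⁵ draws by default (p-value resolution ≈ 0.002; the critical value
is the 1−α quantile of max|T|). The classical test assumes independent
groups, matching the named procedure; because validation studies measure
every device on the same participants, a repeated-measures variant
(one-sample t on within-subject differences, max-|t| adjustment over the
empirical difference-correlation matrix, df n−1) is provided behind
`paired=True` and is the appropriate default for end-to-end power at small
n. Devices identical to the criterion give zero-variance differences; their
paired t is defined as 0.

MAPE is the per-subject mean and SD of 100·|device−criterion|/criterion.
Correlations use Pearson (t, df n−2) and Spearman on average ranks (same t
approximation — adequate at n ≈ 19); the partial correlation controlling
body weight correlates OLS residuals with df n−3, returning (0, 1) when a
variable is collinear with the covariate. The modified Bland–Altman places
the *criterion* on the x-axis: bias = mean(device−criterion), limits of
agreement ±1.96 SD, and proportional bias as the criterion–difference
Pearson correlation; differences constant to rounding report prop_r = 0.
Significance is two-sided 0.05 throughout. All Monte-Carlo outputs are
bit-reproducible under a fixed seed.

## Synthetic-study generator

Truth is set at the TEE level and propagated: PAEE truth is 0.9·TEE − BMR,
so the pipeline identities are exercised by construction.

* **Cohort** (default n = 19): alternating sex, ages 21–50, sex-specific
  height and body-fat normals, BMI truncated to 18.5–25; BMR linear in
  fat-free mass (370 + 21.6·FFM, Cunningham-1991 coefficients); PAL normal
  (1.73, 0.21) truncated above 1.1; TEE = PAL·BMR. The implied population
  means (BMR ≈ 1.3 Mcal/day, free-living PAEE ≈ 730 kcal/day) sit where a
  normal-weight adult cohort should.
* **DLW series**: target rCO₂ by inverting the FQ-Weir equation from true
  TEE; TBW from fat-free mass at 73.2% hydration; dilution-space ratio drawn
  inside (1.021, 1.056); k_d from a water-turnover normal (0.09 ± 0.008/day)
  and k_o solved so the CO₂ equation holds exactly; dosing 0.06 g/kg ²H₂O
  (99.8 atom%) and 1.4 g/kg H₂¹⁸O (10 atom%); urine on days 0 (baseline),
  1, 2, 3, 8, 9, 13, 14, 15. Multiplicative log-normal noise (default sd
  1%) applies to the excess, with correlation 0.8 between the two isotopes
  of one urine sample: biological water-pool fluctuation and aliquot
  handling are shared across tracers, while analytic IRMS error is
  isotope-specific. The correlation matters: fully independent 1% noise
  inflates the k_o−k_d difference error to ≈5% of TEE, whereas the shared
  component cancels in the difference, leaving a median TEE error near 2% —
  the regime DLW precision studies report.
* **Chamber trace**: minute VO₂ = MET × resting VO₂ with resting VO₂
  anchored so a 1-MET minute's Weir energy equals true BMR/1440 (the supine
  window then extrapolates to BMR exactly); VCO₂ = 0.85·VO₂; outlet
  concentrations back-computed at fixed 250 L/min outlet flow with a
  consistent nitrogen balance, so Haldane gas exchange inverts the
  construction to machine precision.
* **Devices**: reported TEE (or PAEE) = mult·truth + add + N(0, sd) per day,
  day-to-day true TEE varying with 7% CV; wear = 1440 − non-wear bout
  (42 ± 13 min, logged at 1.8 METs) − sleep for off-wrist placements;
  invalid days at probability 0.007 (≈ the 25/3420 rate of the reference
  accounting table); DIT-inlined devices report a stationary baseline of
  BMR + 0.1·TEE so the no-DIT-subtraction rule reproduces truth exactly.

**What the generator does not emulate** — and hence what green tests do not
show about real data: multi-compartment isotope kinetics and isotope
sequestration, IRMS drift/memory, chamber analyzer lag and humidity
effects, posture- and activity-specific device error (bias here is linear
in truth), device epoch/step algorithms, and behavioural wear patterns
beyond a single daily non-wear bout. Parameter recovery on this generator
validates the estimator algebra and the statistics, not any device's
real-world accuracy.

## Problem sizes and tolerances

The shipped checks run: noiseless DLW recovery on a 19-participant cohort
(tolerance 0.5%, observed ≈ 1e-13); 200 noisy replicates (median TEE error
< 3%, observed ≈ 1.7–2.1%); chamber round-trip on the packaged timetable
(tolerance 1%, observed exact); identity suite on 10⁴ random inputs at
machine precision; Dunnett k=1 vs pooled t within 0.005 at 2×10⁵ draws;
family-wise error at k=11, n=19 over 2000 null replicates within
0.05 ± 0.01; and a 19-participant end-to-end study where −30%-biased
devices must be flagged with negative proportional-bias correlations and
unbiased devices must not. These sizes keep the whole suite in the
tens-of-seconds range on one CPU while leaving the Monte-Carlo error well
inside each tolerance.
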