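# Methods

## Standardized indices

**SPEI.** The drought indicator is built from the monthly climatic water
balance P − PET (precipitation minus potential evapotranspiration,
mm/month). Per grid cell the full monthly series is linearly detrended
**once** — on P − PET directly, not on P and PET separately, so the two
variables keep their physical consistency, and not per calendar month,
because the trend being removed (warming-driven evaporative demand) is a
property of the whole series. Residuals are mean-centered; the intercept
is irrelevant because standardization re-centers per ending month. The
residuals are accumulated over durations d = 1..14 consecutive months
(the longest season handled is 12 months plus two pre-planting months)
and dated by the **ending** month of the accumulation. For each
(duration, calendar ending month) the sample of one value per year is
standardized:

1. fit a three-parameter log-logistic distribution
   F(x) = [1 + (α/(x − γ))^β]⁻¹ by **unbiased probability weighted
   moments** (PWMs in (1 − F)^r form — the convention of the reference R
   implementation the field uses);
2. map each fitted probability to a standard-normal quantile
   (double-precision inverse CDF, clipped to ±4 to avoid infinities at
   extreme empirical probabilities).

At a 36-year sample the PWM fit is not always admissible: the log-logistic
family is right-skewed with a finite lower bound, so samples with negative
skew produce a non-finite or ≤ 1 shape estimate (Γ(1 − 1/β) is undefined
there — a numerical-validity guard beyond the textbook conditions) or a
location γ at/above the sample minimum. In all those cases the
implementation degrades gracefully to **Weibull plotting-position**
empirical standardization (probability rank/(n+1)), flagged per
(cell, duration, month) in the output cube (`method` = 1). With symmetric
Gaussian noise roughly half of all series take the fallback path; both
paths are strictly monotone in the input, so ranks — and hence class
frequencies at moderate thresholds — are essentially indistinguishable
between them at n = 36.

Accumulation windows that would extend before the first data month are
undefined (no partial windows), so for a 36-year record up to the first
two years of a (d, m) series can be missing; the fit then uses the
≥ 34 remaining years (minimum required: 30).

**SYI.** Yearly yields per cropping system follow the *identical*
detrend → fit → standardize path (the detrend removes technology and
management trends), with one implicit annual duration. Identical
processing is the point: it makes moisture and yield deviations
directly comparable and classifiable with the same boundaries.

**Classes.** Both indices are classified with the dry/low tail
upper-inclusive (x ≤ −2 extreme, −2 < x ≤ −1.5 severe, −1.5 < x ≤ −1
moderate), −1 < x < 1 normal, and the wet/high tail lower-inclusive
(1 ≤ x < 1.5, 1.5 ≤ x < 2, x ≥ 2); macro-classes group the three
dry/low and three wet/high classes.

## Spatial aggregation

Fraction cover is block-averaged 6× (mean of the 36 finer cells) to the
analysis grid. Within a country, cell weights are proportional to
fraction cover and sum to 1; countries with zero total cover are
excluded with a diagnostic. Country SPEI is the weighted mean of cell
SPEI (an undefined cell value with positive weight makes the country
value undefined — silent renormalization would bias dry/wet
frequencies); country SYI is a **plain** mean over cells carrying the
cropping system, because gridded yields are already fraction-weighted at
the source. Calendars given as cell-level day-of-year dates are
converted to months (365-day calendar, fixed for determinism) and
averaged per country with half-up rounding; plain, non-circular
averaging is used, and countries whose cell months span more than half
the year are flagged, since a December/January straddle makes the plain
average questionable — an acknowledged limitation.

## Season windows

A season planted in month PM and harvested in HM (wrapping the calendar
year allowed) has length L = ((HM − PM) mod 12) + 1. The admissible
window runs from PM − 2 (pre-sowing moisture matters for soil
workability and early development) through HM: W = L + 2 months, and
every duration d = 1..W at each ending month that keeps the accumulation
inside the window, W(W+1)/2 combinations in total. Ending months earlier
than January of the harvest year carry a year offset, so wrapped seasons
pair the SYI of harvest year y with SPEI values dated y − 1 (or y − 2).
Timing is reported as months before the harvesting month (MBH), which
makes windows comparable across countries with different calendars.

## Contingency statistics

Tables are built from paired yearly values (years with either value
undefined are dropped pairwise) at two levels: per country — the primary
per-record results — and pooled across countries per (cropping system,
duration, MBH), which is the level of the significance matrix and the
dominance summary. The pooled level is where the minimum-sample gate of
36 values is meaningful (a single country contributes at most 36 years),
and it is the only level at which very small p-values are attainable:
the one-sided Fisher exact p is bounded below by the reciprocal of a
binomial coefficient of the anomalous-margin counts, which at one
country's ~6 anomalous years can never go below ~0.1.

The Asymmetry mean gates everything downstream: merged p-values are
reported only when all three components strictly exceed 50 %. A
component with target > 0 and counterpart 0 is 100 %; with both 0 it is
undefined and blocks the mean — this preserves the "> 50 %" semantics.
The Fisher table layout [[LY_D, LY_W], [HY_D, HY_W]] (normal classes
excluded, alternative: odds ratio > 1) is a documented choice — the
only arrangement consistent with the asymmetry macro-classes — computed
as a hypergeometric upper tail. Wilcoxon rank-sum tests use the exact
permutation distribution when both groups have ≤ 10 values (midranks,
two-sided doubling rule) and the tie-corrected normal approximation with
continuity correction otherwise; each group must have ≥ 5 values
(configurable — the minimum behind "no minimum sample reached" cells is
not standardized anywhere, 5 keeps the normal approximation serviceable).
The merged p-value is the most conservative of the three Vovk–Wang
valid mergers for K = 3 under arbitrary dependence: scaled arithmetic
(×2), geometric (×e) and harmonic (×e·ln 3) means, capped at 1. A
nominally significant merged p whose magnitude tests point the wrong way
(higher yields under drought, or higher SPEI in low-yield years) is
reported as class `reversed`, never as positive evidence.

Dominance is computed within the 3 × 3 LY_D block lettered row-major
from (extremely-low-yield, extremely-dry); the diagonal holds
equal-severity co-occurrences and the upper triangle the cells where the
yield class is severer than the drought class. Per-system summaries
average dominances across analysed tables (analysed = pooled n ≥ 36 and
a non-empty LY_D block) and report the share of tables strictly above
the 66.7 % / 50 % thresholds; the cross-system average weights systems
by their number of analysed tables.

## Susceptibility

For each year with country SYI ≤ −1, the number of window combinations
with defined SPEI ≤ −1 is counted (undefined values never count as
drought) and averaged across low-yield years. Averages pooled over all
cropping systems are split into five quintile classes (linear-
interpolation quantile estimator, lower-open/upper-closed bins — the
estimator is a fixed choice, none being canonical), with exact zeros as
their own class; fewer than five positive values trigger a single-class
fallback. The yearly global view summarizes per-year country counts with
median, quartiles and Tukey whiskers (most extreme values within
1.5 × IQR), and echoes the upper bound of the second quintile bin as the
low/medium susceptibility boundary.

## The synthetic world

The generator emulates only the statistical structure the analysis
assumes, not any real product's magnitudes or spatial covariance:

| parameter | default | meaning |
|---|---|---|
| `n_years` | 36 | record length (the shortest the standardization tolerates is 30) |
| `fine_shape`, `coarse_factor` | (36, 36), 6 | fraction grid and 6× block aggregation |
| `n_countries` | 6 | contiguous rectangular blocks (row strips) |
| `base_ppet`, `trend_ppet` | 10, −0.2 mm/month(/yr) | intercept and mild drying trend |
| `season_amp` | 40 mm/month | sinusoidal seasonal cycle, phase drawn once per cell |
| `ar1_rho`, `noise_sd` | 0.3, 30 mm/month | AR(1) month-to-month persistence at stationary marginal SD |
| `yield_base`, `yield_trend`, `yield_noise_sd` | 5, 0.05, 0.5 | yield level, technology trend, interannual noise |
| `coupling_beta`, `coupling_duration`, `coupling_ending_mbh` | 0, 3, 2 | yield response per standardized anomaly of the stated window |
| `coupling_kind` | `linear` | `linear`: β·z (surplus helps as much as deficit hurts); `deficit`: β·min(z, 0) |

Magnitudes are mid-latitude-plausible (a ±40 mm/month seasonal cycle
with 30 mm/month interannual noise; ~5 t/ha yields with a 1 %/yr
technology trend). Dry spells are injected additively on P − PET before
any detrending, so interannual events survive the pipeline's linear
trend removal. Cell noise streams are independent by construction. That
independence has a consequence worth stating: averaging k independent
standardized indices shrinks the country index's variance by √k, so
multi-cell countries show far fewer anomalous years than real countries
do (real drought is spatially coherent). Worlds built to exercise the
*statistical* machinery therefore use single-cell countries, which keep
country-level indices standardized — the structural assumption of the
analysis — while the weighting arithmetic is exercised separately.

The `deficit` coupling exists because a symmetric linear response makes
lower-yield-under-drought and higher-yield-under-wet co-occurrences
equally frequent by construction, so the strict asymmetry gate toward
LY_D passes with probability ~½ no matter how strong the coupling; an
asymmetric drought → loss response — the phenomenon the statistics are
designed to detect — requires the one-sided form. Coupled-recovery
scenarios also set `ar1_rho = 0`: with persistent months, window cells
adjacent to the injected one correlate with the signal genuinely, so a
zero-persistence world is used where recovery must be attributable to
the exact injected (duration, timing) cell.

**What a green test does and does not establish.** The generator has no
spatial covariance, no non-Gaussian climate tails beyond what the AR(1)
+ sinusoid produces, no irrigation or management confounders, and
country-level coherence only in the single-cell limit. Green tests
establish that the formulas, gates, exact tests and classifications are
implemented correctly and that the pipeline recovers a known injected
signal with calibrated false-positive behavior — not that any
real-world association exists or that effect sizes transfer.

## Numerical choices

- Standard-normal quantiles clipped to ±4; detrending flags residual
  variance ≤ 1e−9 of the data scale as degenerate (a perfect line leaves
  only float cancellation noise).
- Country weight sums are exact to 1e−9; weights of exactly 0 exclude a
  cell from NaN propagation.
- Half-up rounding for country calendar months (4.5 → 5).
- Exact Wilcoxon tail uses a 1e−9 tolerance when comparing enumerated
  rank sums to the observed one, so midrank float noise cannot flip a
  tie.
- Quantile bins assign boundary values to the lower (upper-closed) bin.
- Seeds: geography, climate and yields draw from independent child
  streams of one root seed, so any stage is reproducible in isolation.

## Known limitations

- Calendars straddling December/January within one country are averaged
  plainly (flagged), not circularly.
- The pooled significance matrix treats country-years as exchangeable;
  no spatial or temporal multiple-testing correction is applied across
  the duration × timing matrix (none is standard for this analysis), and
  pooled samples from overlapping windows share years, so the pairwise
  magnitude comparisons are correlated.
- Fisher's exact test at per-country sample sizes is severely
  granular; per-country significance classes are reported but rarely
  informative below n ≈ 100.
- The log-logistic fit falls back to plotting positions for roughly half
  of all symmetric-noise series at n = 36; results at moderate class
  thresholds are insensitive to this, but extreme-class frequencies
  (|index| ≥ 2) are slightly compressed under the fallback.
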