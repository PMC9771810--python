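# Methods

## Change model

The unit of analysis is a 30-m pixel (nominal area 900 m²) inside a marsh
extent mask, observed monthly. For each pixel the detector compares the
mean NDVI over QA-passing observations in the peak-biomass months of an
analysis epoch (Aug–Sep north of the equator, Feb–Mar south) with the same
mean over the 1984–1999 reference window. The anomaly Δ = mean_epoch −
mean_ref classifies the pixel per epoch:

- loss if Δ < −0.2, gain if Δ > +0.2 — strict inequalities, so |Δ| = 0.2
  exactly is stable. The 0.2 threshold is the conventional value for
  tidal-wetland NDVI change at Landsat scale.
- no-data if either mean has zero valid observations. No-data pixels are
  excluded from all numerators and denominators, never assumed stable.

Classification is per-epoch and pointwise: there is no temporal smoothing
across epochs, so raising the threshold can only shrink the loss/gain sets
(a property test asserts this). When a pixel qualifies as loss in several
epochs the loss is dated to the earliest one. A loss pixel is *recovered*
if any strictly later epoch's mean is at least the reference mean
(inclusive); the recovery epoch is the earliest such epoch. The inclusive
hard threshold means a pixel that returns exactly to baseline is detected
with probability ≈ 0.5 under symmetric observation noise; this is a
property of the rule, not an estimator defect.

Watersheds with sparse early imagery can be given a per-watershed reference
override (e.g. 1984–2004), supplied as a mapping from watershed id to an
alternative reference window.

Gain is counted within the marsh mask by default. Because gain could also
mean expansion into the surrounding land, the change map covers the full
1.8-km processing buffer and callers may count gains there instead; the
100-m ring around the marsh provides the buffer loss/gain covariates used
by the driver panel. Which of the two gain conventions is "right" for a
given mapping campaign is a user decision; both are exposed.

## Area estimation

Mapped areas (pixel count × 900 m²) are bias-adjusted with a stratified
accuracy-assessment sample. With stratum weights W_i (mapped proportions)
and sample counts n_ij (map class i, reference class j):

    p̂·j  = Σ_i W_i n_ij / n_i·
    SE²   = Σ_i W_i² p_ij (1 − p_ij) / (n_i· − 1)

Areas are total_area × p̂·j with 90% CIs at a fixed z = 1.645 (no t
correction; samples are large) and no finite-population correction (the
sample is vastly smaller than the pixel population). Strata with n < 2 are
rejected by name. User's, producer's and overall accuracies come from the
same matrix. Aggregation across regions sums areas and combines SEs as the
root sum of squares — an independence assumption, stated as such. Net
change = gross loss − gross gain; recovery is separate bookkeeping and is
never re-subtracted. The rate is 100 × net / (base extent × years), % yr⁻¹,
and is additive over region splits.

## Drivers

**Sea level.** Each tide station's monthly mean sea level record is split
into the 5-year epochs; each epoch (≥ 24 months required) is decomposed
additively — trend = centred 2×12-month moving average with half-weight
endpoints, seasonal = month-wise means of the detrended series centred to
zero, residual = remainder (statsmodels `seasonal_decompose`, identical to
the classical filter in R's `decompose`). The local sea-level change (LSLC)
is the OLS slope of the trend component against decimal year, in mm yr⁻¹
(≥ 12 defined trend months required, otherwise missing); stations within a
watershed are averaged. The moving average passes linear trends through
exactly and annihilates 12-month sinusoids, so noiseless recovery is exact
to machine precision.

**Hurricanes.** HURDAT2 archive text is parsed losslessly (hemisphere
suffixes signed, −999 sentinels → missing). Storm diameter at a track point
is 2 × the maximum available 34-kt quadrant radius (nmi → km at 1.852);
when all radii are missing, a configurable category-average diameter table
supplies a fallback, and points with neither are skipped with a warning.
Saffir–Simpson category bounds (64/83/96/113/137 kt, lower bound inclusive)
are configuration, not constants. Buffers are circular per point — tracks
are not swept between 6-hourly points — on a local equirectangular plane;
the contract is topological (intersects / does not), not sub-metre.
A watershed-epoch is exposed if any hurricane-strength point's buffer
(category ≥ 1; tropical-storm points are ignored so "category 0" always
means "no exposure") intersects the watershed polygon, and records the
maximum category over intersecting points.

**Panel regression.** Loss and gain responses are fit by OLS with watershed
and epoch fixed effects (dummy columns) plus the covariates LSLC, 100-m
buffer loss, buffer gain, urbanization increment, hurricane category. The
two-way fixed-effects specification is a design choice to absorb
watershed-level and epoch-level confounding. Rows with missing covariates
are dropped and counted; rank-deficient designs raise with the most
collinear column pair named.

## Carbon accounting

Unit chains (area in km²):

- AGB carbon [Tg C] = area × 10⁶ × 705.9 g m⁻² × 0.441 / 10¹²
- Burial change [Tg CO₂e yr⁻¹] = (net area / years) × 10⁶ × 168 / 10¹² × 44/12
- SOC release [Tg C] = area × 100 ha km⁻² × SOCS [Mg ha⁻¹] / 10⁶

Belowground biomass is never added separately — it is assumed included in
the soil-core SOCS values. SOCS defaults: 270.4 ± 2.8 Mg ha⁻¹ (in situ) or
317.2 ± 19.1 (literature) for the first metre; a 30-cm path requires an
explicitly supplied 30-cm density. Dispersions are used as printed (the AGB
value carries a standard deviation, burial and SOCS carry standard errors);
which dispersion is sampled is the parameter's as-given value.

Uncertainty is propagated by Monte Carlo: each uncertain input is drawn
independently (default 100,000 draws), the quantity is evaluated per draw,
and the mean plus empirical percentile 90% CI is reported. Carbon densities
are drawn truncated-normal at zero (physical non-negativity — with the AGB
sd of 720 the truncation lifts the sampled mean above 705.9, which the
engine reports honestly); areas are drawn plain normal, since published
intervals for area-driven quantities extend below zero. Area SEs may be
back-derived from printed 90% CIs as (high − low)/(2 × 1.645). Results are
deterministic given the seed, and every result carries units; converting
Tg C to Tg CO₂e applies 44/12 exactly once and refuses a second
application.

Yearly emission rates should use per-epoch rates where available (loss from
2015–2019, gain from 2000–2004, the epochs least affected by mapping-year
bias); with only 20-year totals, totals/20 are used and labelled as such.

## Synthetic data

The scene generator emulates what the detector consumes, not sensor
physics: per-pixel NDVI = base (0.5) + a seasonal sinusoid (amplitude 0.15)
peaking in the hemisphere's peak-biomass months + Gaussian noise
(default sd 0.05) + injected event shifts, observed monthly from 1984
through 2019 with i.i.d. Bernoulli QA dropout (default 0.3, emulating
cloud/quality filtering). A consistent red/NIR pair is emitted
(red = (1−NDVI)/4, nir = (1+NDVI)/4) so the NDVI formula is exercised.
Events shift the post-onset mean by a configurable delta (default 0.3,
comfortably beyond the 0.2 threshold); recovery events restore the baseline
at the recovery epoch. Masks are rectangles with distance-transform rings
(100-m ≈ 3.3 px, 1.8-km ≈ 60 px); watersheds are vertical strips. Tide
series are trend + 12-month sinusoid + noise; panels are linear models with
drawn fixed effects and covariates on realistic scales.

What passing tests on these scenes show: the detector, estimators and
regressions recover known truth under the stated noise model. What they do
not show: robustness to cross-sensor calibration drift, tidal-stage optical
effects, scan-line artifacts, spatially correlated cloud masks, or
non-Gaussian NDVI noise — none of which the generator emulates.

## Problem sizes and numerical choices

The test suite exercises 128×128-pixel scenes (20 noisy replicates for
detection fidelity), 1,000 simulated accuracy assessments with 1,000 points
per stratum for CI coverage (comparable to the 12,600-point scale of a real
campaign), 100 tide-series replicates, 60-replicate panel simulations and
100,000-draw Monte Carlo runs — sizes chosen so each statistical check has
enough replication to be meaningful while the whole suite runs in well
under a minute of compute per module. Float comparisons against truth use
1e-6 to 1e-12 tolerances depending on whether a moving-average or OLS step
intervenes; exact-recovery claims are asserted at 1e-8 or tighter.

## Known limitations

- Per-point (not swept) storm buffers can miss a fast-moving storm's
  between-fix coverage.
- The equirectangular local plane distorts at continental scale; watershed
  sets spanning many degrees of latitude should be projected properly
  upstream.
- The stratified estimator's CI is a normal approximation; with very small
  strata or near-0/1 cell proportions its coverage degrades (the estimator
  refuses n < 2 but does not otherwise warn).
- Recovery detection at the exact baseline is a coin flip under noise (see
  above); recovered areas under noise are therefore conservative.
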