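# marshchange

Epoch-based salt-marsh change detection and blue-carbon accounting.

Salt marshes sequester carbon, buffer coasts against storms, and are being
lost to sea-level rise, hurricanes and drainage. This package implements a
complete, testable analysis pipeline for quantifying that change and its
carbon consequences from Landsat-scale NDVI time series:

1. **NDVI anomaly change detection** — each pixel's mean NDVI over
   peak-biomass months (Aug–Sep in the Northern Hemisphere, Feb–Mar in the
   Southern) in four 5-year epochs (2000–2004 … 2015–2019) is compared with
   its 1984–1999 reference mean. With Δ = NDVI_epoch − NDVI_ref, a pixel is
   a **loss** anomaly if Δ < −0.2, a **gain** if Δ > +0.2 (strict
   inequalities), and **recovered** if, after a loss, a later epoch's mean
   returns to at least the reference mean.
2. **Stratified area estimation** — mapped class areas are bias-adjusted
   with a stratified accuracy-assessment sample: p̂·ⱼ = Σᵢ Wᵢ nᵢⱼ/nᵢ·, with
   SE(p̂·ⱼ) = √( Σᵢ Wᵢ² pᵢⱼ(1−pᵢⱼ)/(nᵢ·−1) ) and 90% CIs at z = 1.645;
   net change = gross loss − gross gain, rate = 100·net/(extent·years).
3. **Drivers** — local sea-level change (OLS trend of the classically
   decomposed monthly tide-gauge series, mm yr⁻¹ per epoch), hurricane
   exposure (HURDAT2 tracks buffered by storm diameter, Saffir–Simpson
   category per watershed-epoch), urbanization, and two-way fixed-effects
   panel regressions of loss and gain on these covariates.
4. **Carbon accounting** — aboveground biomass carbon (705.9 g m⁻² × 0.441),
   forgone burial (168 g C m⁻² yr⁻¹), and soil organic carbon stock released
   under complete 1-m loss (270.4 Mg C ha⁻¹ in situ), each propagated with
   100,000 Monte-Carlo draws to empirical 90% CIs, in Tg C / Tg CO₂e
   (CO₂e = C × 44/12).

A synthetic-scene generator (`marshchange.scene`, `marshchange.simulate`)
produces all pipeline inputs with known ground truth — NDVI stacks with
injected change events, tide series with known trends, HURDAT2 text, panels
with known coefficients — so every stage is validated against truth.

## Worked example

`python examples/carbon_budget.py` (global 2000–2019 change totals as input):

```
burial flux change: 0.0447 Tg CO2e yr-1 (MC mean 0.0447, 90% CI 0.022-0.067)
SOC loss (1m, insitu): MC mean 73.90 Tg C (90% CI 58.07-89.68)
  as CO2e: 271.0 Tg CO2e
AGB carbon: MC mean 1.104 Tg C (90% CI 0.135-2.392)
```

The first line is the annual carbon burial forgone by the net loss of
1,452.84 km² spread over 20 years; the second is the soil carbon released if
the first metre of soil under the 2,733.33 km² gross loss is completely
lost, with Monte-Carlo uncertainty from the area SE (±355.06 km²) and the
SOCS density SE (±2.8 Mg ha⁻¹).

`python examples/change_detection.py` runs the detector on a noisy synthetic
scene and reports per-epoch loss/gain areas plus truth-set agreement
(36/36 injected loss pixels found, 0 false positives at noise sd 0.05 and
30% QA dropout). The other `examples/*.py` scripts demonstrate area
estimation, sea-level trends, hurricane exposure, panel regression and the
one-config pipeline (`run_pipeline`) in the same style.

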