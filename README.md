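# phenoflux

Growth and diurnal-transpiration phenotyping pipelines for
controlled-environment screening of plant collections — built around the
kind of lab model used to rank banana (*Musa* spp.) genotypes for
performance under water limitation.

## What it does

Screening a germplasm collection for drought behaviour typically runs two
complementary lab experiments, and `phenoflux` implements the analysis of
both:

**Stage 1 — growth under osmotic stress.** Plants of many genotypes grow in
sealed hydroponic containers under a control (0% PEG) and a mild
osmotic-stress (5% PEG-8000, ≈ −0.05 MPa) treatment, arranged in staggered
sub-experiments that all share one reference cultivar. The pipeline:

* estimates above-ground growth allometrically
  (initial shoot mass = whole-plant mass × cultivar-specific shoot proportion);
* removes batch effects by the reference-cultivar median ratio,
  `X_norm = X × median(X_allRef) / median(X_subExpRef)`,
  computed per variable, treatment and sub-experiment;
* summarizes growth per genotype (mean ± SE, n = 8 per treatment) with the
  growth-inhibition percentage `100·(1 − mean_stress / mean_control)`;
* regresses control on stress means (OLS, adjusted R²), groups genotypes by
  k-means on per-condition growth ranks, ranks stress-responsive
  morphological variables with a from-scratch sparse PLS-DA, and tests
  effects with a two-way ANOVA (Type-II SS) + Tukey HSD;
* measures canopy area from top-view images by HSV colour segmentation
  calibrated against a red 10 × 5 cm reference.

**Stage 2 — diurnal transpiration dynamics.** Each plant sits on a
precision balance logging container weight every 10 s across 12 h/12 h
photoperiod days; weight loss of a sealed container is transpiration.
The pipeline converts the trace to cumulative transpiration that resets at
every light switch, fits the 12-h day curve with a continuous 3-segment
piecewise-linear model (two estimated breakpoints: start → maximum →
pre-night reduction; the night is one extra 12-h segment), and extracts 23
named variables per plant-day — segment durations (A–C), per-gram volumes
(D–I), daily proportions (J–M), rates (N–P), day/night rate ratios (Q–T)
and the water saved by the afternoon rate reduction
(U = (E + F + C·O) − H, V = 1 − P/O, W = 1 − H/(E + F + C·O)).
Per-plant medians feed genotype-level hierarchical clustering (average
linkage on the mean absolute difference of z-scaled variables) that
separates water-saving (group A) from water-spending (group B)
transpiration phenotypes.

A fully-tested synthetic-data generator emulates the whole design
(11 sub-experiments, shared reference, batch effects, 4-phase diurnal
curves with genotype-specific breakpoints, gas-exchange traces, top-view
images) with machine-readable ground truth, so every stage is testable
without the original raw data.

## Worked example

Analyze one synthetic plant's six-day balance log:

```python
from phenoflux.synthetic import GeneratorConfig, default_profiles, gen_balance_log
from phenoflux.transpiration import analyze_balance_log

profile = default_profiles()[4]          # genotype "GA04", water-saving group A
log, truth = gen_balance_log(GeneratorConfig(seed=0), profile,
                             mass_before=18.0, mass_after=24.0)
res = analyze_balance_log(log)
fit = res.fits[1]
print(f"day-1 fit: b1={fit.b1:.2f} h, b2={fit.b2:.2f} h")
for k in ("duration_Reduction", "relTransp_dayNight", "closureProp", "propSave"):
    print(f"{k}: {res.medians[k]:.4f}")
```

prints

```
day-1 fit: b1=1.88 h, b2=7.24 h
duration_Reduction: 4.7635
relTransp_dayNight: 0.4641
closureProp: 0.4496
propSave: 0.1910
```

i.e. the fitted breakpoints recover the planted profile (b1 = 1.88 h,
b2 = 7.24 h) through σ = 0.05 g reading noise; this genotype transpires
0.46 mL per gram of plant per 24 h, cuts its transpiration rate by 45% in
the afternoon (`closureProp`), and that early reduction saves 19% of the
water a full day at the maximum rate would have cost (`propSave`).

The growth stage ships with a packaged per-genotype growth summary table
(31 genotypes, control and stress means ± SE). Reproduce its derived
statistics with:

```bash
phenoflux report --seed 0
```

which recomputes the inhibition column (all 31 rows within 0.1 of the
printed percentages), the control–stress regression
(control = 3.70 + 1.54 × stress, adjusted R² = 0.77), the k-means
performance grouping on growth ranks (92.1% of total SS captured at k = 5)
and the mean remaining growth under stress (58.6% of control).

A full synthetic end-to-end run (simulate → growth → transpiration →
clustering, with a provenance manifest) is:

```bash
phenoflux run --seed 1 --out runs/demo
```

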