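# Methods

This note documents the models, estimators and design choices behind
`phenoflux`, and what the synthetic-data generator does and does not
emulate.

## Experimental model

The package targets a two-part lab screening of a plant collection.

*Growth characterization*: genotypes are grown hydroponically for 21 days
under a control (0% PEG) and a mild osmotic-stress treatment (5% PEG-8000,
≈ −0.05 MPa), n = 8 plants per genotype × treatment, arranged in 11
staggered sub-experiments of 4 genotypes each. One reference cultivar is
present in every sub-experiment so that batches can be compared. The
response of interest is above-ground growth (pseudostem + leaf fresh-mass
increase), a yield proxy.

*Transpiration phenotyping*: individual plants in sealed containers sit on
0.01 g balances logging weight every 10 s over six 12 h light / 12 h dark
days. Because only the shoot is exposed, container weight loss is
transpiration (1 mg ≈ 1 µL of water; density 1 g/mL).

## Stage 1: growth analysis

**Allometric initial shoot mass.** Plants cannot be measured destructively
at the start, so the initial shoot mass is the starting whole-plant mass
times a cultivar-specific shoot proportion estimated from the final
destructive measurements of control plants, assuming that proportion is
stable over the trial.

**Batch normalization.** For every variable X and treatment, the factor
median(X over reference plants of all sub-experiments) /
median(X over reference plants of this sub-experiment) multiplies every
plant of that sub-experiment and treatment. Applying it to the reference
plants as well (not only the other genotypes) makes the reference medians
exactly equal across batches, which is the invariant the pipeline tests;
for all non-reference genotypes this is identical to applying the factor
only to them. Normalization is refused when a sub-experiment/treatment has
no reference plants. The factor is undefined (error) when the
sub-experiment reference median is zero. Second application yields factors
of 1 (idempotence).

**Genotype summaries.** Mean ± SE (sd/√n) per treatment; inhibition
= 100·(1 − mean_stress/mean_control), undefined and flagged when the
control mean is ≤ 0; negative growth values are retained and flagged, not
clipped. Per-genotype control-vs-stress significance uses a Welch
two-sample t-test with tiers \*\*\* p<0.001, \*\* p<0.01, \* p<0.05 — the
test is a package choice; the summary tables the pipeline reproduces do
not name one.

**Regression and grouping.** Control means are regressed on stress means
by OLS; adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2). Performance groups come
from k-means (k = 5 by default, Euclidean, 100 random restarts with a
recorded seed, best RSS kept) on the two-column matrix of per-condition
growth ranks (average ranks on ties); the captured fraction is
between-cluster SS over total SS, which is non-decreasing in k.

**ANOVA.** Two-way treatment × group ANOVA with Type-II sums of squares
(the screening design is unbalanced across groups), pairwise Tukey HSD on
the treatment:group cell means; empty cells are an error naming the cell.

## Sparse PLS-DA

Variable ranking uses a NIPALS-style sparse PLS-DA written from scratch.
X is column-autoscaled (constant columns dropped with a warning); Y is a
centered one-column-per-class dummy coding. Per component, the X-weight
vector w ∝ Xᵀu is soft-thresholded so only the `keep` largest-magnitude
entries survive (the rest shrink to zero by the keep-th largest magnitude),
then normalized; scores t = Xw; Y-loadings q = Yᵀt/tᵀt; the inner loop
iterates to tolerance 1e-9 (max 500 iterations). Both X and Y are deflated
by the rank-one regression on t, which makes score vectors mutually
orthogonal and strictly reduces the Frobenius norm of X. Each component's
sign is fixed so its largest-magnitude loading is positive. With no
sparsity the first component equals the dominant eigenvector of XᵀYYᵀX,
which the test suite verifies against an explicit eigen-decomposition.

Variable importance is the maximum over components of |loading| weighted
by that component's share of explained X variance; the direction of change
is the sign of the stress-minus-control (or group-B-minus-group-A) median
of the raw variable. The combination rule across components is a package
choice — a defensible aggregation where only "rank by consistency of
change" is specified. Defaults: keep 10 variables per component for the
stress-response ranking; dense (keep = p) for the transpiration-group
ranking, where only an ordering is needed. Sparsity is not cross-validated
(out of scope).

## Stage 2: transpiration dynamics

**Cumulative conversion.** Within each 12-h phase, cumulative transpiration
at a reading is the first weight of the phase minus the current weight;
values reset to zero at every light switch. All bookkeeping is in
trial-local time (t = 0 at the first lights-on). Readings are binned to
1-minute means before fitting (a 3-segment model does not need 4,320
points per phase; the bin width is configurable, 0 disables binning).
Missing readings are flagged as gaps (> 60 s) and never imputed; the
fitting basis tolerates irregular spacing.

**Segmented day fit.** The day curve is fitted with the continuous basis
{1, t, (t−b1)₊, (t−b2)₊}; the intercept is estimated rather than forced
through zero to tolerate a constant evaporation offset. The breakpoint
pair minimizing the RSS is found by exhaustive search on a 5-minute grid
(minimum segment length 0.5 h), then refined continuously by Nelder–Mead.
The grid search is exact but cheap: suffix prefix-sums over the sorted
time axis turn every Gram-matrix entry into an O(1) lookup, so the ~7,000
candidate pairs cost one batched 4×4 solve (~10 ms per day) instead of
7,000 least-squares fits. The procedure is deterministic and seed-free.
Segment slopes follow from the hinge coefficients; segment volumes are the
fitted line's increments (not raw-data increments), which is what makes
noiseless synthetic data reproduce planted variables to machine precision.
A day whose 3-segment RSS improves on the single-line RSS by less than
1e-9 of the total SS is flagged "no-breakpoint"; segment identity is
positional (start/maximum/reduction = 1st/2nd/3rd) with a shape flag when
the expected s2 ≥ s1 ≥ s3 ordering does not hold.

**Night segment and plant size.** The night is one additional 12-h
segment; its volume is the least-squares linear rate times 12 h (robust to
noise and to the last reading falling just short of the switch). The night
assigned to a fitted day is the one *following* it (configurable to
preceding; the pairing is a package choice). Per-day plant mass is a
linear interpolation between the weights before and after the trial,
evaluated at the day midpoint. Volume and rate variables are divided by
that mass.

**The 23 variables.** Durations A–C from the breakpoints; per-gram volumes
D–G; H = E+F+G; I = D+H; daily proportions J–M (= D/I … G/I, summing to
1); rates N–P (= E/A, F/B, G/C); night-referenced rate ratios Q–T (using
the night rate D/12; reported missing, never infinite, when D is 0 or
unavailable); water-saving variables U = (E+F+C·O) − H, V = 1 − P/O,
W = 1 − H/(E+F+C·O). These identities hold to 1e-9 for every extracted
plant-day by construction and are asserted in the tests. Days with less
than 90% of expected readings in either phase, and partial first/last
days, are excluded; per-plant summaries are medians across the remaining
days (NaN-aware).

**Gas exchange.** Intrinsic water-use efficiency is A/g_s (undefined at
g_s ≤ 0); the afternoon decline of a per-minute trace is
100·(1 − mean(decline window)/mean(reference window)).

## Phenotype clustering

Per-plant medians are averaged per genotype (the reference cultivar is
restricted to one designated sub-experiment — default the first — to avoid
flooding the analysis with its replicates) and z-scaled per variable.
Genotype distance is the mean absolute difference of scaled variables
(L1/23; Euclidean available by configuration — the "average difference" is
ambiguous and L1/23 is the literal reading). Agglomeration is average
linkage (UPGMA) with deterministic tie-breaking by sorted genotype order;
the tree is cut at two clusters, refused when all genotypes are identical.
Group "A" is by convention the water-saving cluster: the one with the
lower mean 24-h transpiration per gram (relTransp_dayNight). Per-variable
group separation is tested at plant level with Welch t-tests, tiers
\*\*\* p<0.001, \* p<0.05, nS otherwise.

## Canopy imaging

Pixels are classified in HSV: green hue 70–170°, red −20–20° (wrapping),
blue 190–260°, all requiring saturation > 0.25; anything else is
unclassified. The thresholds are package defaults calibrated on the
generator's images and exposed in the configuration. Calibration uses the
largest connected red component (guarding against stray red pixels):
cm²/px = 50 cm² / reference pixel count. Leaf length is the pixel-cloud
extent along its principal axis plus one pixel (so an N-pixel row measures
N pixels), width the extent perpendicular to it, area the pixel count
times the calibration. The one-pixel edge correction is exact for
axis-aligned shapes and biases rotated thin shapes by up to one pixel of
their width. Overlapping-leaf instance segmentation is out of scope
(leaves are physically separated before imaging).

## Synthetic data generator

The generator is first-class, tested code and defines the conditions under
which the pipelines are validated:

* design defaults: 11 sub-experiments × 4 genotypes sharing the reference,
  n = 8 plants per treatment; one multiplicative batch factor per
  sub-experiment, drawn uniformly from (0.8, 1.25), applied to all
  absolute-size variables (scale-free ratios are untouched, as a shared
  vigor effect cancels in them);
* morphology noise: multiplicative Gaussian with CV 10% (typical biological
  replicate spread at this scale); stress multiplies growth by
  (1 − inhibition), reduces leaf area/width and relative water contents,
  and raises root:shoot dry allocation (×1.5 for root-investment genotypes,
  ×1.05 otherwise);
* balance logs: 10-s readings over 6 days; day-phase loss rate is
  piecewise-constant (s1, s2, s3 across the two breakpoints), the night
  rate constant, all scaled by the day's interpolated mass; additive
  Gaussian reading noise σ = 0.05 g (a 0.01 g balance plus vibration);
* the default panel is 26 genotypes — 13 per transpiration group (group A:
  earlier reduction onset b2 ≈ 6.6–8.5 h, lower maximum rate
  s2 ≈ 0.036–0.052 mL/h/g; group B: b2 ≈ 9.2–10.9 h,
  s2 ≈ 0.062–0.084 mL/h/g), spanning five growth-performance tiers
  (control means ≈ 7–53 g, inhibition ≈ 0.10–0.65) — with 3 lysimeter
  plants per genotype. The pre-night closure fraction is planted equal
  (1 − s3/s2 = 0.45) across groups, so the clustering tests can assert it
  does *not* separate the groups;
* gas-exchange traces plant a 59% afternoon conductance decline and a 34%
  assimilation decline; top-view images draw green discs of requested
  area, a red 10 × 5 cm reference and a blue field, with optional
  antialiasing.

A fixed seed makes all outputs bit-identical; different seeds change only
the noise realization, never the planted truth, and every generator emits
a machine-readable truth record.

What the generator does **not** emulate: circadian drift within segments
(real day curves bend rather than kink), autocorrelated balance noise
(vibration bursts, door openings), plant growth feedback on transpiration
within a day, non-linear plant-size trajectories, chamber micro-gradients,
and overlapping leaves in images. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model and design, not
robustness to every failure mode of real lysimeter data.

## Problem sizes and numerical choices

The test suite runs the full default panel (26 genotypes × 3 plants ×
6 days of 10-s readings) for the clustering round-trip, 100 noisy
single-day logs for breakpoint-recovery statistics, 500 replicates for the
inhibition-coverage check and 1,000 simulated layouts for the ANOVA
type-I calibration — sizes at which the measured quantities are stable to
well within the asserted tolerances. Tolerances: inner sPLS-DA iteration
1e-9; breakpoint refinement 1e-7 h; identity assertions 1e-9; the
no-breakpoint flag threshold 1e-9 of total SS. Degenerate inputs
(constant columns, zero night loss, all-zero volumes, identical genotypes,
empty ANOVA cells) are flagged or raised explicitly rather than producing
infinities.

## Known limitations

* The packaged growth-summary table prints 31 of the study's 32 genotypes
  (the reference cultivar's own row is absent), so statistics that the
  original analysis computed at n = 32 are reproduced here at n = 31;
  the regression and grouping figures agree within the documented
  tolerances but cannot match exactly.
* The sPLS-DA importance aggregation across components and the exact HSV
  segmentation thresholds are package choices where the underlying
  procedure is underdetermined; both are configurable.
* Breakpoint estimates at segment boundaries shorter than the 0.5 h
  minimum segment length are not identifiable and are excluded by
  construction.
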