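# Methods

This note records the models, parameter choices, and numerical decisions
behind `leafcal`, and what the synthetic-data tests do and do not
demonstrate about measured data.

## Calibration model and evaluation protocol

The calibration is single-response PLS (PLS1) of per-leaf chlorophyll
(ug/cm2) on reflectance channels.  Predictors are mean-centered but not
variance-scaled by default, since all channels share relative-reflectance
units; unit-variance scaling and absorbance-space fitting are switches
(`PLSCalibrator(scale=True)`, `to_absorbance`).  Predictions are never
clipped: negative estimates pass through so MAE and R2 stay unbiased.

The latent-variable count `k` is chosen by Akaike's criterion
`AIC = n ln(RSS/n) + 2k`.  Both `n` and RSS refer to **leaf-level**
predictions (the mean of a leaf's replicate predictions) on the inner
test leaves, matching the leaf-averaged scores the pipeline reports; a
spectra-level alternative can be reproduced by passing one spectrum per
leaf.  Ties in mean AIC break toward smaller `k` (parsimony).

Evaluation is double-nested Monte-Carlo cross-validation with two
guarantees asserted programmatically on every split:

* **group integrity** — all spectra of a leaf stay on one side of every
  split, so replicates can never leak across sets;
* **stratification** — held-out sets sample 10 quantile bins of leaf
  chlorophyll with per-bin counts differing by at most one.  Bin edges
  are computed once per dataset and reused by every split at every
  level, so bin identity is stable across repetitions.

Defaults follow the 100-leaf study shape — 20 validation leaves held out
per outer repetition, 60/20 inner splits, 20 inner repetitions, 50 outer
repetitions (1000 inner iterations per candidate `k`) — and scale
proportionally for other dataset sizes.  Candidate `k` ranges are 1–6
for 6-channel layouts and 1–16 for the 18-channel layout.  A master seed
deterministically spawns one child seed per outer repetition
(`SeedSequence(master).generate_state(reps) & 0x7FFFFFFF`), making full
runs bit-reproducible and single repetitions reproducible in isolation.

Learning curves fix one stratified test hold-out per repetition, shared
across all training-set sizes within that repetition, isolating the
effect of training-set size from test-set variability.

## Outlier screening

Spectral screening computes Mahalanobis distances either of raw spectra
(`full` mode) or of replicate residues — a replicate minus the mean of
the leaf's other two replicates (`residue` mode) — independently per
(sensor x species) dataset, and flags distances beyond mean + 3 SD.
`full` mode also flags genuinely unusual leaves (young, undeveloped
ones); `residue` mode targets measurement error only, which is why it is
the preprocessing default.

Reference-disk screening centers each leaf's disks at their median and
scales residuals by a species-level MAD (1.4826 x median absolute
residual, floored at 1e-6 ug/cm2 against zero-variance degeneracy),
excluding disks beyond 3x that spread.  Robust center and scale were
chosen because a mean/pooled-SD rule is self-masking at triplicate
sample sizes: a gross disk error inflates both its own leaf mean and the
pooled spread enough to hide itself.  With a median center, a leaf can
only lose all disks when it has two (wildly disagreeing) usable disks;
that case raises an explicit error so the caller drops the leaf
deliberately.

## Synthetic populations

The generator emulates the study conditions: five species x 100 leaves,
triplicate spectra per leaf on each layout, triplicate reference disks.
Leaf reflectance follows a Beer–Lambert-style link
`R(w) = R_bg(w) exp(-kappa(w) chl)` with absorption `kappa` peaking in
the blue (~0.028 cm2/ug near 430 nm) and red (~0.030 near 680 nm),
dipping in the green, and vanishing in the NIR, over a background curve
rising from ~0.5 in the visible to a ~0.85 NIR plateau.  This produces
the monotone, saturating chlorophyll-reflectance relationship and the
NIR > green > red ordering the calibration exploits.

Species profiles (defaults, chosen from the study's qualitative
contrasts and fixed before any evaluation):

| species   | chl range (ug/cm2) | replicate noise SD | texture SD | bg mix max | chip SD |
|-----------|-------------------|--------------------|------------|-----------|---------|
| banana    | 25–80             | 0.010              | 0.03       | 0         | 0.005   |
| jasmine   | 35–65             | 0.020              | 0.06       | 0         | 0.020   |
| mango     | 15–90             | 0.010              | 0.04       | 0         | 0.005   |
| rice      | 20–70             | 0.030              | 0.05       | 0.45      | 0.100   |
| sugarcane | 20–75             | 0.025              | 0.05       | 0.25      | 0.040   |

Broad smooth leaves (mango, banana) get the lowest replicate noise and
no background mixing; jasmine is textured with the narrowest chlorophyll
range; narrow-leaf rice and sugarcane mix background reflectance into
each replicate and carry the largest per-chip artifacts.  The default
disk-noise SD of 3 ug/cm2 follows from a reported within-leaf reference
MAE near 2 ug/cm2 (`E|disk - mean of 3| = sqrt(2/3) sqrt(2/pi) sd ~
0.65 sd`).

Noise layers, in order: a per-leaf lognormal texture factor; a
per-replicate convex mixture with a flat 4% background ("narrow leaf not
covering the optical path") — drawn **per chip** on the 18-channel
layout, since each of its three apertures views its own patch of a
narrow leaf, and once per replicate on single-aperture layouts; a
per-chip, per-replicate lognormal gain (aperture disagreement,
18-channel layout only); additive per-channel noise in
relative-reflectance units (repositioning/illumination error — additive
rather than proportional, so replicate consistency does not depend on a
leaf's brightness); and a count-level shot-noise floor
(`sd = sqrt(counts)`) applied to the raw counts, which are reflectance
times a fixed per-layout illumination intensity curve.  Reference disks
are drawn as `chl + N(0, disk SD)` and converted to (A647, A664) pairs
that invert exactly through the DMF equation, so the noise-free
reference pipeline reproduces truth to machine precision.  All
randomness flows from one explicit seed through a single generator; no
global state.

Young, undeveloped leaves (`simulate_with_young_leaves`) combine very
low chlorophyll (high visible reflectance) with a depressed NIR plateau
(underdeveloped spongy mesophyll, default factor 0.6) and normal
replicate consistency — spectral extremes that a full-spectrum screen
flags and a residue screen leaves alone.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline's statistics behave
correctly under the generator's assumptions: formulas match independent
arithmetic; screening recovers injected gross errors at 10 channel-SDs
with few false flags; the AIC scan recovers a known latent
dimensionality; splits never leak and are bit-reproducible; calibration
recovers chlorophyll on smooth-leaf populations and degrades under
background mixing.  They do not certify accuracy on measured leaves,
whose noise is not Gaussian, whose chlorophyll-reflectance link is not
exactly exponential, and whose acquisition drifts (thermal effects,
LED aging) are not modeled at all.

One documented gap: with the zero-mean per-chip artifact model, the
combined 18-channel fit consistently matches or beats its best
single-chip subset, because the combined feature set contains every
subset and averaging independent chip noise helps a leaf-averaged linear
model at these sample sizes.  Several artifact structures (per-replicate
and per-leaf gains, asymmetric aperture coverage, per-channel patch
heterogeneity, per-chip effective-chlorophyll offsets) all behave this
way.  Measured devices can show the opposite ordering on narrow leaves;
reproducing that reversal evidently requires device systematics outside
a zero-mean noise model, and the corresponding check is expected to fail
on synthetic data.  The chip-subset machinery itself (`chip_comparison`,
`chip_subset`) is fully functional, and the directional effect that is
reproducible — per-chip artifacts reduce the combined sensor's scores —
is tested.

## Numerical choices

* Covariance inversion for Mahalanobis distances uses the sample
  covariance (n-1); if its condition number exceeds 1e12 a ridge of
  `1e-8 trace/p` is added (18 correlated NIR bands on small subsets can
  be near-singular).
* Inside the LV scan, RSS is floored at 1e-12 so perfect fits select the
  smallest adequate `k` rather than producing -inf AIC; the public
  `aic()` raises on RSS = 0.
* The inner scan fits one PLS model per split at the largest candidate
  `k` and evaluates all smaller `k` from the coefficient path (leading
  blocks of the upper-triangular `P'W`); path-vs-direct equality is
  unit-tested to 1e-8.
* The 18-channel chip map (A = first six channels, B/C interleaving the
  rest) is configuration, not data: device revisions differ, so custom
  maps load from YAML and analyses record which map was used.
* Test-suite and acceptance-script problem sizes (100-leaf populations,
  20 outer x 20 inner repetitions in the acceptance study, 10x10 for
  paired comparisons) are the package's chosen desk-scale defaults;
  the full 50x20 protocol runs in seconds and is exercised in the
  integrity test.

## Known limitations

* Radiometric realism is out of scope: no LED spectra, integration-time
  or drive-current effects, thermal drift, or detector nonlinearity.
* The generator's species contrasts are qualitative emulations, not fits
  to measured populations; absolute R2/MAE values depend on its noise
  defaults and should not be read as device performance claims.
* Reference chemistry assumes the DMF coefficients and a fixed
  chlorophyll-b/a absorbance ratio when synthesizing disk absorbances.
* PLS is the only regressor; nonlinear models are out of scope.
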