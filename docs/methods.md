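# Methods

## Scope and model

The package analyses a two-group (control vs drought-stressed) tomato trial
in which every plant carries an implanted organic-electrochemical-transistor
sensor whose channel current tracks xylem-sap ion content, is imaged from
three orthogonal views (RGB + NIR) on scheduled days, and is sampled manually
for stomatal conductance, leaf water status and SPAD. Two built-in designs
mirror the trials the pipeline was developed around: a pilot (16 h
photoperiod; 3 d settling, 14 d drought, 2 d rewatering, 6 d second drought)
and a main experiment (12 h photoperiod; 1 d settling, 16 d drought with one
50 cm³ emergency irrigation on day 8, 7 d rewatering, imaging every other
day, physiology on days 0/7/14/21). Day 0 is sensor implantation and all
timestamps are minutes since implantation; day boundaries for 24 h averaging
are midnights of that clock (the boundary choice is a convention, not data-
driven). The emergency-irrigation day defaults to day 8 but is configurable,
since published accounts of such events are often ambiguous about the day.

## Sensor chain

`R = (I_ds − I_ds0)/I_ds0` per sample; samples with `|I_ds0| < 1e-3 µA` are
dropped and counted (the floor is arbitrary, logged, configurable). R is
scale-invariant in the currents by construction. Daily means use a ≥50%
sample-coverage rule; incomplete windows are flagged and excluded by
default. NR is the ratio of the *group mean* daily R of stressed over
control plants — a group-mean ratio rather than a mean of per-pair ratios,
which is robust to unequal group sizes and requires no plant pairing.

**Phase segmentation** fits a continuous piecewise-linear model (hinge basis
`{1, x, (x−b)+}`) to the daily NR series. For each breakpoint count
k = 0…5 the breakpoint positions are found by exhaustive search over the
integer day grid (each segment must keep ≥2 points; a point exactly at a
breakpoint belongs to the left segment, matching the hinge basis); k is then
chosen by BIC with 2 + 2k parameters (two base coefficients plus a slope
change and a position per breakpoint) and an RSS floor of 1e-12 to keep the
noiseless case finite — ties resolve to the smallest k. Segments are
labelled from the design's expected phase windows after snapping fitted
breakpoints to the nearest expected boundary within ±2 d; a positive-slope
segment strictly inside the drought window is relabelled DA.

**Onset detection** scans a grid (the sampling interval) of endpoints t from
stress start to +72 h. For each, the OLS slope of sub-daily NR over
[t − 12 h, t] is tested one-sided against zero, with the slope's standard
error derived from the residual variance of a linear fit to the 24 h
pre-stress baseline. Because a scan over hundreds of correlated windows at a
fixed per-window level would not control the family false-positive rate, the
level is Bonferroni-corrected across scanned windows by default; the
programmed decline is so steep relative to the NR noise that power is
essentially unaffected (measured ≥ 99% in-window over 200 replicates, with a
~1% null false-detection rate). With zero noise the test degenerates to
"slope < 0", so a noiseless programmed break is detected one grid step after
it occurs.

**Recovery** is the mean NR over the PIII plateau (PIII excluding its first
2 d of rise) divided by the mean NR over PI; < 1 indicates incomplete
recovery.

## Imaging chain

Segmentation gates on hue (vegetation window 25–185°, spanning green, yellow
and brown tissue) and saturation (> 0.15) for RGB, or a fixed margin above
the stated uniform background level for NIR, then keeps the largest
connected component. The indices follow the standard definitions; three
choices deserve note:

- The biovolume's logarithmic third term uses the **top view** (the two side
  silhouettes enter linearly); the view is configurable.
- Compactness is computed on the **top view** by default — "how much of the
  hull area is covered by leaves" describes canopy closure — and its hull is
  taken over the *corner points of the occupied pixel squares*, not pixel
  centers, so a filled convex region scores exactly 1.
- The green window defaults to hue 60–180°; greenness fractions in the
  literature differ in their window, so it is a configuration constant.
- The NIR index bins intensities into 128 equal bins over [0, 256) and
  returns the count-weighted mean of bin centers; it therefore stays within
  half a bin width (1 intensity unit) of the plain pixel mean.

Height is the mean vertical pixel extent over available side views (row 0 is
the image top); no mm calibration is applied since none is defined for the
synthetic camera.

## Physiology

RWC follows the fresh/turgid/dry weight formula and is invariant to common
rescaling of the weights; a fresh weight outside [dry, turgid] is flagged as
a measurement error but still returned. "Relative SPAD" is interpreted as
the plant mean over the *same-day control-group mean* (an alternative day-0
normalization is available), since the term is used in the field without a
fixed definition. The conductance fold change is control mean over stressed
mean.

## Integrative statistics

The feature table pools plant × imaging-day rows of C, GI, SC, R, NI, DB.
R enters as the **magnitude** of the per-plant daily mean response joined to
the nearest day: the raw response is negative (the gate bias de-dopes the
channel), and its magnitude is what tracks sap ion content and transpiration,
so correlations against conductance and biovolume carry the physiologically
meaningful sign. SC is joined from the nearest physiology day. Pearson r
uses the t transform with n − 2 df; the correlation matrix uses
pairwise-complete rows and reports n per cell. PCA standardizes the
variables (they have incommensurate units), so components diagonalize the
correlation matrix; variance shares sum to 100% over all components and
loadings are orthonormal. Per-timepoint tests are two-sample equal-variance
t or one-way ANOVA (identical for two groups: F = t²), with unadjusted
p-values and conventional star thresholds (∗ p ≤ 0.05 … ∗∗∗∗ p ≤ 0.0001); an
inverted star map seen in some published figure captions is available as a
preset, and Benjamini–Hochberg adjustment is deliberately off by default to
match common practice in such trials.

## Synthetic experiment

One latent daily state per plant — biomass, height, hydration, chlorosis,
turgor, sap ion concentration — drives every modality, so cross-modal
correlations are emergent rather than imposed. The default effect sizes are
the study conditions the pipeline targets: a 30 h lag between water
withholding and the sap-ion decline; an NR decline of 0.12/day with a
drought-avoidance rebound recovering 50% of the preceding decline (the
rebound amplitude is not quantified in published accounts; 50% is the
package default); a post-rewatering NR plateau at 70% of baseline; a 15%
height deficit by stress day 6 (held thereafter); turgor loss over stress
days 4–14 recovering after rewatering; a hydration dip over days 7–10 with a
bump at the emergency irrigation and full restoration after rewatering; a
4.5-fold conductance reduction during stress days 7–14; a 23% RWC drop at
peak stress, fully restored after rewatering; and a +4 SPAD unit shift under
stress. Groups of 4 plants each, 15 min sensor sampling.

The ion-response map is saturating and monotone,
`R(c) = r_baseline · log10(1 + c/c0) / log10(1 + c_ref/c0)` with c_ref =
50 mM and c0 = 5 mM (xylem-sap ionic strengths are tens of millimolar);
any monotone map suffices for pipeline testing since only direction and
detectability are asserted. Diurnal modulation is a half-sine over the
photoperiod that deepens the (negative) response during daytime; it is
common to both groups and cancels in NR. Noise is additive Gaussian on the
per-sample response (SD 0.01) and multiplicative/additive on physiology;
fixed per-plant gain factors (SD 3%) emulate device and size variation.

The renderer draws a stem with eight elliptical leaves on a uniform mid-blue
background. Side-view plant area is proportional to biomass times a
projection factor `0.55 + 0.45·turgor` — drooping leaves present a smaller
silhouette, so biovolume falls during wilting even while structural biomass
creeps up, as observed in real drought trials. The latent height is the
*realized* (wilting-inclusive) height and equals the rendered vertical
extent, so the programmed day-6 deficit is exactly what the imaging pipeline
should recover; turgor additionally drives leaf droop in side views and
rosette spread in the top view (raising top-view compactness as plants
wilt). The chlorotic fraction of leaf pixels equals the latent chlorosis
(oldest/lowest leaves yellow first); NIR plant intensity is affine in
hydration (55 + 180·h, jitter SD 1.5).

What the generator does **not** emulate: real platform backgrounds and
lighting, leaf occlusion and 3-D canopy structure, soil-water dynamics,
sensor drift beyond a slow baseline exponential, and genotype differences.
Passing tests therefore demonstrate that the pipeline recovers known effects
from data with the right statistical structure — not that segmentation or
onset detection would survive the messiness of real greenhouse imagery.

## Determinism and numerics

All randomness flows from one integer seed through named substreams
(`SeedSequence([seed, tag, ...])`), so a rerun with the same configuration is
byte-identical, including PNGs; the orchestrator records tool version, seed
and a configuration hash in `manifest.json`. Degenerate inputs are handled
explicitly: empty traces and all-dropped samples raise; a zero control-group
mean masks that day of NR; empty masks flag their indices as missing rather
than zero; a zero top-view area zeroes the biovolume log term with a
warning; zero residual variance turns the onset test into a sign test.

## Problem sizes

The default experiment is 8 plants × 24 d at 15 min sampling (~18k sensor
samples), 12 imaging days × 6 images at 160 px, and 4 physiology days. The
replicated onset analysis uses 200 default and 200 null experiments. These
sizes keep a full analysis around 20 s while leaving every statistical
criterion comfortably powered.

## Known limitations

- NR uses group means; a single-reference-plant normalization would behave
  differently with device dropouts.
- Exhaustive breakpoint search is exponential in k; it is intended for the
  daily-resolution series (≤ ~30 points, k ≤ 5) it is applied to.
- The feature table's nearest-day SC join repeats one conductance value
  across neighbouring imaging days, slightly inflating the effective n of
  SC-involving correlations (as any such join does).
- The published headline correlation and PCA figures from real trials are
  not reproducible from synthetic data; only signs, significance and
  separation properties are asserted.
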