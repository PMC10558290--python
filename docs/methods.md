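# Methods

## The conversion chain

A blot abundance *a* (ng of target per µg of total protein) converts to a
cellular concentration through c = a·K/MW, with K in µM·kDa per (ng/µg).
Dimensionally K is the cytoplasmic total-protein mass concentration in
g/L. Two values of K are defensible and they disagree:

- **calibrated (default)**: K = c·MW/a evaluated on the actin row of the
  reference table (13.2 µM, 41.8 kDa, 7.99 ng/µg) gives K ≈ 69.06,
  equivalent to ≈69 g/L cytoplasmic protein. Every other row of the table
  is consistent with this K (see "known inconsistencies"), so this mode
  reproduces the published concentrations.
- **first principles**: total protein mass per cell (4 pg) divided by the
  cytosolic volume (≈27 fL) gives ≈148 g/L. The stated constants
  therefore do *not* reproduce the published µM column; the ≈2.15×
  mismatch is exposed by `conversion_constant_discrepancy()` rather than
  silently resolved.

The cytosolic volume is wet mass / density × cytoplasm fraction
(6×10⁻¹¹ g, 1.1126 g/ml, 0.5 → 26.96 fL). Molecules per cell are
c·V·N_A (1 µM·fL ≈ 602 molecules). All concentrations are carried in µM,
volumes in fL, masses in g; conversions are centralized in
`abpcensus.core` and never inlined.

Tpm2 is not blotted; its abundance is Tpm1's divided by six (a published
molar-ratio observation), then converted with Tpm2's own MW. Note the
division happens on the *abundance*: dividing the final concentration by
six instead would give 2.07 µM, not the published 2.54 µM, because the
two tropomyosins differ in MW.

### Known inconsistencies in the reference table

The packaged table stores the published values verbatim; the test suite
asserts, rather than hides, where they are not self-consistent:

- **Cap1/2** (capping protein, stored as the heterodimer per convention,
  `oligomer_n = 2`): no single K consistent with the other rows turns
  1.43 ng/µg at 64.3 kDa into the printed 1.46 µM (the calibrated chain
  gives 1.54, +5.2 %). Its printed molecule count (5.12×10⁴) matches
  per-polypeptide accounting at the single-subunit MW within ~3 %.
- **Pfy1 / Abp140**: quantified by GFP intensity, not blot; their ng/µg
  entries are back-derived and rounded, so the chain reproduces them to
  ~1.2 % and ~0.5 % respectively.
- **Aip1**: the printed count (2.40×10⁴) is ~25 % below c·V·N_A
  (3.00×10⁴) and is most plausibly a transcription error.

All other rows agree with the calibrated chain within 1 % and with
c·V·N_A within 2 %.

## The actin budget

G-actin is estimated kinetically: cable elongation at 0.3 µm/s × 370
subunits/µm requires 111 subunits/s, which at a formin elongation
coefficient of 25 subunits·s⁻¹·µM⁻¹ needs 4.44 µM profilin-actin.
F-actin is total actin minus that (8.76 µM with the unrounded estimate;
8.8 with the published 4.4). Binder-class sums run over the flagged
records, excluding actin itself; the Arp2/3 complex is represented by the
Arp2 subunit's concentration, as the table does. Cof1's cytosolic
fraction could not be measured (GFP fusions are non-functional); budget
outputs that need it use an explicit assumption, defaulting to 0.76, the
midpoint of the 0.61–0.91 range observed for the other ABPs, and carry a
`fraction_assumed` flag. "Binding within x seconds" is read as the mean
waiting time 1/(k_on·c) of a Poisson binding process at a
diffusion-limited on-rate of 10 s⁻¹µM⁻¹; whether a quantile was intended
is not recoverable, and the mean is the conservative, parameter-free
reading.

## The synthetic cell generator

`abpcensus.synth` emulates spinning-disk confocal acquisition of single
yeast cells: 35 z-slices at 0.2 µm, 0.065 µm pixels, cell radius
2.25 µm (population sampling 10–40 µm² projected area). A cell is a
uniform-intensity sphere of cytosol (100 AU/voxel) plus either punctate
patches (3D Gaussians, 0.15 µm, placed near-uniformly on the cortex
shell, |cos θ| ≤ 0.95) or cable arcs (Gaussian tubes bowed along the
mother–bud axis). The tagged-protein channel carries cytosol +
structures + in-cell autofluorescence (20 AU/voxel); the marker channel
carries structures only. Both are blurred with an anisotropic Gaussian
PSF (σ 0.1 µm lateral, 0.3 µm axial — the standard desk-scale
approximation to a high-NA confocal PSF) and corrupted with Poisson shot
noise (gain 1 AU/photon) plus Gaussian read noise (σ 2 AU). One seed
fixes the entire stack; a separate `noise_seed` lets Monte-Carlo checks
vary noise over fixed geometry.

The ground-truth cytosolic fraction is the analytic integral ratio
∫cytosol / (∫cytosol + ∫structures) on the pre-noise, pre-background
fields — exactly the quantity the masking measurement estimates, and
invariant under PSF blur because convolution conserves integrated
intensity (truncation at the field boundary stays below 1 % with the
default geometry). `target_fraction` scales the structure amplitude so
this ratio is hit exactly, which is how recovery experiments get known
truth.

What the generator does *not* emulate — and hence what passing recovery
tests do not certify about real data: bud/neck geometry, organelle
exclusion volumes, depth-dependent aberrations, photobleaching, temporal
dynamics, marker/target colocalization error, and segmentation difficulty
of crowded fields (cells are isolated spheres, so the built-in
threshold segmenter suffices; real images need a learned segmenter, for
which `segment_cells` takes a plug-in callable).

## The fraction measurement and its numerical choices

Projections follow the acquisition convention: ABP channel averaged over
z (mean signal per unit area), marker channel maximum-projected
(structures are thin in z). The default set point is the Otsu threshold
of the marker projection *within* the cell mask — automatic and
reproducible where a manual value would be arbitrary — with a numeric
override, and a ±25 % sweep quantifies sensitivity. The structure mask is
dilated by 3 px (~0.2 µm ≈ two lateral PSF sigmas) by default: a
threshold at the Otsu level keeps only the bright core of a blurred
punctum (~67 % of its light on default fixtures), and the leaked tails
otherwise bias the cytosol mean upward by 0.1–0.25 in fraction units;
the PSF-scale margin captures ~98 % of structure light. Dilation is
exposed (`mask_dilate`, `--mask-dilate`; 0 disables).

Background is a single scalar per channel per session, measured as the
mean in-cell projected intensity of fluorophore-free cells and subtracted
from every pixel before the means are taken. Because in-cell
autofluorescence scales with column depth while the subtraction is
scalar, a small residual pattern survives; it contributes <0.01 to the
fraction at default settings. Fractions marginally above 1 (possible on
noisy input) are reported as-is with a `flagged` bit, never clipped, so
population statistics stay unbiased. Cells touching the image border are
excluded from population statistics by default.

Residual systematic error: with defaults, recovered fractions run
+0.02–0.03 above truth. The remaining bias is geometric — masked cortical
patches preferentially remove projection pixels with shorter cytosol
columns, raising the cytosol mean — and is inherent to the mean-over-
pixels definition of the measurement, not to the synthetic data. For
cable cells the same effect has the opposite sign and larger magnitude
(cables cross the deep cell center; at high fractions the measured value
can run ~0.1 low), which is why quantitative recovery claims are made for
the patch geometry. Median absolute recovery error over seeded patch
cells at default noise stays below 0.05 across ground-truth fractions
0.3–0.9 (20 cells each; the test suite runs exactly this).

## Blot quantification

Standard curves are unweighted ordinary least squares with signal as the
response (standards span about one decade, so weighting would change
little and the published analysis states none). The linear-range rule is
interpolation-only: a lysate band whose inverse-predicted mass falls
outside [min, max] standard mass raises an out-of-range error and is
excluded from aggregation (and logged). Replicate spread is the sample
(n−1) SD, absent at n = 1. The fixture generator's default lysate loads
(2, 4, 6 µg at 7.99 ng/µg truth) place all bands mid-range, as a
well-designed blot would; noise-free fixtures quantify exactly, and 200
fixtures at 5 % signal noise recover the mean within 0.5 %. The GFP
calibration line is fitted with intensity as the response (concentration
on x, matching the published equation y = 102x + 35.22) and inverted for
prediction; intensities below the intercept raise an error rather than
returning a negative concentration.

## Population statistics

"Constant over the cell cycle" is operationalized as: the 95 % CI of the
OLS slope of per-cell fraction (or total signal) against projected cell
area contains zero. This is this package's definition — the source
analysis reports regressions without a formal test — and it is reported
alongside the raw slope and CI. No multiplicity correction is applied
across proteins (none was applied originally); the report says so. The
coefficient of variation is the sample SD over the mean, requiring n ≥ 2
and a positive mean. Method-comparison tables join per-protein µM values
by name, report missing entries as absent (never imputed), and invert
ratios consistently under argument swap.

## Problem sizes

Image-based tests and the recovery experiment use single cells of the
default 35×100×100-voxel geometry (and 21–25 slice reductions where the
check is structural rather than quantitative); population checks use
30–40 cells. These sizes make every statistical criterion reproducible in
seconds on one CPU while leaving the per-cell measurement identical to
what larger runs would execute.
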