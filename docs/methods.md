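# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Intelligent protocolling (`amri.protocolling`)

A protocol is a set of pulse sequences; each sequence owns a look-up table
(LUT) mapping acquisition-parameter combinations `P_acq` over its degrees of
freedom (DOF) to the acquisition time `t_acq` (seconds) and the
console-reported relative SNR (rSNR, dimensionless). Acceleration is a
constrained search per sequence under a whole-protocol budget `T_acq`:

1. **Time allocation.** Each sequence gets the share
   `%TA = ((y2-y1)/(x2-x1)) * (x - x1) + y1`, the straight line through the
   minimum and maximum feasible time percentages. `x1`/`x2` are the
   shortest/longest protocol times (sums of the per-sequence extremes);
   `y1` is the shortest sequence time over the shortest protocol time, and
   `y2` is built the same way from the longest times. The symmetric
   construction of `y2` is this package's interpretation — the source
   formulation names only the numerator of `y1`. Budgets outside
   `[x1, x2]` are clamped with a warning. Degenerate LUTs in which every
   sequence has a single timing collapse the line to a fixed share.
2. **Weighted rank.** Rows exceeding the allocated per-sequence budget are
   discarded (boundary inclusive: only rows *exceeding* the budget go).
   Each survivor is ranked by the weighted sum of normalised absolute
   differences from the default (gold-standard) combination, plus an rSNR
   difference term relative to the default rSNR. Contrast-critical timing
   DOFs (TE/TR/TI/ETL) default to weight 1.0, geometry DOFs to 0.5, and
   rSNR to 0.1 — rSNR deliberately gets the smallest weight because SNR is
   the quantity being traded away and later restored by denoising. These
   defaults are this package's own; they are configuration, not a claim
   about any particular site's weighting. Normalisers default to the
   default entry's value (or the LUT's value range when the default is
   zero or categorical). Categorical DOFs contribute zero when equal to
   the default and their full weight otherwise.
3. **Iteration.** The minimum-rank feasible row wins (ties: lower `t_acq`,
   then input order). Budgets decrease geometrically (default factor 0.95
   per step) from the gold-standard duration until some sequence has no
   feasible row; the last complete assignment is the fastest protocol.
   The geometric schedule is a package choice — any strictly decreasing
   schedule can be supplied.

`brute_force_search` re-implements the same contract by exhaustive scan and
exists purely as a test oracle.

## Volume model and I/O (`amri.volume`)

Volumes are 3D magnitude images; the through-plane (slice) axis is by
convention the last array axis. NIfTI-1 is the on-disk format, with voxel
spacing on the affine diagonal and contrast/subject/repeat metadata in a
JSON sidecar (`<stem>.json`), since NIfTI has no native slots for them.
`central_slab` keeps the centered `round(fraction * n)` slices (half-up,
minimum one; an odd margin drops the extra slice from the start) — the
default 0.5 fraction excludes edge slices that hold either pure background
or unwanted anatomy.

## Quality metrics (`amri.metrics`)

- **Object mask**: threshold at `p2 + 0.1 (p98 - p2)` of the intensity
  histogram, keep the largest 3D connected component, fill holes. This is a
  deterministic reduction of brain-extraction-style masking; full surface
  evolution is out of scope.
- **Local SNR**: in-plane `window x window` (default 5) mean divided by a
  robust global background noise scale, evaluated on the central 50% slab;
  "object-masked" statistics take the median over the mask. The noise scale
  is `(Q75 - median) / 0.6745` of the background intensities. For symmetric
  noise this equals the usual `1.4826 x MAD`; it was chosen over the MAD
  because magnitude images are clipped at zero, which can floor half the
  background at exactly zero and drive the MAD itself to zero, while the
  upper half-spread stays exact. The local-SNR estimator as a whole is one
  isolated operation: the literature it descends from does not pin down a
  variant, so the package fixes and documents its own.
- **PSNR**: `20 log10(range) - 10 log10(MSE)`; the data range defaults to
  the reference maximum because magnitude MR images carry no bit depth.
  Identical inputs raise rather than return infinity.
- **MS-SSIM**: the canonical 5-scale weights (0.0448, 0.2856, 0.3001,
  0.2363, 0.1333), 11x11 Gaussian window (sigma 1.5), K1=0.01/K2=0.03,
  means over the fully-supported (valid) region, 2x2 mean-pool between
  scales. Images too small for five scales use as many scales as fit, with
  renormalised weights and a warning. Volumes are scored per slice and
  averaged, matching the 2D processing used throughout.
- **var-Lap**: variance of the interior response to the 3x3 Laplacian
  stencil, pooled over slices; a referenceless blur measure (affine images
  score exactly zero).
- **MR Value**: sum of per-contrast median object-masked local SNR divided
  by the protocol duration in *seconds* (validated by the worked examples:
  243.354/1152 s -> 0.211, 215.767/592 s -> 0.364). Printed third decimals
  may reflect truncation rather than rounding, so comparisons allow
  +-0.001.

## Native-noise forward model (`amri.noise`)

Rather than assuming a noise law, the forward model harvests the empirical
background of the noisiest acquisition (minimum median object-masked local
SNR over a volume set), collages all non-object voxels into a reusable
block (layout defaults to the source shape; deficits are filled by seeded
shuffled repetition), and corrupts clean volumes by adding i.i.d.
resampled draws scaled by a factor, clipping at zero. The scale is
calibrated on the grid `{start, start + step, ...}` (defaults 1.0 and 0.5;
a 0.5 start is exposed as configuration because the source material states
both) until the corrupted volume's median local SNR falls *strictly below*
the target — the noisiest acquisition's own SNR — making the simulated data
at least as noisy as the worst real data. The median, not the mean, guides
calibration because local SNR distributions are skewed. One fixed seed per
calibration run makes the returned scale reproducible. Because the
harvested background of magnitude images is non-negative, corruption also
shifts the local mean slightly; SNR still decreases strictly with the
scale, which is what the calibration relies on. Subject splits are always
subject-wise (largest-remainder rounding of 85-10-5 by default) so no
subject leaks across partitions.

## Denoiser (`amri.denoiser`, `amri.nn`)

The network is a single-channel fully-convolutional residual chain: 13
ResBlocks by default (two ReLU 3x3 convolutions each; a ReLU 1x1 projection
on the skip when the filter count changes), 2x2 max-pooling after one third
and two thirds of the blocks, two nearest-neighbour upsamplings before the
output stage, a global identity skip adding the input to the pre-final
features, and a final ReLU 3x3 single-filter convolution (outputs are
therefore non-negative, consistent with magnitude data). Pooling placement,
the upsampling operator, and the filter schedule (64 everywhere, 128
between the pooling stages) are package choices — only the block count,
activation, projection rule, global skip, and final layer are fixed by the
source architecture.

No deep-learning framework is used: `amri.nn` is a small reverse-mode
automatic-differentiation engine over numpy (im2col convolutions, 2x2
pooling, nearest upsampling, a fused Fourier-crop RMS node), with every
gradient verified against central finite differences in the test suite.
Training uses Adam; all randomness (init, shuffling, patch sampling) flows
from one config seed, and the epoch snapshot with the lowest validation
loss is returned.

**Loss.** `Mix-L = alpha (1 - MS-SSIM) + (1 - alpha) L1` with alpha = 0.84.
MS-SSIM inside the loss uses 3 scales — the most that fit a 64x64 patch
with an 11-pixel window — with renormalised weights. The data-consistency
term FTD is the RMS magnitude of the spectral residual
`M . |F(y_pred) - F(y_true)|` over the central 16x16 k-space crop `M`, with
the DFT normalised by the patch area. The normalisation is this package's
resolution of an ambiguous published form: area-normalised spectra put the
term on the image intensity scale, stable across patch sizes (a constant
offset `c` contributes exactly `|c| / kmask`), so beta = 1 balances rather
than swamps the image-domain terms. `Mix-L+FTD = Mix-L + beta FTD`; the
investigated beta grid is {0, 0.01, 0.1, 1} with default 1. The beta sweep
harness exists, but selecting beta by volumetric RMSE on real data is out
of scope.

**Training constants.** 100 epochs, batch 256, 64x64 patches at identical
noisy/clean coordinates inside per-dataset crop bounds (bounds keep random
crops on anatomy). Baseline initial learning rates per contrast: T1
2.5e-4, T2 1e-4, T2-FLAIR 1e-4, T2* 2.5e-4, DWI 1e-4. Subject-specific
(SS) fine-tuning re-trains briefly (default 10 epochs) on noisy-as-clean
pairs — the subject's noisiest acquisition corrupted by its own scaled
native noise as input, the acquisition itself as target — at reduced rates
(T1 1e-5 or 1e-6, T2 1e-5, T2-FLAIR 1e-4, DWI 1e-5; T2* SS is not
applicable). Inference slides a 64x64 window per slice at a configurable
stride, clamps edge positions, and averages overlaps uniformly.

**Smoke scale.** The in-repo training experiment uses 3 ResBlocks with 16
filters, 5 epochs, 2,000 patch pairs, batch 32, learning rate 1e-3, on
96x96x32 phantoms — sizes chosen so the whole experiment trains in a few
minutes on one CPU core while still demonstrating that held-out PSNR and
MS-SSIM improve over the noisy input. It validates the machinery (losses,
backprop, selection, inference stitching), not the published full-scale
gains, which depend on external clinical datasets and orders of magnitude
more optimisation.

## Explainability (`amri.explain`)

The probe is a 2x2 collage of 64x64 constant panels at intensities
(0.125, 0.375, 0.625, 0.875), row-major ascending (the quadrant order is a
determinism choice), corrupted with sampled native noise. The 128x128 side
follows from four 64x64 panels; the side is configurable. For every 2D
convolution layer in depth order the filter stack is collapsed by per-pixel
maximum-intensity projection, min-max normalised to [0, 1] (constant maps
become all-zero with a warning-free convention), and hard-thresholded at
0.75 by default (alternatives 0.5-0.9 are exposed). The collage PNG layout
is deterministic, so re-runs are byte-identical.

## Agreement statistics (`amri.agreement`)

ICC(2,1) — two-way mixed-effects, absolute agreement, single measures —
from repeated-measures ANOVA mean squares:
`ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))`.
Absolute agreement (not consistency) is the right form because the question
is whether methods produce interchangeable volumes, not merely correlated
ones. Category cut-offs: strictly greater than 0.9 excellent, (0.75, 0.9]
good, (0.5, 0.75] moderate, otherwise poor; 0.9 itself classifies as good
by the strict reading of the cut-off. Repeats either enter as extra rows
(default) or are averaged per subject (`repeat_handling="mean"`); missing
cells are rejected, never imputed. The bundled
`data/brain_volumetry_icc.csv` carries published reference ICC values for
27 brain subregions and 3 tissues used as fixture data for the category
summary (27 excellent / 2 good / 1 moderate).

## Synthetic phantoms (`amri.synthetic`)

Phantoms are three nested ellipsoidal shells (outer/middle/inner standing
in for CSF/GM/WM contrast) on a zero background with i.i.d. Gaussian noise
added everywhere and magnitudes clipped at zero (Rician noise is a config
option; Gaussian keeps the calibration loop's monotonicity analyzable).
Default grid 96x96x32, object radius fraction 0.3, noise sigma 0.05, and
per-contrast intensity triples chosen so tissue brightness orders the way
the named contrast orders it. Subject-to-subject variation of
`object_radius_frac` reproduces the size-drives-SNR premise behind
subject-specific denoising. What the phantom does *not* emulate: anatomy,
partial-volume texture, coil-profile (spatially varying) noise, k-space
sampling artifacts, or Rician bias at low SNR. Passing tests therefore
establish correctness of the algorithms and the direction of their effects,
not clinical performance. LUT fixtures sample DOF values uniformly, tie
rSNR positively to `t_acq` with jitter, and designate the slowest entry as
the default, giving the search a ground truth against brute force.

## Numerical conventions

- All generators and training are pure functions of their seeds; tests pin
  seeds and the suite is deterministic.
- float32 is the working precision for network training (gradient checks
  run in float64); metrics compute in float64.
- PSNR on identical inputs, zero-variance ICC tables, constant volumes in
  masking, and zero-spread noise blocks raise errors instead of returning
  sentinels.
- MS-SSIM component means are clamped at zero before the weighted geometric
  combination to keep fractional powers real on pathological inputs.

## Known limitations

- The local-SNR estimator and the allocation-line `y2` are documented
  interpretations (see above); both are isolated behind single operations.
- The DOF weights shipped as defaults are illustrative, not calibrated to
  any scanner.
- The denoiser trains on CPU via numpy; it is deliberately small. Scaling
  to the published 100-epoch/256-batch regime requires a GPU framework and
  external datasets, both out of scope.
- Noise blocks store empirical values only; spatial noise correlation is
  destroyed by i.i.d. resampling.
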