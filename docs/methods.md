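# Methods

## Density model

The package models the SUVs of a 3D PET volume as a discretized sample from
a smooth spatial process. Each voxel at position p_i (mm, voxel-center
convention: `origin + index * spacing`) with intensity s_i counts as s_i
coincident observations at p_i, so the estimated density is the SUV-weighted
trivariate Gaussian KDE

    f̂(p; h) = (hx hy hz)⁻¹ (Σ s_i)⁻¹ Σ_i Π_d K((p_d − p_id)/h_d) s_i .

Assumptions worth spelling out:

* **Weights are frequencies.** SUVs must be non-negative; an all-zero volume
  is rejected (the normalizer vanishes). Multiplying all SUVs by a positive
  constant leaves f̂, all quantile thresholds and all masks unchanged.
* **Coordinates are physical (mm).** Bandwidths are in mm, so smoothing is
  isotropic in tissue, not in voxel index, on anisotropic grids. On the 1 mm
  isotropic grids typical of head-and-neck PET challenge data the two
  conventions coincide. Users with strongly anisotropic spacing should note
  that the literature often leaves this convention implicit.
* **Zero padding at the faces.** Kernels leak mass across the volume
  boundary rather than being renormalized; the discrete integral of f̂ is
  ≤ 1 and ≥ 0.99 whenever the uptake support stays ≥ 4·max(h) from every
  face. This matches the literal weighted sum over observed voxels.

On a regular grid the weighted sum is exactly a separable Gaussian
correlation of the SUV volume, which is the default evaluation path
(truncated at `truncation_radius` = 6 standard deviations per axis; relative
truncation error ≤ 1e−6 against the literal triple sum, which is retained as
the `direct` oracle path). Bandwidths smaller than the voxel spacing are
allowed but warned about: the density then degenerates towards the scaled
raw image.

## Probability volume contours

For ω ∈ (0, 1) the threshold λ_ω is the **SUV-weighted ω-quantile**
(inverse empirical CDF, lower nearest-rank, no interpolation) of the density
values at voxels with positive SUV. The weighting follows from the frequency
interpretation: a voxel with SUV s contributes s copies of its density value,
verified exactly against repetition expansion for integer SUVs. The region
S(λ_ω) = {f̂ > λ_ω} (strict inequality; the boundary has measure zero on the
grid) is then a highest-density region containing a fraction 1 − ω of the
probability mass of the data.

Two notions of "enclosed mass" exist and the package reports both:

* `enclosed_mass` — the probability mass of the **data** inside the contour,
  i.e. the SUV fraction. This is the quantity the quantile construction
  calibrates: it equals 1 − ω up to grid discretization (measured
  |error| < 0.005 on a σ = 6 mm blob with h = 2 mm).
* `density_mass` — the discrete integral of f̂ inside the contour. It is
  systematically smaller than 1 − ω because smoothing inflates the density's
  spatial scale (for a Gaussian blob, σ² becomes σ² + h²); with σ = 6 mm and
  h = 2 mm the ω = 0.5 contour holds ≈ 0.45 of the density integral. This is
  a diagnostic, not the calibrated quantity.

Contours are computed jointly for an ordered level list (default
{0.1, 0.3, 0.5, 0.7, 0.9}); thresholds are non-decreasing and masks strictly
nested by construction. Surfaces are extracted with marching cubes at the
threshold value and exported in mm coordinates. Connectivity for component
reporting is 6-neighbourhood.

## Coarse-to-fine refinement

The fine stage needs three inputs that a coarse segmenter provides:

* **Bounding box** — tightest box around the coarse mask, dilated by
  `margin_voxels` (default 8) and clipped; disconnected coarse masks get one
  covering box. The density is re-estimated inside the crop only, accepting
  boundary leakage at the box faces.
* **Bandwidth** — arithmetic per-channel mean of the 3-channel bandwidth
  feature volume (aggregation after the positivity transform).
* **Threshold** — the `robust_fraction` (default 0.10) lower nearest-rank
  quantile of density values inside the coarse mask: a robustified minimum
  that ignores outlier voxels in the coarse prediction.

A consequence users should understand: the threshold tracks the coarse
region's own envelope. Refining a *perfect* coarse mask trims the
lowest-density 10% of its volume, capping the achievable Dice at
2(1−q)/(2−q) ≈ 0.947 for q = 0.10; and a coarse mask that systematically
over-segments (e.g. a dilated truth) produces a proportionally inflated
refined mask — the fine stage smooths and trims, it does not contract past
the coarse boundary. Setting `robust_fraction` to 0 makes refinement of a
perfect mask lossless at the price of outlier sensitivity.

## Losses and metrics

The F-loss is 1 − (1+β²)Σŷy / (Σŷ + β²Σy + ε) with ε = 1e−8; β defaults
to 2, weighting recall (missing tumour at the coarse stage is costlier than
over-contouring); β = 1 reproduces the Dice loss to 1e−9. It accepts soft
predictions in [0, 1] as well as hard masks. The two-stage objective is
α·L_KsPC + (1−α)·L_CNN with α = 0.7.

Dice, precision and recall follow the confusion-matrix formulas with
challenge conventions for empty denominators (both masks empty → all 1;
truth empty, prediction non-empty → recall 1, precision and Dice 0). HD95
extracts 6-connectivity boundary voxels of both masks, pools the two
directed nearest-neighbour distance lists in mm, and takes the lower
nearest-rank 95th percentile — the pooled-percentile robustification of the
Hausdorff distance as used by segmentation challenges. It is symmetric and
undefined (reported as such, never 0) when either mask is empty.

## LiteSE-Net backbone

A slim 3D U-Net with squeeze-excitation normalization after every
convolution. Channel widths along the U are 6, 12, 24, 48, 96, 48, 24, 12, 6.
Blocks: a conv stem; one residual block per encoder level (two 3×3×3 convs,
identity shortcut at constant width, 1×1×1 projection shortcut across
width/stride changes, stride-2 downsampling) with a second residual block at
the 96-channel bottleneck; decoder levels upsample trilinearly (×2,
half-voxel aligned), reduce channels 1×1×1, concatenate the skip and apply
two 3×3×3 conv blocks; three extra upsampling paths lift the deep decoder
features (48, 24, 12 channels) to full resolution through 1×1×1 convs and
are summed into the head input. SE-Norm instance-normalizes each channel and
modulates it with γ = sigmoid(FC(z)), shift β = tanh(FC(z)) where z is the
global average pool of the layer input (reduction ratio 2). Heads: 1×1×1
conv + sigmoid for segmentation; 1×1×1 conv + softplus for the 3-channel
bandwidth volume, bias-initialized so the untrained bandwidth starts near
2 mm. The default build totals 1,364,080 learnable parameters; `kspc params`
prints the per-layer audit.

Everything is implemented in NumPy with hand-written backward passes
(convolutions as per-offset GEMMs, exact adjoints for the trilinear
upsampler), validated against central finite differences. Batch size is 1;
the network is fully convolutional for input sizes divisible by 16 (other
sizes are zero-padded at inference).

## End-to-end training

Training minimizes the two-stage objective with Adam and a cosine-annealed
learning rate from 1e−3 to 1e−5 restarting every 10 epochs. The KsPC stage
is made differentiable by relaxing the hard level set to
sigmoid((f̂ − λ)/T), with temperature T = 0.05·max(f̂); the quantile
threshold λ, the coarse mask and its bounding box are treated as constants
within a step (they are piecewise-constant functions of the weights), while
the gradient reaches the bandwidth head analytically through the Gaussian
kernel taps (∂f̂/∂h_d combines a correlation with the derivative taps
K(u)u²/h_d and the −f̂/h_d normalizer term). If the coarse prediction is
empty the argmax voxel serves as the coarse region for that step.

The bundled training loop is a desk-scale demonstration, not a recipe for
clinical-scale training: the default run uses 8 phantoms of 32³ voxels for
20 epochs (≈2 minutes on one CPU core) and shows the weighted loss falling
from ≈0.87 to ≈0.30. GPU-scale training on challenge data is out of scope.

## Synthetic phantoms

A phantom is a flat background (default 0.5 SUV) plus one or more
anisotropic Gaussian uptake blobs (default: one centered blob, σ = 6 mm,
peak 8 SUV — a tumour-to-background ratio ≈ 16:1, within the clinically
typical range), degraded by voxel-wise multiplicative gamma noise with unit
mean and coefficient of variation `noise_scale` (default 0.1), which keeps
values non-negative like real SUVs. The ground truth is the half-maximum
surface of the noiseless blob signal, exactly known analytically (for a
single blob: a ball of radius σ√(2 ln 2)). Dataset generation jitters blob
centers, sizes and amplitudes from per-index child seeds, so datasets are
reproducible and pairwise distinct.

What the phantoms do **not** emulate: scanner point-spread blur,
attenuation/reconstruction artifacts, respiratory motion, anatomical
heterogeneity, or physiological uptake (brain, bladder, tonsils). Passing
phantom tests therefore demonstrates the mathematics of the method —
calibration, nesting, recovery of a known half-maximum truth — not clinical
segmentation accuracy.

## Numerical choices and degenerate inputs

* Quantiles everywhere are lower nearest-rank (weighted inverse CDF where
  weighted); no interpolation. Interpolation differences vanish at image
  scale, and nearest-rank is well-defined for weighted multisets.
* Level-set membership is strict (f̂ > λ). Rescaling SUVs can flip voxels
  whose density ties the threshold in the last ulp; this is the only
  scale-dependence and is confined to exact ties.
* All-zero images, empty coarse masks, non-finite thresholds, out-of-range
  quantile levels, non-binary mask files, negative SUVs (without an explicit
  clamp flag) and oblique NIfTI affines are rejected with typed errors
  rather than silently handled.
* Seeds: every stochastic component (phantom noise, dataset jitter, weight
  initialization, training order) is driven by explicit integer seeds;
  identical seeds give bit-identical outputs.

## Known limitations

* The refinement threshold cannot correct systematic over-segmentation of
  the coarse mask (see above); it assumes the coarse boundary is
  approximately right and only needs smoothing/trimming.
* Mass calibration of the contours is exact for the data (SUV) measure; the
  density-integral measure is biased outward by the smoothing scale and
  should not be read as the calibrated probability.
* With a flat positive background, the background dominates the total SUV
  mass, so low-ω contours legitimately cover much of the field of view;
  contours tighter than the tumour neighbourhood come from the coarse-to-fine
  path, which crops before contouring.
* The backbone is CPU-bound NumPy; it trains desk-scale phantoms in minutes
  but is not intended for 144³ clinical patches at scale.
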