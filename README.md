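# kspc — kernel-smoothing probability contours for PET tumour segmentation

`kspc` segments high-uptake regions in 3D PET volumes and, as a byproduct,
produces nested **probability volume contours** suitable for dose painting by
contours (DPBC) in radiotherapy planning. It is aimed at researchers working
on PET-based gross tumour volume (GTV) delineation who want contour-based,
probabilistically calibrated segmentations rather than raw voxel-wise CNN
output.

## The model

The standardized uptake values (SUVs) of a PET volume are treated as
frequencies of an underlying smooth metabolic process. A voxel at position
p_i = (x_i, y_i, z_i) with intensity s_i behaves like s_i coincident
observations, giving the SUV-weighted trivariate kernel density estimate on
the voxel grid

    f̂(p; h) = (hx·hy·hz)⁻¹ (Σᵢ sᵢ)⁻¹ Σᵢ K((x−xᵢ)/hx) K((y−yᵢ)/hy) K((z−zᵢ)/hz) sᵢ

with K the standard Gaussian kernel and h = (hx, hy, hz) the per-axis
bandwidth in mm. A threshold λ on this density defines the segmentation
S(λ) = {p : f̂(p) > λ}. Choosing λ_ω as the **SUV-weighted ω-quantile of the
density values at the data points** makes S(λ_ω) a highest-density region
enclosing a fraction 1 − ω of the probability mass — so the default levels
ω ∈ {0.1, 0.3, 0.5, 0.7, 0.9} give nested contours enclosing 90%, 70%, 50%,
30% and 10% of the mass, which map directly onto DPBC boost sub-volumes.

Around this core the package provides:

* a **coarse-to-fine pipeline**: any upstream coarse mask (e.g. from the
  bundled CNN backbone) supplies a bounding box, a bandwidth vector and a
  robustified quantile threshold; the kernel-density segmentation then runs
  inside the cropped box only;
* **LiteSE-Net**, a slim 3D U-Net with squeeze-excitation normalization
  (channel widths 6–96, ≈1.36M learnable parameters) with a segmentation
  head and a positive 3-channel bandwidth head, implemented in NumPy with
  explicit backward passes and a desk-scale end-to-end training loop;
* the F-loss (F_β overlap loss, Dice loss at β = 1) and the weighted
  two-stage objective α·L_KsPC + (1−α)·L_CNN;
* evaluation metrics (Dice, precision, recall, HD95 in mm);
* a **synthetic phantom generator** with exactly known ground truth, so the
  whole pipeline is testable without clinical data.

## Worked example

```python
from kspc import KsPC, Bandwidth
from kspc.phantom import PhantomSpec, Blob, generate_phantom

spec = PhantomSpec(
    blobs=(Blob(center=(31.5, 31.5, 31.5), sigma=(6.0, 6.0, 6.0), amplitude=8.0),),
    background_level=0.0, noise_scale=0.0, seed=1,
)
image, truth = generate_phantom(spec)
results = KsPC(image, Bandwidth(2.0, 2.0, 2.0)).fit()
print(results.summary())
```

```
KsPC density manifold
================================================================
grid dims          : (64, 64, 64)
voxel spacing (mm) : (1.0, 1.0, 1.0)
bandwidth h (mm)   : (2, 2, 2)
total SUV          : 27215.3
discrete integral  : 0.999999
----------------------------------------------------------------
  omega   lambda_omega  encl. mass  dens. mass   voxels
   0.10   1.511974e-05      0.8999      0.8686    14136
   0.30   4.775105e-05      0.6997      0.6519     6344
   0.50   8.700809e-05      0.4988      0.4529     3280
   0.70   1.330867e-04      0.2975      0.2642     1520
   0.90   1.936401e-04      0.0990      0.0860      400
================================================================
```

Each row is one probability contour: `lambda_omega` is the density threshold
at quantile level ω, `encl. mass` the fraction of the probability mass of the
data inside the contour (≈ 1 − ω, the calibration the construction
guarantees), `dens. mass` the discrete integral of the density inside the
contour (slightly smaller because kernel smoothing spreads mass outward),
and `voxels` the contour volume. The ω = 0.5 contour encloses 49.9% of the
mass in 3280 voxels; on a real scan this sub-volume would receive the
second-highest DPBC boost.

The coarse-to-fine stage and the metrics work the same way:

```python
from kspc import CoarseOutput, CoarseToFineKsPC, evaluate

coarse = CoarseOutput(coarse_mask=truth, bandwidth=Bandwidth(2, 2, 2))
fine = CoarseToFineKsPC(image, coarse).fit()
print(evaluate(truth, fine.mask).as_record())
# dice=0.9471  hd95_mm=1.0000  precision=1.0000  recall=0.8995  tp=1324  fp=0  fn=148
```

The command-line interface mirrors the library: `kspc phantom`,
`kspc segment`, `kspc refine`, `kspc eval`, `kspc params`,
`kspc train-smoke` (see `kspc --help`). Volumes are NIfTI; contour surfaces
export to OBJ/STL; every run writes a JSON manifest with the configuration
and library versions.

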