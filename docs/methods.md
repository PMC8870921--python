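# Methods

`lesionquant` quantifies white-matter lesion load on paired T1-weighted and
FLAIR brain MRI of multiple-sclerosis patients with two slice-wise U-Nets:
one extracts the brain from T1-w, the other segments FLAIR-hyperintense
lesions on the skull-stripped image. Lesion load is the count of segmented
voxels on an isotropic 1 mm³ grid, reported in mm³. This note records the
model, the numerical choices, and what the synthetic phantoms do and do not
establish.

## Pipeline

For a subject with volumes `I_T1` and `I_FLAIR` (axial slices along the
third axis):

1. **Reslice** both volumes to isotropic 1 mm³ with cubic B-spline
   interpolation (masks always travel with nearest-neighbour so they stay
   binary through every resampling step).
2. **Denoise** slice-wise with Perona–Malik anisotropic diffusion,
   `∂I/∂t = div(g(|∇I|) ∇I)`, conductance `g = exp(−(|∇I|/κ)²)` (a rational
   variant `1/(1+(|∇I|/κ)²)` is selectable). Defaults: κ = 15 expressed as
   a percentage of the slice's intensity range (so the same setting is
   edge-preserving on a [0, 1]-rescaled image and on raw scanner units;
   absolute units are available via ``relative=False``), 10 iterations,
   dt = 0.125; the explicit 4-neighbour scheme is stable for dt ≤ 0.25. The update is written in flux form — each
   inter-pixel flux is applied antisymmetrically — so the per-slice
   intensity sum is conserved exactly and the Neumann (zero-flux) boundary
   is implicit. Constant slices are fixed points.
3. **Register** FLAIR to T1-w with one in-plane rigid transform per volume
   (tx, ty in mm, θ about the slice centre), slices paired by index. The
   similarity is normalised mutual information, (H(A)+H(B))/H(A,B), from a
   32×32-bin joint histogram with partial-volume (bilinear) binning — each
   sample spreads over its four neighbouring bins, so the similarity is
   smooth in the transform parameters where a hard histogram is piecewise
   constant and stalls the optimiser. NMI is robust to the different
   T1/FLAIR contrasts; it is maximised by a gradient-free Powell search
   over a coarse-to-fine in-plane pyramid (downsampling 4×, 2×, 1×).
   Linear interpolation is used inside the search; the final resample is
   cubic. On phantoms this recovers injected misalignments to ≲0.1 mm and
   ≲0.01 rad.
4. **Resize** slices to the network input shape (in-plane spacing rescaled
   so physical extent is preserved) and **rescale** the volume to [0, 1].
   A per-slice z-score normaliser is also provided; the pipeline feeds the
   networks min-max-rescaled intensities, applying the operations in the
   order align → resize → rescale. Constant slices/volumes normalise to
   zeros with a logged warning instead of an exception — background-only
   edge slices are routine.
5. **Brain extraction**: the T1 U-Net produces per-pixel brain memberships;
   thresholding (default 0.5) gives the brain mask, which is transferred to
   FLAIR (voxels outside set to 0).
6. **Bias correction** inside the brain mask: a low-order 3D polynomial
   (default order 3) is fit to log-intensities by least squares,
   exponentiated into a strictly positive multiplicative field, normalised
   to mean 1 over the mask, and divided out. The fit is made robust by
   iteratively re-fitting on inliers (residuals within 2.5 robust SDs):
   anatomy such as lesions produces heavy-tailed residuals against the
   smooth field and would otherwise bend the surface — the same reason
   production bias-field estimators use robust or histogram-based fitting.
   A polynomial surface was chosen
   over a full N4-style B-spline fitter to keep the estimator
   self-contained and analytically testable; the contract (smooth,
   positive, mean-1 multiplicative field) is the same, and an external N4
   implementation can be substituted behind the same interface.
7. **Tissue-referenced rescale**: the stripped, bias-corrected FLAIR is
   scaled so the median of in-brain intensities maps to 0.5 (clipped to
   [0, 1]). The median is normal brain tissue whether or not lesions are
   present, so the lesion network sees the same tissue scale on every
   subject; anchoring at the maximum or a high percentile would be
   lesion-dependent and, on a lesion-free brain, would stretch normal
   tissue up to the intensity the network associates with lesions.
8. **Lesion segmentation**: the FLAIR U-Net yields lesion memberships;
   thresholding (default 0.5, see threshold calibration below) and
   intersection with the brain mask give the lesion mask. The mask is
   resampled (nearest) back to the isotropic grid, where voxel count ×
   voxel volume = lesion load in mm³.

All cubic-spline resampling clips its output to the input intensity range:
spline ringing at sharp edges would otherwise create out-of-range voxels
that destabilise any normalisation keyed to extrema. The training-data
preparation applies the same operations in the same order as the pipeline
(with the generator's known transform standing in for the estimated
registration), so training and inference inputs share one distribution.

Every step appends its parameters to the result's provenance list, so a run
is reproducible from its outputs.

## Network

Both tasks share one U-Net implementation configured differently. The
encoder applies `depth` blocks of [3×3 conv → (BatchNorm) → ReLU] ×2
followed by 2×2 max-pooling (stride 2); channel widths double per level
from `base_channels`, capped at `max_channels`. The decoder mirrors the
encoder with non-learned 2× nearest-neighbour up-sampling, concatenation of
the matching encoder feature map, and two convolutions. The head is a 1×1
convolution with a sigmoid. Convolutions use 'same' padding, so feature
maps never shrink and skips concatenate without cropping. The input side
length must be divisible by 2^depth. The reference full-size configuration
is depth 5, base 16 (widths 16→256) on 256×256 inputs; phantom-scale
experiments use depth 3, base 8 (widths 8→64) on 64×64.

The head bias is initialised to the logit of `foreground_prior`, the
standard initialisation for rare-foreground segmentation: the network
starts at the class prior instead of at p = 0.5. This matters here because
Adam's per-step parameter change is bounded by roughly the learning rate,
so with few optimisation steps a zero-initialised head would spend most of
the budget just driving the output down to the background rate. The lesion
net (foreground ≈ 0.6%) uses prior 0.01. The brain net keeps the balanced
default 0.5: at 13% foreground the saving is small, and starting the output
at the decision threshold (0.5) means even weak early discrimination
already yields sharp masks, which empirically converges fastest at this
step budget.

The layer kit (convolution via im2col + BLAS matmul, batch normalisation
with running statistics, max-pooling, up-sampling, Adam) is implemented in
NumPy with explicit backpropagation, float32, NHWC layout; gradients are
verified against numeric directional derivatives in the test suite. At
exact ReLU kinks the one-sided convention ReLU'(0)=0 is used, and pooling
ties route gradient to the first maximum — the usual subgradient choices.

## Training protocol

Binary cross-entropy loss (predictions clipped to [1e-7, 1−1e-7]), Adam
with learning rate 0.001, batch size 32, 60 epochs, all slices of the
training subjects shuffled each epoch with the run seed. Per-epoch loss and
— unless disabled for speed — Dice, accuracy, precision, sensitivity and
specificity on train/validation sets are logged, all computed by the
metrics module on predictions binarised at 0.5. Model evaluation uses
repeated seeded 80:20 splits at the subject level (a subject's slices never
straddle the split), 10 repeats by default; the phantom-scale experiments
in the tests and the acceptance script run 3 repeats, training the brain
net on six mid-volume slices per case (its task converges in half the
steps) and the lesion net on all sixteen (the rare-class take-off needs
the larger step count to be robust to initialisation), which keeps the
full suite within single-CPU reach while leaving the optimisation protocol
itself untouched. No augmentation, early
stopping or LR schedule is used. Training is deterministic given the seed.

## Threshold calibration

A sigmoid head trained for a few hundred optimisation steps is
systematically under-confident at lesion boundaries: memberships cross 0.5
inside the true lesion, so a fixed 0.5 threshold under-counts volume by
10–20% on unseen subjects. `calibrate_lesion_threshold` therefore picks the
operating point by minimising the summed per-case |predicted − reference|
volume over a calibration set of phantoms run through the full pipeline
(estimated registration, predicted brain mask — the deployed conditions).
The calibration set includes lesion-free phantoms, which penalise
thresholds low enough to fire on normal-appearing tissue; it is disjoint
from any evaluation data. With a well-converged network the calibrated
threshold sits near 0.5 and calibration is a no-op; with a short training
budget it repairs the boundary bias without touching the model.

## Evaluation

Five overlap measures from the voxel-wise confusion table: Dice
2TP/(2TP+FP+FN), accuracy, precision, sensitivity, specificity. Comparisons
of two empty masks define the vacuous ratios (Dice, precision, sensitivity)
as 1 and flag them via `ConfusionCounts.degenerate_metrics()` — lesion-free
subjects are legal inputs, and silently returning 0 would misreport a
correct prediction. Volumetric agreement between automatic and reference
volumes is summarised Bland–Altman style (bias = mean(auto − manual),
limits of agreement bias ± 1.96·SD with SD at ddof = 1) plus the squared
Pearson correlation (R², matching the usual correlation-panel convention,
not a concordance coefficient).

## Phantoms

Each phantom is a 64×64×16 grid at 1 mm³: an ellipsoidal brain (semi-axes
22×18×6 mm), a 2.5 mm skull-like shell (bright on T1, suppressed on
FLAIR), and 1–4 spherical lesions of radius 2–4.5 mm rejection-sampled to
lie fully inside the brain — hypointense on T1 (0.35 vs brain 0.60),
hyperintense on FLAIR (0.90 vs brain 0.50). Nuisances injected on top of
the clean geometry: additive Gaussian noise (σ = 0.02 on a ~0–1 intensity
scale), a smooth random polynomial bias field of order 2 spanning ±20%
applied multiplicatively to both modalities, and a random in-plane rigid
misalignment of FLAIR (|tx|,|ty| ≤ 3 mm, |θ| ≤ 0.05 rad). Ground-truth
brain and lesion masks stay clean, and the true lesion volume is the exact
voxel count of the analytic union of spheres — the anchor for all
volumetry checks. Generation is bit-reproducible from the seed; datasets
derive per-case seeds from one root seed.

What the phantoms do not emulate: MR sequence physics, partial-volume
fractions at tissue boundaries, Rician noise statistics, anatomical
variability, or confluent irregular lesion shapes. Passing the phantom
suite therefore demonstrates that the pipeline's machinery (preprocessing
recovery, learning, quantification, agreement analysis) is correct, not
that the trained phantom weights transfer to clinical scans; training on
real cohorts (e.g. NFBS / ISBI 2015 / MICCAI 2016) is supported through the
same CLI but deliberately outside the test suite.

## Numerical choices and edge cases

- Resampling: cubic spline for images, nearest for masks, everywhere;
  probability maps are clipped back to [0, 1] after spline resampling.
- Registration parameters are optimised in a space where 1 unit ≈ 1 mm
  (θ scaled by a 50 mm lever arm) so Powell's steps are isotropic.
- Bias estimation shifts intensities if any voxel inside the mask is ≤ 0
  before the log; the returned field is positive by construction (exp).
- `as_binary_mask` refuses any voxel farther than `tol` from {0, 1} — it
  exists to load manual annotations, and accepting grey values would hide
  file mix-ups.
- Empty brain mask from an untrained/failed brain net: bias correction is
  skipped (nothing inside the mask to fit); the lesion mask is then forced
  empty by the containment rule lesion ⊆ brain.
- Lesion volume is always quantified on the isotropic grid, not the
  network's processing grid, so the reported number does not depend on the
  in-plane resize.

## Known limitations

- One rigid transform per volume (slices paired by index); through-plane
  motion and per-slice wobble are out of scope.
- The polynomial bias model cannot represent high-frequency coil
  inhomogeneity; order ≥ 4 fits become ill-conditioned on small masks.
- Volume is reported without connected-component analysis (no lesion
  counts or per-lesion sizes).
- NumPy training is practical at phantom scale (64×64, depth 3) on one CPU;
  the full-size depth-5/256×256 configuration is exposed but expects hours,
  not minutes, without an accelerated backend.
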