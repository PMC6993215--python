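# Methods

This note documents the models and procedures implemented in `mpsseg`,
the parameters that matter, the synthetic data the package is validated
on, and the numerical and design choices made where the method left
room.

## Data model

Volumes follow the BraTS conventions: four co-registered, skull-stripped
MR sequences (T1, T1C, T2, FLAIR) per case at 1 mm³, stored as NIfTI in
a `<case>/<case>_{t1,t1ce,t2,flair,seg}.nii.gz` layout.  Shapes are
quoted slice-first (axial slice axis leading; a full scan is
155 × 240 × 240).  Raw labels are {0 background, 1 NCR/NET, 2 ED, 4 ET};
they are mapped to contiguous class indices {0, 1, 2, 3} =
[background, NCR/NET, ED, ET] at load time (softmax channels need
contiguous indices) and mapped back on write.  Evaluation merges labels
into the nested regions WT = {1,2,4}, TC = {1,4}, ET = {4}; nesting
ET ⊆ TC ⊆ WT therefore holds for any label volume by construction.
Voxel coordinates are 0-based.

Preprocessing is intentionally minimal (inputs arrive registered and
skull-stripped): a center crop around the bounding box of nonzero FLAIR
(default target 146 × 192 × 152 on full-size scans) discards black
background, with the crop offsets retained so predictions re-embed into
the original frame; and each channel is standardized to zero mean / unit
variance *over its nonzero voxels only*, zeros staying exactly zero.  A
channel whose nonzero voxels are constant standardizes to all-zeros; one
with fewer than two nonzero voxels is rejected as degenerate.

## Network

Encoder–bottleneck–decoder FCN on 2D slices, four input channels, four
softmax outputs:

* encoder: `depth` blocks of two 3 × 3 same-padded convolutions + ReLU,
  feature maps doubling per block from `base_filters`; 2 × 2
  spatial-max-pooling between blocks;
* bottleneck: two further convolutions (`base_filters · 2^depth` maps);
* decoder: mirror of the encoder; each level first spatial-max-unpools
  using the index stack recorded by the matching pooling layer, then
  concatenates the same-level encoder output, then applies two
  convolutions; a final 1 × 1 convolution + softmax yields per-pixel
  class probabilities.  Output H × W always equals input H × W.

**Spatial-max-pooling/unpooling.**  Pooling records, per window and per
feature map, the argmax position (ties broken to the first position in
row-major order, making the pair deterministic); unpooling places each
value back at its recorded position with exact zeros elsewhere.  On the
nonnegative (post-ReLU) maps the layers actually see,
`pool(unpool(y, idx)) == y` and `unpool(pool(x))` is nonzero exactly at
the argmax positions.  The tensor entering an unpooling layer carries a
multiple of the recorded index maps (the bottleneck doubles the top
encoder width); index maps are shared across equal channel groups.
Setting `use_indices=False` replaces unpooling by nearest-neighbor
upsampling — the "plain pooling" ablation baseline.

The implementation is pure numpy (im2col convolutions, manual
backpropagation, Adam) — exact, deterministic, and fast enough at the
problem sizes this package targets; gradient correctness is verified
against finite differences in the test suite.  Note that finite
differences are only meaningful away from ReLU kinks: with
zero-initialized biases, regions zeroed by unpooling sit exactly on the
kink, so the gradient checks randomize biases.

**Training.**  Xavier-uniform initialization; Adam.  Full-scale defaults
are learning rate 1e−4, batch 16, 20 epochs.  Patches (default
128 × 128 at full scale) are sampled per plane with the brain
constraint: the drawn center pixel's FLAIR intensity must strictly
exceed the volume-wide FLAIR minimum (the black surround), and the patch
window is shifted inward so no padding intensity is ever invented.
Per-plane patch budgets are proportional to 111,690 : 142,160 : 118,400
(axial : coronal : sagittal), rescaled by a single factor.  Augmentation
applies, per patch per epoch, a random rotation (uniform 0–10°), shifts
(uniform within ±10 % of the patch size), and horizontal/vertical flips
(probability 0.5 each); labels get the identical transform with
nearest-neighbor interpolation.  Validation splits are made at the case
level (default 20 %), never at the patch level, to avoid leakage.

## Losses

All losses act on `(C, N)` arrays: probabilities `P` (simplex columns)
and one-hot ground truth `G`.  With `wa_c = 1/(Σ_n G_cn + ε)²`
(adaptive, per mini-batch) and static weights `ws_c`:

* `WGDL = 1 − 2 Σ_c wa_c Σ_n G_cn P_cn / Σ_c wa_c Σ_n (G_cn + P_cn)` ∈ [0, 1];
* `WLL = −(1/N) Σ_n Σ_c ws_c G_cn log(P_cn + ε)`;
* aggregated loss `λ_d·WGDL + λ_l·WLL` with default `λ_d = λ_l = 1`
  (the combination weights are a free choice; equal weights treat the
  region-level and pixel-level views symmetrically);
* multiclass focal loss `−(1/N) Σ (1−P)^γ G log(P + ε)`, default γ = 2,
  as an imbalance-handling comparator.

ε = 1e−6 guards empty classes and `log 0`; it sits inside the log and
inside the squared volume sum.  Analytic gradients `∂L/∂P` are provided
for the training loop and are finite-difference-checked.

**Static weights.**  `ws_c` is computed once from the training patches
as inverse class frequency raised to the power 0.5 and normalized to
mean 1.  The square-root damping matters: with raw inverse frequencies
on a ~98 %-background dataset the background weight becomes ~0.01, so an
optimizer can park in a solution that spills edema over healthy tissue
almost for free; damping keeps the background penalty non-negligible
while still up-weighting the rare classes.

## Multi-planar fusion

A volume is resliced along a plane by permuting axes so that plane's
slicing axis leads (axial (0,1,2), coronal (1,0,2), sagittal (2,0,1));
reorientation round trips are exact.  Each plane's network segments
every slice at full resolution (inputs reflectively padded to a multiple
of `2^depth` and outputs cropped back), the per-slice maps are stacked
and restored to the axial frame, and the three maps are averaged
voxel-wise.  The mean of simplex points stays on the simplex; fusion is
symmetric in its arguments.  Discrete labels are the per-voxel argmax,
ties resolving to the lower class index (background).

## Dense 3D CRF

Energy of a labeling `l` over all voxel pairs (Potts compatibility
`[l_i ≠ l_j]`):

    E(l) = Σ_i −log p_i(l_i)
         + Σ_{i<j} [l_i ≠ l_j] (ω₁·P(i,j) + ω₂·f(i,j)),

with smoothness `P(i,j) = exp(−Σ_d |s_id−s_jd|²/σα_d²)` and appearance
`f(i,j) = exp(−Σ_c |I_ic−I_jc|²/σγ_c² − Σ_d |s_id−s_jd|²/σβ_d²)`.
Defaults (selected by grid search at full scan scale): ω₁ = 2.5,
ω₂ = 4.0, σα = (24, 24, 24), σβ = (17, 12, 10), σγ = 8, five mean-field
iterations.  Intensity features are the standardized intensities scaled
by 50 and clipped to ±127, putting σγ = 8 on an 8-bit-like scale.

Inference is parallel mean-field: `Q ← p`, then per iteration
`m_i(l) = Σ_{j≠i} k(i,j) Σ_{l'≠l} Q_j(l')` and
`Q_i(l) ∝ p_i(l)·exp(−m_i(l))`.  With ω₁ = ω₂ = 0 the labels equal the
unary argmax exactly.  Two execution paths:

* **dense** (small instances): the full pairwise kernel matrix,
  unnormalized, exactly as written above.  The same machinery powers the
  `crf_energy` oracle (explicit pair sums, capped at 4096 voxels), which
  tests compare against independent re-implementations and exhaustive
  enumeration on tiny grids.
* **filtered** (full volumes): the smoothness message is an exact
  separable Gaussian correlation (unnormalized 1D kernels
  `exp(−t²/σ²)`, truncated at 2.5σ, zero beyond the volume); the
  appearance message uses a codebook bilateral approximation — the
  4-channel intensity field is vector-quantized by k-means and the
  bilateral sum becomes Σ_k (affinity to codeword k) × (spatial blur of
  Q restricted to codeword k).  The k-means subsample is stratified by
  unary-argmax class (≤ 5000 voxels per class, 12 codewords by default):
  without stratification, classes occupying a fraction of a percent of
  the volume never receive a centroid and the appearance kernel cannot
  protect them.  On this path each kernel's messages are normalized per
  voxel to a weighted average, as standard dense-CRF implementations do;
  otherwise the pairwise sum grows with the volume and drowns the unary
  term.

Updates are parallel (not sequential); the method reference leaves the
order unspecified.  Mean field carries no convergence guarantee on the
energy, but the tests verify on random small instances that the refined
labeling's energy never exceeds the unary argmax labeling's.

**Scale of the spatial kernels.**  The default σα/σβ were chosen for
full-size scans.  On reduced volumes the pipeline scales them per axis
by `shape / (155, 240, 240)` (`CRFParams.scaled_to`): the phantom's
anatomy shrinks proportionally, and keeping full-size kernel widths
would let the smoothness kernel span half the volume and erase thin
structures (the enhancing rim, the necrotic core) whenever the unaries
are less than certain.  `CRFParams()` itself keeps the full-scale
defaults.

## Metrics

Per region (WT/TC/ET): Dice `2|P∧G|/(|P|+|G|)`, sensitivity `|P∧G|/|G|`,
specificity `|P⁰∧G⁰|/|G⁰|`, and surface Hausdorff distances in mm.
Surfaces are mask voxels with ≥ 1 face-adjacent (6-connectivity)
non-mask neighbor, the volume border counting as outside; directed
distances are Euclidean via a KD-tree, scaled by the voxel spacing.
Classic Hausdorff is the max of the two directed suprema; Hausdorff95 is
the max of the two directed 95th percentiles (hence HD95 ≤ HD).
Conventions for degenerate cases (common evaluation practice): both
masks empty → Dice/sensitivity 1; exactly one empty → Dice 0 and the
distance is a NaN sentinel, reported distinctly rather than as 0.

## Synthetic phantoms

A phantom is a zero-intensity background, a healthy-brain ellipsoid
(nonzero intensity), and a nested tumor of concentric ellipsoids:
necrotic core (label 1) inside enhancing shell (label 4) inside edema
(label 2).  Defaults: 64³ voxels, brain semi-axes 0.42 of the volume,
tumor semi-axes ED (14, 16, 12) / TC (9, 10, 7.5) / NCR (4.5, 5, 3.5),
Gaussian intensity noise σ = 6 against compartment separations of ≥ 18
in the discriminating channel (so a small network can learn the task in
minutes; the contrast is configurable downward for harder tests).  The
intensity table encodes the qualitative contrasts of real scans — edema
brightest in FLAIR, enhancing rim brightest in T1C, necrosis dark in
T1C.  Cohorts jitter radii (±20 %), intensities (±5 %) and tumor
centers, with per-case seeds derived from one base seed; draws violating
the nesting invariant are resampled with bounded retries.  Tumor voxels
are < 10 % of the volume, reproducing the background-dominance regime
the losses target.  An optional low-frequency multiplicative bias field
(off by default) stresses the standardization.

What phantoms do **not** emulate: real anatomy and texture, infiltrative
or multifocal tumor shapes, partial-volume boundaries, acquisition
artifacts, inter-scanner variation.  Passing phantom tests shows the
pipeline's machinery is correct and that the method's claimed behaviors
(fusion ≥ single planes, CRF removes isolated regions without degrading
overlap) hold in a controlled setting — not that the trained weights
transfer to clinical data.

## Scaled-down study sizes

The test suite and `scripts/acceptance.py` run a reduced profile chosen
to exercise every stage in a few CPU-minutes: 64³ phantoms, 10 training
cases (20 % case-level validation) + 3 held-out cases, ≈ 200 patches of
32 × 32 per plane, network depth 2 with 8 base filters, 15 epochs at
learning rate 3e−3 (a freshly initialized tiny network on a few hundred
patches needs a larger step than the full-scale 1e−4 to converge within
a few epochs), and volume-scaled CRF kernels as above.  Typical results:
held-out whole-tumor Dice ≈ 0.95–0.99 per single plane, ≈ 0.98 fused,
≈ 0.999 after CRF refinement.

## Known limitations

* The dense path is O(V²) and capped; the filtered appearance kernel is
  an approximation whose fidelity depends on the codebook (exact when
  intensities coincide with their codewords, as in noise-free phantoms).
* Mean-field updates are parallel and undamped; strongly coupled
  instances can oscillate in principle (not observed at the default
  iteration count).
* Training is single-threaded numpy; full-scale BraTS training (depth 4,
  32 base filters, 10⁵ patches of 128 × 128) is out of reach without a
  GPU framework, so full-scale claims are not reproduced here.
* The pool/unpool inverse identities hold on nonnegative activations
  (always the case after ReLU), not for arbitrary signed inputs.
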