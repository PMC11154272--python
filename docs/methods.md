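# Methods

This note records the models, conventions and numerical choices behind
`dualct`, in the order data flows through the pipeline.

## Acquisition model and geometry

The scanner is a rotating-source fan beam with a **flat, equidistant
detector**.  Defaults mirror a realistic protocol: 512 views uniformly
over 360°, source–detector distance 1280 mm, source–isocenter distance
640 mm, 720 detector elements of 1 mm pitch.  View *k* places the source
at angle *k*·(360/​n_views)° counterclockwise from the +x axis of the image
frame; the rotation isocenter coincides with the image center, and image
row index follows +y.  With these constants the field of view inscribed in
the fan at the isocenter has diameter `n_det · pitch · (SID/SDD)` =
360 mm, so the default pixel size for a 512² grid is 0.703125 mm
(`default_pixel_size` inscribes the fan in the image).

The projector evaluates `g(k, u) = ∫ f dl` along each source→detector ray
by sampling at `pixel_size/2` steps with bilinear interpolation — a
Joseph-style accuracy/speed compromise validated in the tests against a
denser independent ray-marcher and against the analytic disk integral
2 r μ (agreement well within 1 %).  The matching back-projector scatters
with the same sample points and weights, making `Aᵀ` the **exact
transpose** of the discrete `A`; the dot-product identity holds to
~1e-7 relative.

Units: images are linear attenuation per mm (water ≈ 0.02 /mm at CT
energies); sinograms are attenuation·mm (dimensionless optical depth).

## Photon-noise model

Mixed Gaussian+Poisson corruption is applied to the *sparse* sinogram
before view interpolation: with `M = max(s)`,

    t     = exp(−s / M)                      (transmittance)
    N     = Poisson(I0 · t) + Normal(I0 · m, I0 · var)
    s'    = −log(clamp(N, 1e-8) / I0) · M

Defaults: `I0 = 5e6`, `m = 0`, `var = 0.05` (training setting); robustness
sweeps use `I0 = 1e6, 5e5, 1e5`.  This count-domain formulation makes the
log-restoration dimensionally consistent and the corruption vanish as
`I0 → ∞, var → 0` (verified to < 1e-3 relative at `I0 = 1e12`); one bin is
unbiased to within Monte-Carlo resolution at the training setting.  The
clamp floor only matters at photon starvation (`N ≤ 0`), where the
log-domain value saturates instead of becoming undefined.

## Filtered back-projection

Standard weighted-filter-backproject scheme for equidistant fan-beam
data, computed on a virtual detector through the isocenter: cosine
pre-weighting `SID/√(SID² + t²)`, spatial-domain band-limited Ram-Lak
kernel (`h(0) = 1/4τ²`, `h(odd n) = −1/(nπτ)²`, even taps zero) applied by
FFT with zero-padding to the next power of two ≥ 2·n_det, then
backprojection with inverse-square magnification weighting `1/U²` and
linear detector interpolation, scaled by `Δβ/2` for the 360° scan.  No
apodization window is applied to the ramp.  A noiseless 512-view scan of
a piecewise-constant ellipse phantom reconstructs with interior rRMSE
≈ 0.5 % at 128²; the error grows strictly as views drop to 128/64/32.

Because every step is linear, the backward pass of the FBP embedding
layer is the operator transpose, realized by replaying the same discrete
operations in adjoint order (detector scatter → self-adjoint filtering →
cosine weighting).  The filtering window selection is handled as an
explicit embed/restrict pair so the transpose is exact, not approximate.

## Haar wavelets

The four 2×2 directional kernels are applied non-overlapping with stride
2 and scaled by ½, i.e. **orthonormal Haar**: analysis and synthesis use
the same bank, round trips are exact to machine precision and energy is
conserved, for square and rectangular (sinogram-shaped) inputs alike.
The first kernel index is the row (vertical) axis, so the LH band
responds to vertical variation.  A brute-force convolve-and-downsample
oracle and PyWavelets (up to its detail-band sign convention) pin the
convention down in the tests.  The same code path runs on numpy arrays
and autodiff tensors, which is how the networks differentiate through
the transform.

## Network wiring

The figure-level topology of the published architecture is not fully
recoverable from text, so the branch wiring is fixed here as follows
(channel multiples {1, 2, 4, 8, 12}·C, C = 32 at full scale):

* trunk: input → RCU(C) → stride-2 RCU(2C) → stride-2 RCU(4C);
* low branch: concat(trunk, ll2) → RCU(8C) → RCU-Att-Resblock(8C) →
  output RCU(C) → 3×3 conv → residual added to ll2;
* LV2-high branch: stacked (lh2, hl2, hh2) → RCU(4C) → MFNF fed by the
  8C low features → 3×3 conv → residual added to the bands;
* LV1-high branch (half resolution): stacked level-1 bands → RCU(2C) →
  MFNF fed by the bilinearly 2×-upsampled concatenation of the 8C low
  features and the 4C LV2 fusion output (12C aggregate) → residual.

Supporting decisions:

* **Residual band prediction with zero-initialized emitting
  convolutions** — a freshly built network is exactly the identity map.
  This stabilizes early training (the model starts at the
  FBP-of-interpolated baseline rather than at noise) and gives the
  identity-stub mode an exact anchor.
* **Recurrent state threading** — each RCU passes (h, c) to the next in
  its chain; the first receives zeros; time-step count is 1.  States
  crossing a channel change are adapted by a pointwise convolution, and
  average pooling bridges stride-2 resolution changes (the source
  publication is silent on both).
* **Attention** operates across channels (channel×channel score matrix,
  softmax over keys, scaled by √d_k with d_k = channel count of K), which
  keeps cost linear in spatial size.  In SNFM the "residual attention
  feature" driving the γ/β modulation convs is the attended feature plus
  the high-frequency input.  SNFM's aggregation convolutions project the
  low features to the fusion width before attention.
* **SDNet output** is globally residual to the interpolated sinogram (a
  consequence of per-band residuals), resolving an ambiguity in the
  source description in favor of the stable choice.
* Batch norm uses batch statistics in training (batch size 1 ⇒ spatial
  statistics) and running averages (momentum 0.1) at evaluation.  Weight
  initialization is He-normal from a single seeded generator recorded in
  the model config; biases start at zero.
* Ablation axes: `use_conv_lstm=False` reduces every RCU to its
  CBR + output-conv path; `use_acstf=False` replaces soft thresholding
  with ReLU; `fusion_mode ∈ {snfm, sum, concat}` switches the MFNF fusion
  stage (sum-mode projection is bias-free so zero low features reduce
  exactly to the high path).

## Losses and metrics

`L = MAE(sinogram) + MSE(image) + α·L_edge`, α = 0.02.  The LoG kernel is
the sampled `−1/(πσ⁴)(1 − r²/2σ²)exp(−r²/2σ²)` on a 5×5 grid,
mean-subtracted to kill the DC response; σ defaults to 1.0 px, the
conventional value for a 5×5 support.  The edge term penalizes
second-derivative disagreement and counteracts MSE over-smoothing.

Metrics: RMSE = Frobenius-norm error / √(pixel count) (reduces to the
‖·‖/N form on square images); PSNR = 20·log10(MAX/RMSE) with MAX the
maximum over both images (identical images give +∞, documented
sentinel); SSIM in its global whole-image form with population
statistics and c₁ = (0.01R)², c₂ = (0.03R)² — deliberately the printed
formula rather than the windowed variant; rRMSE = 100·‖I−I_ref‖/‖I_ref‖.
Sharpness: AG = mean √((Δrow² + Δcol²)/2) over first differences,
SF = √(RF² + CF²) with RF/CF the RMS row/column first differences.
Metrics are computed on images linearly mapped to [0, 1] over the
dataset's attenuation window (default [0, 0.04] /mm), since display
windows in HU do not transfer to synthetic attenuation units.

## Synthetic phantoms

Each phantom is a body-outline ellipse (semi-axes 0.55–0.85 of the field
of view) painted with 3–7 internal ellipses of randomized pose and
attenuation plus at least one small insert of ±(0.004–0.012) /mm
contrast, all piecewise-constant with sharp boundaries — the structure
the high-frequency branches and edge loss exist for.  Edges are
anti-aliased by 4× coverage supersampling so discrete line integrals
track the continuous object.  Everything is deterministic in
(seed, index).  What the generator does **not** emulate: anatomical
texture, smooth attenuation gradients, high-attenuation bone/metal,
scanner effects beyond photon noise (scatter, beam hardening, crosstalk).
Passing tests therefore demonstrate correct mechanics and learnability of
piecewise-smooth structure, not clinical-grade performance.

## Training protocol and problem sizes

Adam (β = 0.9/0.999), initial LR 1e-3 decayed by a multi-step schedule to
5e-4 (single milestone, chosen to match the stated endpoint values),
25 epochs and batch size 1 at full scale.  Validation runs each epoch and
the best-validation checkpoint is kept (the alternative — last epoch —
is not distinguishable from the source description; best-validation is
the recorded choice).  A per-run seed covers phantom generation, weight
initialization, noise draws and sample order, and is stored in the
checkpoint, giving bitwise-reproducible first steps.

The package's study configuration — used by the test suite and
`scripts/acceptance.py` — is a desk-scale instance chosen so the whole
pipeline runs comfortably on one CPU: 96/16/16 phantoms at 64², geometry
scaled to 128 full views and 180 detectors, 32 sparse views, C = 8, and
288 optimizer steps (3 epochs, milestone at epoch 2).  Under these
conditions the model exceeds the FBP-of-interpolated baseline by ≈ 7 dB
held-out PSNR.  Full-scale 512² manifests are config-selectable but not
exercised by the tests.

## Numerical choices and degenerate inputs

* Projector/FBP internals run in float64; network training in float32
  (float64 selectable via the model config, used by the
  finite-difference gradient tests).
* Soft thresholding is composed as `relu(x−τ) − relu(−x−τ)`, which is
  exact including the boundary and differentiable almost everywhere.
* Position normalization adds 1e-5 to the variance before the root;
  batch norm uses the same epsilon.
* View interpolation treats the view axis as periodic over 360° and
  never resamples the detector axis; retained original angles reproduce
  their values exactly.
* All-zero sinograms are rejected by the noise model (MAX(s) = 0);
  non-square images, odd wavelet dimensions, non-divisor view counts and
  geometry mismatches raise `ValueError` with named fields.

## Known limitations

Monochromatic pencil-ray physics only (no scatter, spectra, or 3-D
cone-beam geometry); reconstruction is analytic FBP rather than
iterative; the Conv-LSTM runs a single time step by design; attention is
channel-wise only.  The numpy autodiff engine executes eagerly on one
core — adequate at desk scale, not a GPU training substrate.  The exact
figure-level wiring of the published architecture is a reconstruction
(documented above), not a verbatim copy.
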