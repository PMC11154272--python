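# dualct — dual-domain sparse-view CT reconstruction

Sparse-view CT (SVCT) lowers X-ray dose by acquiring far fewer projection
angles than Nyquist-complete scanning requires.  The missing views make the
inverse problem ill-posed: filtered back-projection (FBP) images of sparse
sinograms are dominated by streak artifacts.  `dualct` implements a
dual-domain learned reconstruction for fan-beam SVCT, together with
everything needed to study it without clinical data: a fan-beam projector
with an exact adjoint, a mixed Gaussian+Poisson photon-noise model,
flat-detector FBP, a synthetic phantom generator, a training/evaluation
pipeline and a CLI.  It is aimed at researchers prototyping tomographic
reconstruction networks on CPUs, at desk scale.

## Model

The acquisition model is the linear inverse problem `g = A f + n`, where
`f` is the attenuation image, `A` the fan-beam projection operator
(line integrals `∫_L f dl` from the Beer–Lambert law), and `n` noise.  The
reconstruction network is

```
sparse sinogram ──bilinear view interpolation──► SDNet ──FBP layer──► IDNet ──► image
```

* **SDNet / IDNet** are structurally identical single-domain networks.
  Each decomposes its input with a two-level orthonormal Haar DWT and
  restores the frequency groups in three branches: the level-2
  low-frequency band (trunk + channel self-attention residual block), and
  the level-2 / level-1 detail bands, each predicted as a residual
  correction.
* **RCU** (recurrent convolution unit): conv–batch-norm–ReLU followed by a
  single Conv-LSTM cell whose gates `f, i, o = σ(W ⊗ (x, h))`,
  `c' = tanh(W_c ⊗ (x, h))`, `c_t = f⊙c_{t-1} + i⊙c'`, `h_t = o⊙tanh(c_t)`
  use factored 1×1-conv → 3×3-depthwise transforms; hidden/memory states
  are threaded between successive RCUs in a branch.
* **MFNF** fuses low-frequency context into the high-frequency branches
  through channel-wise self-attention (`W = softmax(QKᵀ/√d_k)`, `A = WV`)
  and a position-normalization/modulation step
  `x_H = γ_H · (x_L − μ_L)/σ_L + β_H`, followed by **ACSTF** — adaptive
  per-channel soft thresholding `τ = Sigmoid(z) ⊙ GAP(|x|)` learned by a
  squeeze-and-excitation path.
* **FBP layer**: flat-detector weighted-filter-backproject FBP.  It is
  linear, and its backward pass is the exact operator transpose, so
  gradients of the image-domain loss reach SDNet.
* **Loss**: `L = ‖S − S_ref‖₁ + ‖I − I_ref‖₂² + α · L_edge` with
  `α = 0.02`, where `L_edge` is the mean absolute difference of the images
  after 5×5 Laplacian-of-Gaussian filtering.

The learned components run on a compact numpy reverse-mode autodiff engine
included in the package (`dualct.autodiff`), verified against finite
differences in the test suite.

## Worked example

Build a desk-scale dataset (96 train / 16 val / 16 test phantoms at 64×64,
128 full views subsampled to 32), train for 288 steps and evaluate:

```python
from dualct import (DatasetManifest, ModelConfig, TrainConfig,
                    build_dataset, evaluate, train)
from dualct.phantom import PhantomDataset

build_dataset(DatasetManifest(), "desk.h5")      # defaults = study setup
ds = PhantomDataset("desk.h5")
ckpt = train(ds, ModelConfig(base_channels=8, init_seed=1),
             TrainConfig(epochs=3, seed=1, milestones=(2,), max_steps=288))
report = evaluate(ckpt, ds, split="test")
for method, res in report["methods"].items():
    agg = res["aggregate"]
    print(method, round(agg["psnr"]["mean"], 2), "dB,",
          "rRMSE", round(agg["rrmse"]["mean"], 2), "%")
```

A run of exactly this configuration printed:

```
fbp_interp 29.06 dB, rRMSE 8.86 %
model 35.94 dB, rRMSE 4.12 %
```

i.e. the learned dual-domain reconstruction beat the FBP-of-interpolated
baseline by 6.9 dB PSNR and halved the relative error on held-out
phantoms.  (At 32 of 128 views the baseline images show strong streaks;
the model removes them and restores the low-contrast inserts.)

The same workflow is available from the shell:

```
dualct simulate --config config.yaml --views 32 --out desk.h5
dualct train    --config config.yaml --data desk.h5 --out ckpt.npz
dualct evaluate --checkpoint ckpt.npz --data desk.h5 --out report.json
dualct reconstruct --checkpoint ckpt.npz --input sample.h5 --out recon
```

## Layout

| module | contents |
| --- | --- |
| `dualct.geometry` | scan geometry, projector/adjoint, view subsampling and interpolation, noise model |
| `dualct.fbp` | flat-detector fan-beam FBP and its transpose |
| `dualct.wavelet` | two-level orthonormal Haar DWT/IDWT (numpy and autodiff paths) |
| `dualct.network` | Conv-LSTM, RCU, attention/fusion blocks, single- and dual-domain networks |
| `dualct.losses_metrics` | LoG edge loss, total loss, PSNR/SSIM/RMSE/rRMSE/AG/SF |
| `dualct.phantom` | phantom generator and HDF5 dataset builder |
| `dualct.pipeline` | Adam, training loop, checkpointing, evaluation |
| `dualct.cli` | `dualct` command-line entry point |
| `dualct.autodiff` | the reverse-mode engine behind the learned components |

See `docs/methods.md` for the modeling choices, defaults and limitations.
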