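"""Training loop, evaluation harness and checkpointing.

Training minimizes the dual-domain objective (sinogram MAE + image MSE +
weighted LoG edge loss) with Adam and a multi-step learning-rate decay.
Images and sinograms are scaled by the upper attenuation-window bound
during optimization so both loss terms operate on O(1) quantities; the
scaling is linear and commutes with the FBP layer.  The best-validation
epoch is kept.  Evaluation reports the standard metric set for both the
FBP-of-interpolated baseline and the model, aggregated as mean +/- std
over a split, on images normalized to [0, 1] over the declared
attenuation window.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fbp import FBPConfig
from .geometry import ScanGeometry, Sinogram
from .losses_metrics import (LossConfig, aggregate_metrics, compute_metrics,
                             normalize_window, total_loss)
from .network import DualDomainNet, ModelConfig
from .phantom import DatasetManifest, PhantomDataset


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 1
    initial_lr: float = 1e-3
    final_lr: float = 5e-4
    milestones: tuple = (15,)
    betas: tuple = (0.9, 0.999)
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    max_steps: Optional[int] = None  # cap on optimizer steps (scaled runs)

    def __post_init__(self):
        if not (0 < self.final_lr <= self.initial_lr):
            raise ValueError("require 0 < final_lr <= initial_lr")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    def to_dict(self):
        return {"epochs": self.epochs, "batch_size": self.batch_size,
                "initial_lr": self.initial_lr, "final_lr": self.final_lr,
                "milestones": list(self.milestones), "betas": list(self.betas),
                "seed": self.seed, "max_steps": self.max_steps,
                "loss": {"alpha": self.loss.alpha, "sigma": self.loss.sigma}}

    @classmethod
    def from_dict(cls, d):
        loss = LossConfig(**d.get("loss", {}))
        return cls(epochs=d.get("epochs", 25), batch_size=d.get("batch_size", 1),
                   initial_lr=d.get("initial_lr", 1e-3),
                   final_lr=d.get("final_lr", 5e-4),
                   milestones=tuple(d.get("milestones", (15,))),
                   betas=tuple(d.get("betas", (0.9, 0.999))),
                   seed=d.get("seed", 0), loss=loss,
                   max_steps=d.get("max_steps"))


class Adam:
    """Adam optimizer over a list of parameters."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]


@dataclass
class Checkpoint:
    """Serializable training artifact: weights plus every config needed to
    rebuild the model and reproduce its outputs."""

    weights: dict
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    manifest: DatasetManifest
    epoch: int
    val_history: list
    opt_state: Optional[dict] = None

    def build_model(self, stub: bool = False) -> DualDomainNet:
        geom = self.manifest.geometry
        px = 2.0 * geom.fov_radius / self.manifest.phantom.image_size
        model = DualDomainNet(
            self.model_cfg, geom,
            FBPConfig(image_size=self.manifest.phantom.image_size,
                      pixel_size=px), stub=stub)
        model.load_state_dict(self.weights)
        return model

    def save(self, path):
        meta = {"model_cfg": self.model_cfg.to_dict(),
                "train_cfg": self.train_cfg.to_dict(),
                "manifest": self.manifest.to_dict(),
                "epoch": self.epoch,
                "val_history": self.val_history}
        payload = {f"w:{k}": v for k, v in self.weights.items()}
        payload["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        if self.opt_state is not None:
            payload["opt:t"] = np.array(self.opt_state["t"])
            for i, m in enumerate(self.opt_state["m"]):
                payload[f"opt:m:{i}"] = m
            for i, v in enumerate(self.opt_state["v"]):
                payload[f"opt:v:{i}"] = v
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            weights = {k[2:]: data[k] for k in data.files if k.startswith("w:")}
            opt_state = None
            if "opt:t" in data.files:
                n = len([k for k in data.files if k.startswith("opt:m:")])
                opt_state = {
                    "t": int(data["opt:t"]),
                    "m": [data[f"opt:m:{i}"] for i in range(n)],
                    "v": [data[f"opt:v:{i}"] for i in range(n)]}
        return cls(weights=weights,
                   model_cfg=ModelConfig(**meta["model_cfg"]),
                   train_cfg=TrainConfig.from_dict(meta["train_cfg"]),
                   manifest=DatasetManifest.from_dict(meta["manifest"]),
                   epoch=meta["epoch"],
                   val_history=meta["val_history"],
                   opt_state=opt_state)


def _sparse_of(split_data, i, manifest: DatasetManifest) -> Sinogram:
    key = "sinogram_noisy" if "sinogram_noisy" in split_data else \
        "sinogram_sparse"
    vals = split_data[key][i]
    geom = manifest.geometry
    angles = np.arange(vals.shape[0]) * (geom.angular_span / vals.shape[0])
    return Sinogram(vals, angles, geom.with_views(vals.shape[0]))


def _loss_for(model, split_data, i, manifest, loss_cfg, scale):
    sparse = _sparse_of(split_data, i, manifest)
    sparse = Sinogram(sparse.values / scale, sparse.view_angles,
                      sparse.geometry)
    s_hat, i_hat = model(sparse)
    s_ref = Tensor(split_data["sinogram_full"][i].astype(s_hat.data.dtype)
                   / scale)
    i_ref = Tensor(split_data["image"][i].astype(i_hat.data.dtype) / scale)
    return total_loss(s_hat, s_ref, i_hat, i_ref, loss_cfg)


def train(dataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
          log_path=None, progress: bool = False) -> Checkpoint:
    """Train a dual-domain model on a built dataset; keep the best epoch.

    `dataset` is a PhantomDataset or a path to a built HDF5 container.
    """
    if not isinstance(dataset, PhantomDataset):
        dataset = PhantomDataset(dataset)
    manifest = dataset.manifest
    geom = manifest.geometry
    size = manifest.phantom.image_size
    px = 2.0 * geom.fov_radius / size
    model = DualDomainNet(model_cfg, geom,
                          FBPConfig(image_size=size, pixel_size=px))
    scale = manifest.phantom.attenuation[1]
    opt = Adam(model.parameters(), lr=train_cfg.initial_lr,
               betas=train_cfg.betas)
    rng = np.random.default_rng(train_cfg.seed)
    tr = dataset.split("train")
    va = dataset.split("val")
    n_train, n_val = dataset.n("train"), dataset.n("val")
    gamma = (train_cfg.final_lr / train_cfg.initial_lr) ** (
        1.0 / max(len(train_cfg.milestones), 1))
    log_fh = open(log_path, "a") if log_path else None
    best = None
    val_history = []
    steps = 0
    train_losses = []
    try:
        for epoch in range(train_cfg.epochs):
            lr = train_cfg.initial_lr * gamma ** sum(
                1 for ms in train_cfg.milestones if epoch >= ms)
            opt.lr = lr
            model.train()
            order = rng.permutation(n_train)
            t0 = time.time()
            epoch_losses = []
            done = False
            for i in order:
                loss = _loss_for(model, tr, int(i), manifest,
                                 train_cfg.loss, scale)
                model.zero_grad()
                loss.backward()
                opt.step()
                val = float(loss.data)
                epoch_losses.append(val)
                train_losses.append(val)
                steps += 1
                if train_cfg.max_steps and steps >= train_cfg.max_steps:
                    done = True
                    break
            model.eval()
            with ad.no_grad():
                val_losses = [float(_loss_for(model, va, i, manifest,
                                              train_cfg.loss, scale).data)
                              for i in range(n_val)]
            val_loss = float(np.mean(val_losses)) if val_losses else \
                float(np.mean(epoch_losses))
            val_history.append(val_loss)
            if best is None or val_loss <= best[0]:
                best = (val_loss, epoch, model.state_dict(),
                        opt.state_dict())
            record = {"epoch": epoch, "lr": lr,
                      "train_loss": float(np.mean(epoch_losses)),
                      "val_loss": val_loss, "steps": steps,
                      "wall_time_s": time.time() - t0}
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if progress:
                print(json.dumps(record))
            if done:
                break
    finally:
        if log_fh:
            log_fh.close()
    _, best_epoch, best_weights, best_opt = best
    ckpt = Checkpoint(weights=best_weights, model_cfg=model_cfg,
                      train_cfg=train_cfg, manifest=manifest,
                      epoch=best_epoch, val_history=val_history,
                      opt_state=best_opt)
    ckpt.train_losses = train_losses
    return ckpt


def reconstruct_split(model: DualDomainNet, dataset: PhantomDataset,
                      split: str, scale: float) -> np.ndarray:
    """Model reconstructions for every sample of a split (attenuation units)."""
    data = dataset.split(split)
    model.eval()
    out = np.empty_like(data["image"])
    with ad.no_grad():
        for i in range(out.shape[0]):
            sparse = _sparse_of(data, i, dataset.manifest)
            sparse = Sinogram(sparse.values / scale, sparse.view_angles,
                              sparse.geometry)
            _, i_hat = model(sparse)
            out[i] = i_hat.data.astype(np.float32) * scale
    return out


def evaluate(checkpoint_or_model, dataset, split: str = "test",
             window=None) -> dict:
    """Metric table (per-image rows + mean/std) for baseline FBP and model."""
    if isinstance(checkpoint_or_model, (str, Path)):
        checkpoint_or_model = Checkpoint.load(checkpoint_or_model)
    if isinstance(checkpoint_or_model, Checkpoint):
        model = checkpoint_or_model.build_model()
    else:
        model = checkpoint_or_model
    if not isinstance(dataset, PhantomDataset):
        dataset = PhantomDataset(dataset)
    manifest = dataset.manifest
    if window is None:
        window = tuple(manifest.phantom.attenuation)
    scale = manifest.phantom.attenuation[1]
    data = dataset.split(split)
    recon = reconstruct_split(model, dataset, split, scale)
    report = {"split": split, "views": manifest.views,
              "window": list(window), "methods": {}}
    for method, stack in (("fbp_interp", data["fbp_baseline"]),
                          ("model", recon)):
        rows = []
        for i in range(stack.shape[0]):
            img = normalize_window(stack[i], window)
            ref = normalize_window(data["image"][i], window)
            rows.append(compute_metrics(img, ref, data_range=1.0))
        report["methods"][method] = {
            "per_image": [r.to_dict() for r in rows],
            "aggregate": aggregate_metrics(rows)}
    return report
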