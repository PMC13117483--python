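"""Training loop for the four-band U-Net.

Optimization happens exclusively in the wavelet band domain with the
band-weighted L1 loss; SSIM/PSNR are monitored on the image-domain
reconstruction (IDWT, then inverse rotation when samples carry an alignment
angle) without contributing to any gradient — the monitors run outside the
autograd graph entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mriwave.bands import BAND_NAMES, BandSet, DEFAULT_BAND_WEIGHTS, idwt2_bands
from mriwave.nn import autograd as ag
from mriwave.nn.unet import WaveletAttentionUNet
from mriwave.orientation import rotate_back


@dataclass
class PairedSample:
    """One (corrupted, clean) band pair, optionally orientation-normalized."""

    x: BandSet
    y: BandSet
    angle_deg: float = 0.0  # rotation applied during alignment; 0 = none


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 50
    workers: int = 4  # recorded for provenance; loading is in-process
    band_weights: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    wavelet: str = "db2"
    seed: int = 0
    patience: int = 5  # early stop on validation loss; <=0 disables
    monitor_image_metrics: bool = True

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class History:
    """Per-epoch records plus the best-validation-loss checkpoint."""

    rows: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    best_state: dict | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def _as_sample(item) -> PairedSample:
    if isinstance(item, PairedSample):
        return item
    x, y = item
    return PairedSample(x=x, y=y)


def _stack_dataset(samples, weights_order=BAND_NAMES):
    xs = np.stack([s.x.stack() for s in samples]).astype(np.float32)
    ys = np.stack([s.y.stack() for s in samples]).astype(np.float32)
    return xs, ys


def _image_metrics(model: WaveletAttentionUNet, samples, xs, batch_size):
    """Mean SSIM/PSNR of reconstructed predictions vs. clean references."""
    from mriwave.metrics import psnr, ssim

    ssims, psnrs, maes = [], [], []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo: lo + batch_size]
        pred = model.predict(xs[lo: lo + batch_size])
        for s, pb in zip(chunk, pred):
            bs = BandSet.from_stack(pb.astype(float), family=s.y.family,
                                    source_shape=s.y.source_shape,
                                    boundary_mode=s.y.boundary_mode)
            img_p = idwt2_bands(bs)
            img_t = idwt2_bands(s.y)
            if s.angle_deg:
                img_p = rotate_back(img_p, s.angle_deg)
                img_t = rotate_back(img_t, s.angle_deg)
            ssims.append(ssim(img_p, img_t))
            psnrs.append(psnr(img_p, img_t))
            maes.append(float(np.mean(np.abs(img_p - img_t))))
    return float(np.mean(ssims)), float(np.mean(psnrs)), float(np.mean(maes))


def train(model: WaveletAttentionUNet, dataset, cfg: TrainConfig, val_dataset=None) -> History:
    """Train on (corrupted, clean) band pairs; returns the epoch history.

    ``dataset``/``val_dataset`` are sequences of PairedSample or (x, y)
    BandSet tuples sharing one slice geometry.
    """
    samples = [_as_sample(s) for s in dataset]
    if not samples:
        raise ValueError("empty training dataset")
    val_samples = [_as_sample(s) for s in (val_dataset or [])]
    xs, ys = _stack_dataset(samples)
    if val_samples:
        xv, yv = _stack_dataset(val_samples)
    weights = np.array([cfg.band_weights[b] for b in BAND_NAMES], dtype=np.float32)

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7124]))
    opt = ag.Adam(model.parameters(), lr=cfg.learning_rate)
    history = History()
    n = len(samples)
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            opt.zero_grad()
            out = model(ag.Tensor(xs[idx]))
            loss = ag.band_weighted_l1(out, ys[idx], weights)
            lv = loss.item()
            if not np.isfinite(lv):
                raise FloatingPointError(
                    f"non-finite training loss {lv} at epoch {epoch}, batch {lo // cfg.batch_size}; "
                    "reduce the learning rate or inspect the input scaling")
            loss.backward()
            opt.step()
            losses.append(lv)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}

        model.eval()
        if val_samples:
            vlosses, mae_da = [], []
            for lo in range(0, len(val_samples), cfg.batch_size):
                pred = model.predict(xv[lo: lo + cfg.batch_size])
                diff = np.abs(pred - yv[lo: lo + cfg.batch_size])
                vlosses.append(float((weights * diff.mean(axis=(0, 2, 3))).sum()))
                mae_da.append(float(diff[:, BAND_NAMES.index("DA")].mean()))
            row["val_loss"] = float(np.mean(vlosses))
            row["val_mae_DA"] = float(np.mean(mae_da))
            if cfg.monitor_image_metrics:
                row["val_ssim"], row["val_psnr"], row["val_mae"] = _image_metrics(
                    model, val_samples, xv, cfg.batch_size)
        monitor = row.get("val_loss", row["train_loss"])
        if monitor < history.best_val_loss:
            history.best_val_loss = monitor
            history.best_epoch = epoch
            history.best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
        history.rows.append(row)
        if cfg.patience > 0 and bad_epochs >= cfg.patience:
            break
    return history
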