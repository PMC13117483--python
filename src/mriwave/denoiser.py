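"""scikit-learn style estimator wrapping the full correction pipeline.

``fit`` consumes paired corrupted/clean 2D slices and trains the four-band
attention U-Net in the wavelet domain; ``predict`` runs the complete
inference chain per slice: Radon-guided rotation, level-1 DWT, network
correction of the four bands, IDWT, inverse rotation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from mriwave.bands import DEFAULT_BAND_WEIGHTS, BandSet, dwt2_bands, idwt2_bands
from mriwave.metrics import ssim
from mriwave.nn.training import PairedSample, TrainConfig, train
from mriwave.nn.unet import ModelConfig, WaveletAttentionUNet, min_input_size
from mriwave.orientation import alignment_angle, estimate_dominant_angle, rotate_align, rotate_back


class WaveletAttentionDenoiser(BaseEstimator):
    """Periodic-artifact corrector for 2D MR slices.

    Parameters mirror the architecture/training hyperparameters; fitted state
    lives in trailing-underscore attributes (``model_``, ``history_``).

    Parameters
    ----------
    wavelet : str
        Daubechies family for the four-band decomposition (db1..db6).
    band_weights : dict or None
        WaveletLoss weights per band; None means {AA: 0.1, AD: 0.3, DA: 0.4,
        DD: 0.3}.
    encoder_widths, bottleneck_width, attention_mid_ratio, leaky_slope
        Architecture of the band U-Net.
    learning_rate, batch_size, epochs, patience
        Adam optimization schedule; early stop on validation loss.
    validation_fraction : float
        Fraction of slices (or of groups when ``groups`` is passed to fit)
        held out for validation monitoring and checkpoint selection.
    radon_align : bool
        Estimate the dominant artifact orientation per slice and rotate it to
        the DA axis before the DWT (inverse rotation after reconstruction).
    random_state : int
        Seed for weight initialization, batching and the validation split.
    """

    def __init__(self, wavelet="db2", band_weights=None,
                 encoder_widths=(64, 128, 256, 512), bottleneck_width=1024,
                 attention_mid_ratio=0.5, leaky_slope=0.2,
                 learning_rate=1e-4, batch_size=8, epochs=50, patience=5,
                 validation_fraction=0.2, radon_align=True,
                 monitor_image_metrics=True, random_state=0):
        self.wavelet = wavelet
        self.band_weights = band_weights
        self.encoder_widths = encoder_widths
        self.bottleneck_width = bottleneck_width
        self.attention_mid_ratio = attention_mid_ratio
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.radon_align = radon_align
        self.monitor_image_metrics = monitor_image_metrics
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _validate_slices(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"expected (n_slices, H, W), got shape {X.shape}")
        m = min_input_size()
        if min(X.shape[1:]) < m:
            raise ValueError(f"slices must be at least {m}x{m}, got {X.shape[1:]}")
        return X

    def _prepare_sample(self, x_img: np.ndarray, y_img: np.ndarray | None):
        angle = 0.0
        if self.radon_align:
            est = estimate_dominant_angle(x_img)
            if est.confidence > 0:
                angle = alignment_angle(est)
        xr = rotate_align(x_img, angle) if angle else x_img
        xb = dwt2_bands(xr, self.wavelet)
        if y_img is None:
            return xb, None, angle
        yr = rotate_align(y_img, angle) if angle else y_img
        return xb, dwt2_bands(yr, self.wavelet), angle

    def fit(self, X, y, groups=None, validation_mask=None):
        """Train on corrupted slices ``X`` against clean references ``y``.

        ``groups`` switches the internal validation split to group
        (e.g. subject) level; ``validation_mask`` overrides the split
        entirely with an explicit boolean per-slice assignment.
        """
        X = self._validate_slices(X)
        y = self._validate_slices(y)
        if X.shape != y.shape:
            raise ValueError(f"X and y shapes differ: {X.shape} vs {y.shape}")
        n = X.shape[0]
        rng = np.random.default_rng(np.random.SeedSequence([int(self.random_state), 0xF17]))
        if validation_mask is not None:
            is_val = np.asarray(validation_mask, dtype=bool)
            if is_val.shape != (n,):
                raise ValueError("validation_mask must have one entry per slice")
        elif groups is not None:
            groups = np.asarray(groups)
            uniq = np.array(sorted(set(groups.tolist()), key=str))
            perm = uniq[rng.permutation(len(uniq))]
            n_val = max(1, int(round(self.validation_fraction * len(uniq)))) if len(uniq) > 1 else 0
            val_groups = set(perm[:n_val].tolist())
            is_val = np.array([g in val_groups for g in groups])
        else:
            perm = rng.permutation(n)
            n_val = int(round(self.validation_fraction * n)) if n > 1 else 0
            is_val = np.zeros(n, bool)
            is_val[perm[:n_val]] = True

        samples = []
        for i in range(n):
            xb, yb, angle = self._prepare_sample(X[i], y[i])
            samples.append(PairedSample(x=xb, y=yb, angle_deg=angle))
        train_set = [s for s, v in zip(samples, is_val) if not v]
        val_set = [s for s, v in zip(samples, is_val) if v]

        cfg = TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, band_weights=dict(self.band_weights or DEFAULT_BAND_WEIGHTS),
            wavelet=self.wavelet, seed=int(self.random_state), patience=self.patience,
            monitor_image_metrics=self.monitor_image_metrics)
        mcfg = ModelConfig(
            encoder_widths=tuple(self.encoder_widths),
            bottleneck_width=self.bottleneck_width,
            attention_mid_ratio=self.attention_mid_ratio,
            leaky_slope=self.leaky_slope)
        model = WaveletAttentionUNet(mcfg, seed=int(self.random_state))
        history = train(model, train_set, cfg, val_dataset=val_set or None)
        if history.best_state is not None:
            model.load_state_dict(history.best_state)
        self.model_ = model.eval()
        self.history_ = history
        self.train_config_ = cfg
        self.model_config_ = mcfg
        self.n_slices_ = n
        return self

    def predict(self, X) -> np.ndarray:
        """Correct corrupted slices; returns an array shaped like ``X``."""
        self._check_fitted()
        X = self._validate_slices(X)
        out = np.empty_like(X)
        batch, meta = [], []
        for i in range(X.shape[0]):
            xb, _, angle = self._prepare_sample(X[i], None)
            batch.append(xb.stack())
            meta.append((xb, angle))
        preds = []
        bs = max(1, int(self.batch_size))
        arr = np.stack(batch).astype(np.float32)
        for lo in range(0, len(batch), bs):
            preds.append(self.model_.predict(arr[lo: lo + bs]))
        preds = np.concatenate(preds, axis=0)
        for i, (xb, angle) in enumerate(meta):
            bset = BandSet.from_stack(preds[i].astype(float), family=xb.family,
                                      source_shape=xb.source_shape,
                                      boundary_mode=xb.boundary_mode)
            img = idwt2_bands(bset)
            out[i] = rotate_back(img, angle) if angle else img
        return out

    def score(self, X, y) -> float:
        """Mean SSIM between corrected slices and clean references."""
        y = self._validate_slices(y)
        pred = self.predict(X)
        return float(np.mean([ssim(p, t) for p, t in zip(pred, y)]))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this WaveletAttentionDenoiser instance is not fitted yet")
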