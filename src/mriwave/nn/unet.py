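"""The four-band attention-gated U-Net.

Input is the (B, 4, H/2, W/2) stack of level-1 DWT sub-bands (AA, AD, DA, DD)
of H x W slices.  Four encoder levels (DoubleConv + 2x2 max pooling), a
bottleneck, and four decoder levels (bilinear upsampling, attention-gated
skip concatenation, DoubleConv); a final 1x1 convolution reconstructs the
four bands.  With one DWT halving before the network and four poolings inside
it, slices must be at least 32 x 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mriwave.nn import autograd as ag
from mriwave.nn.autograd import Tensor
from mriwave.nn.layers import AttentionGate, Conv2d, DoubleConv, Module

N_POOL_LEVELS = 4
DWT_LEVELS = 1


def min_input_size(n_pool_levels: int = N_POOL_LEVELS, dwt_levels: int = DWT_LEVELS) -> int:
    """Smallest square slice side keeping every downsampled map >= 1 pixel."""
    if n_pool_levels < 0 or dwt_levels < 0:
        raise ValueError("level counts must be non-negative")
    return 2 ** (int(n_pool_levels) + int(dwt_levels))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The bottleneck width of 1024 and the four encoder/decoder levels are
    fixed design points; encoder widths follow the classic doubling ladder.
    """

    in_channels: int = 4
    out_channels: int = 4
    encoder_widths: tuple = (64, 128, 256, 512)
    bottleneck_width: int = 1024
    leaky_slope: float = 0.2
    attention_mid_ratio: float = 0.5
    #: predict band corrections added to the input bands (head zero-initialized,
    #: so an untrained model is the identity) rather than bands from scratch
    residual: bool = True

    def __post_init__(self):
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        if len(self.encoder_widths) != N_POOL_LEVELS:
            raise ValueError(f"exactly {N_POOL_LEVELS} encoder widths required")
        if any(b <= a for a, b in zip(self.encoder_widths, self.encoder_widths[1:])):
            raise ValueError("encoder widths must be strictly increasing")
        if self.bottleneck_width <= self.encoder_widths[-1]:
            raise ValueError("bottleneck must be wider than the last encoder level")
        if not 0 < self.attention_mid_ratio <= 1:
            raise ValueError("attention_mid_ratio must be in (0, 1]")


class WaveletAttentionUNet(Module):
    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE7]))
        c = self.cfg
        widths = c.encoder_widths
        self.encoders = [DoubleConv(c.in_channels if i == 0 else widths[i - 1], widths[i],
                                    rng, c.leaky_slope) for i in range(len(widths))]
        self.bottleneck = DoubleConv(widths[-1], c.bottleneck_width, rng, c.leaky_slope)
        self.gates, self.decoders = [], []
        g_ch = c.bottleneck_width
        for i in reversed(range(len(widths))):
            mid = max(1, int(round(c.attention_mid_ratio * widths[i])))
            self.gates.append(AttentionGate(widths[i], g_ch, mid, rng))
            self.decoders.append(DoubleConv(g_ch + widths[i], widths[i], rng, c.leaky_slope))
            g_ch = widths[i]
        self.head = Conv2d(widths[0], c.out_channels, 1, rng)
        if c.residual:
            self.head.weight.data[...] = 0.0
            self.head.bias.data[...] = 0.0

    def forward(self, bands: Tensor | np.ndarray) -> Tensor:
        x = bands if isinstance(bands, Tensor) else Tensor(bands)
        if x.data.ndim != 4 or x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, {self.cfg.in_channels}, h, w) band input, got {x.data.shape}")
        h, w = x.data.shape[2:]
        min_band = min_input_size() // 2
        if h < min_band or w < min_band or h % min_band or w % min_band:
            raise ValueError(
                f"band size {(h, w)} unsupported: slices must be at least "
                f"{min_input_size()}x{min_input_size()} (bands {min_band}x{min_band}) "
                f"and band sides multiples of {min_band}")
        bands_in = x
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = ag.maxpool2(x)
        x = self.bottleneck(x)
        for gate, dec, skip in zip(self.gates, self.decoders, reversed(skips)):
            gated = gate(skip, x)
            x = ag.upsample2_bilinear(x)
            x = dec(ag.concat_channels(gated, x))
        out = self.head(x)
        return ag.add(out, bands_in) if self.cfg.residual else out

    def predict(self, bands: np.ndarray) -> np.ndarray:
        """Inference on a (B, 4, h, w) band stack; no gradient bookkeeping."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(np.asarray(bands, dtype=np.float32))).data
        finally:
            if was_training:
                self.train()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> WaveletAttentionUNet:
    return WaveletAttentionUNet(cfg, seed=seed)
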