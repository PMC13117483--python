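"""Neural-network building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from mriwave.nn import autograd as ag
from mriwave.nn.autograd import Tensor


class Module:
    """Base class: parameter collection, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        for attr in self.__dict__.values():
            if isinstance(attr, Module):
                yield attr
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        params = []
        for m in [self, *self.modules()]:
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {}
        for i, m in enumerate([self, *self.modules()]):
            for name, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{i}.{name}"] = v.data.copy()
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    state[f"{i}.{name}"] = v.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, m in enumerate([self, *self.modules()]):
            for name, v in m.__dict__.items():
                key = f"{i}.{name}"
                if key in state:
                    if isinstance(v, Tensor):
                        v.data[...] = state[key]
                    else:
                        v[...] = state[key]
        return self

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization (LeakyReLU-friendly)
        self.weight = Tensor(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class DoubleConv(Module):
    """conv3x3 -> BN -> LeakyReLU, twice (conventional conv/norm/activation order)."""

    def __init__(self, in_ch: int, out_ch: int, rng, leaky_slope: float = 0.2):
        super().__init__()
        self.slope = leaky_slope
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, padding=1)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.leaky_relu(self.bn1(self.conv1(x)), self.slope)
        return ag.leaky_relu(self.bn2(self.conv2(x)), self.slope)


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    The encoder features x are projected and downsampled with a strided 2x2
    convolution, the decoder gating signal g with a 1x1 convolution; their sum
    passes ReLU, a 1x1 convolution to one channel, and a sigmoid, giving an
    attention map in (0, 1) at the gating resolution which is bilinearly
    upsampled and multiplied into x.
    """

    def __init__(self, x_ch: int, g_ch: int, mid_ch: int, rng):
        super().__init__()
        self.theta = Conv2d(x_ch, mid_ch, 2, rng, stride=2, bias=True)
        self.phi = Conv2d(g_ch, mid_ch, 1, rng, bias=True)
        self.psi = Conv2d(mid_ch, 1, 1, rng, bias=True)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        tx = self.theta(x)
        pg = self.phi(g)
        if pg.data.shape[2:] != tx.data.shape[2:]:
            if tuple(2 * s for s in pg.data.shape[2:]) != tx.data.shape[2:]:
                raise ValueError(
                    f"gating signal at {pg.data.shape[2:]} incompatible with "
                    f"projected skip at {tx.data.shape[2:]}")
            pg = ag.upsample2_bilinear(pg)
        f = ag.relu(ag.add(tx, pg))
        psi = ag.sigmoid(self.psi(f))
        psi_up = ag.upsample2_bilinear(psi)
        return ag.mul(x, psi_up)
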