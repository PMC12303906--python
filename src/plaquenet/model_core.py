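"""DualPlaqueNet: a dual-branch encoder-decoder for plaque analysis.

The network couples two tasks over one shared convolutional trunk:

* a U-Net style segmentation path (encoder, bottleneck, decoder with skip
  connections, 1x1 class head) that labels each pixel background/plaque;
* a size-regression branch that reads the bottleneck features through
  global average pooling and two fully-connected layers and outputs the
  plaque's long and short diameters in millimetres.

Every encoder stage ends in an efficient-channel-attention block whose
channel weights are computed by a *stack* of 1-D convolutions over the
globally pooled channel descriptor (``eca_conv_layers`` of them, with a
rectifier between successive convolutions) rather than the single
convolution of the original design.

All arithmetic is plain NumPy via :mod:`plaquenet.nn`; forward and backward
passes are explicit, which keeps the implementation dependency-free and
directly checkable against finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .nn import (
    BatchNorm2d,
    ChannelConv1d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    sigmoid,
)

__all__ = [
    "ModelConfig",
    "NetworkOutput",
    "ECAML",
    "DualPlaqueNet",
    "adaptive_kernel_size",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyper-parameters fully determining the architecture.

    ``eca_kernel_size`` may be an explicit odd integer or ``"adaptive"``,
    in which case the kernel grows logarithmically with the channel count
    (see :func:`adaptive_kernel_size`).
    """

    input_channels: int = 1
    num_classes: int = 2
    depth: int = 4
    base_channels: int = 64
    eca_conv_layers: int = 2
    eca_kernel_size: int | str = "adaptive"
    regression_hidden_units: int = 64
    regression_outputs: int = 2
    attention: bool = True
    regression_branch: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.regression_outputs != 2:
            raise ValueError("regression_outputs is fixed at 2 (long, short)")
        if isinstance(self.eca_kernel_size, int) and self.eca_kernel_size % 2 == 0:
            raise ValueError("eca_kernel_size must be odd")
        if self.eca_conv_layers < 1:
            raise ValueError("eca_conv_layers must be >= 1")


class NetworkOutput(NamedTuple):
    """Per-batch network result: class scores and diameter estimates."""

    segmentation_scores: np.ndarray  # (N, num_classes, H, W), unnormalized
    diameter_predictions: np.ndarray  # (N, 2) in mm, order (long, short)


def adaptive_kernel_size(channels: int) -> int:
    """Odd 1-D kernel size from the channel count.

    ``k = |log2(C)/gamma + b/gamma|`` with gamma = 2, b = 1, truncated and
    pushed to the next odd integer, never below 3.  E.g. C = 64 -> 3.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = int(abs(math.log2(channels) / 2.0 + 0.5))
    k = t if t % 2 == 1 else t + 1
    return max(k, 3)


class ECAML(Layer):
    """Efficient channel attention with a multi-layer 1-D convolution stack.

    GAP over space -> ``layers`` successive single-channel 1-D convolutions
    along the channel axis (ReLU between, none after the last) -> sigmoid
    -> channel-wise rescaling of the input.  ``force_identity`` bypasses the
    block (weights treated as 1) for ablation studies.
    """

    def __init__(self, channels: int, layers: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        if layers < 1:
            raise ValueError("need at least one 1-D convolution")
        self.channels = channels
        self.convs = [ChannelConv1d(kernel_size, rng, dtype) for _ in range(layers)]
        self.relus = [ReLU() for _ in range(layers - 1)]
        self.force_identity = False
        self._cache = None

    def params(self):
        if self.force_identity:
            return []
        return [p for c in self.convs for p in c.params()]

    def channel_weights(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """The (N, C) attention weights for input ``x``, all in (0, 1)."""
        z = x.mean(axis=(2, 3))
        u = z
        for i, conv in enumerate(self.convs):
            u = conv.forward(u, train)
            if i < len(self.relus):
                u = self.relus[i].forward(u, train)
        return sigmoid(u)

    def forward(self, x, train=True):
        if self.force_identity:
            return x
        w = self.channel_weights(x, train)
        if train:
            self._cache = (x, w)
        return x * w[:, :, None, None]

    def backward(self, gout):
        if self.force_identity:
            return gout
        x, w = self._cache
        self._cache = None
        gin = gout * w[:, :, None, None]
        dw = (gout * x).sum(axis=(2, 3))
        du = dw * w * (1.0 - w)  # through the sigmoid
        for i in range(len(self.convs) - 1, -1, -1):
            if i < len(self.relus):
                du = self.relus[i].backward(du)
            du = self.convs[i].backward(du)
        # descriptor came from a spatial mean
        h, wd = x.shape[2], x.shape[3]
        gin = gin + du[:, :, None, None] / (h * wd)
        return gin


class _ConvBlock(Layer):
    """(Conv3x3 -> BN -> ReLU) x 2, the standard U-Net stage."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32):
        self.seq: list[Layer] = [
            Conv2d(in_ch, out_ch, 3, rng, dtype), BatchNorm2d(out_ch, dtype), ReLU(),
            Conv2d(out_ch, out_ch, 3, rng, dtype), BatchNorm2d(out_ch, dtype), ReLU(),
        ]

    def params(self):
        return [p for l in self.seq for p in l.params()]

    def forward(self, x, train=True):
        for l in self.seq:
            x = l.forward(x, train)
        return x

    def backward(self, gout):
        for l in reversed(self.seq):
            gout = l.backward(gout)
        return gout


class DualPlaqueNet:
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = rng if rng is not None else np.random.default_rng(0)
        c = config.base_channels
        d = config.depth

        self.enc_blocks: list[_ConvBlock] = []
        self.ecas: list[ECAML] = []
        self.pools: list[MaxPool2d] = []
        in_ch = config.input_channels
        for i in range(d):
            out_ch = c * (2 ** i)
            self.enc_blocks.append(_ConvBlock(in_ch, out_ch, rng, dtype))
            if config.attention:
                k = (adaptive_kernel_size(out_ch)
                     if config.eca_kernel_size == "adaptive" else config.eca_kernel_size)
                self.ecas.append(ECAML(out_ch, config.eca_conv_layers, k, rng, dtype))
            else:
                self.ecas.append(None)  # type: ignore[arg-type]
            self.pools.append(MaxPool2d())
            in_ch = out_ch

        bott_ch = c * (2 ** d)
        self.bottleneck = _ConvBlock(in_ch, bott_ch, rng, dtype)

        self.upconvs: list[ConvTranspose2d] = []
        self.dec_blocks: list[_ConvBlock] = []
        ch = bott_ch
        for i in range(d - 1, -1, -1):
            skip_ch = c * (2 ** i)
            self.upconvs.append(ConvTranspose2d(ch, skip_ch, rng, dtype))
            self.dec_blocks.append(_ConvBlock(2 * skip_ch, skip_ch, rng, dtype))
            ch = skip_ch
        self.head = Conv2d(c, config.num_classes, 1, rng, dtype)

        if config.regression_branch:
            self.fc1 = Linear(bott_ch, config.regression_hidden_units, rng, dtype)
            self.fc_relu = ReLU()
            self.fc2 = Linear(config.regression_hidden_units, 2, rng, dtype)
        else:
            self.fc1 = self.fc_relu = self.fc2 = None
        self._cache = None

    # ---- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.enc_blocks:
            out += b.params()
        for e in self.ecas:
            if e is not None:
                out += e.params()
        out += self.bottleneck.params()
        for u in self.upconvs:
            out += u.params()
        for b in self.dec_blocks:
            out += b.params()
        out += self.head.params()
        if self.fc1 is not None:
            out += self.fc1.params() + self.fc2.params()
        return out

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def _bn_layers(self) -> list[BatchNorm2d]:
        blocks = self.enc_blocks + [self.bottleneck] + self.dec_blocks
        return [l for b in blocks for l in b.seq if isinstance(l, BatchNorm2d)]

    def get_state(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}_mean"] = bn.running_mean.copy()
            state[f"bn{i}_var"] = bn.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = state[f"p{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn{i}_mean"]
            bn.running_var[...] = state[f"bn{i}_var"]

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> NetworkOutput:
        d = self.config.depth
        if x.ndim != 4:
            raise ValueError("expected a (N, C, H, W) batch")
        if x.shape[2] % (2 ** d) or x.shape[3] % (2 ** d):
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} not divisible by 2^depth={2 ** d}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for i in range(d):
            x = self.enc_blocks[i].forward(x, train)
            if self.ecas[i] is not None:
                x = self.ecas[i].forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        bott = self.bottleneck.forward(x, train)

        y = bott
        for j in range(d):
            y = self.upconvs[j].forward(y, train)
            skip = skips[d - 1 - j]
            y = np.concatenate([skip, y], axis=1)
            y = self.dec_blocks[j].forward(y, train)
        scores = self.head.forward(y, train)

        if self.fc1 is not None:
            z = bott.mean(axis=(2, 3))
            h = self.fc_relu.forward(self.fc1.forward(z, train), train)
            diam = self.fc2.forward(h, train)
        else:
            diam = np.zeros((x.shape[0], 2), dtype=self.dtype)
        if train:
            self._cache = (bott.shape, [s.shape for s in skips])
        return NetworkOutput(scores, diam)

    def backward(self, dscores: np.ndarray, ddiam: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients from output gradients."""
        d = self.config.depth
        bott_shape, skip_shapes = self._cache
        g = self.head.backward(dscores.astype(self.dtype))
        dskips = [None] * d
        for j in range(d - 1, -1, -1):
            g = self.dec_blocks[j].backward(g)
            skip_ch = skip_shapes[d - 1 - j][1]
            dskips[d - 1 - j] = g[:, :skip_ch]
            g = self.upconvs[j].backward(g[:, skip_ch:])
        dbott = g

        if self.fc1 is not None and ddiam is not None:
            dz = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(ddiam.astype(self.dtype))))
            n, c, h, w = bott_shape
            dbott = dbott + dz[:, :, None, None] / (h * w)
        g = self.bottleneck.backward(dbott)
        for i in range(d - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + dskips[i]
            if self.ecas[i] is not None:
                g = self.ecas[i].backward(g)
            g = self.enc_blocks[i].backward(g)
        self._cache = None

    __call__ = forward


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> DualPlaqueNet:
    """Construct a :class:`DualPlaqueNet` with seeded weight initialization."""
    return DualPlaqueNet(config, np.random.default_rng(seed), dtype=dtype)


def save_checkpoint(model: DualPlaqueNet, path) -> None:
    """Serialize weights + architecture config to a single ``.npz`` file."""
    import json

    cfg = dict(model.config.__dict__)
    state = model.get_state()
    state["_config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> DualPlaqueNet:
    import json

    with np.load(path) as data:
        cfg = json.loads(bytes(data["_config_json"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "_config_json"}
    model = build_model(ModelConfig(**cfg))
    model.set_state(state)
    return model
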