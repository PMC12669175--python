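"""Encoder-decoder segmentation network with MSMS state-space blocks.

Each encoder layer is: depthwise-separable 3-D conv block (stride 1) ->
MSMS block (long-range modeling) -> second conv block with the layer's
down-sampling stride (the strided-conv alternative to max pooling).  The
decoder mirrors the encoder: transposed-conv up-sampling by the matching
encoder stride, concatenation of the skip features, and a conv block.  A
pointwise (1x1x1) head produces class logits at full resolution, with
auxiliary heads at every intermediate decoder resolution for deep
supervision.

The default configuration is the published six-layer architecture: encoder
channels 2-32-64-128-256-320-320, in-plane-only down-sampling in the first
three layers (thick-slice anisotropy), state dimension 16, expansion ratio 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .msms_serialization import MSMSBlock

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "SegmentationOutput",
    "InputSizeError",
    "default_network_spec",
    "conv_block",
    "ConvBlock3d",
    "build_network",
    "Network",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


class InputSizeError(ValueError):
    """Input spatial extent incompatible with the down-sampling chain."""


@dataclass
class LayerSpec:
    """One encoder/decoder level (a Table-style row of the architecture)."""

    kernel: tuple[int, int, int]
    stride: tuple[int, int, int]      # down-sampling stride of this level
    channels: int                     # encoder output channels
    d_state: int = 16
    d_conv: int = 4
    expansion: int = 2
    up_kernel: tuple[int, int, int] | None = None  # decoder transposed conv

    def __post_init__(self):
        self.kernel = tuple(int(k) for k in self.kernel)
        self.stride = tuple(int(s) for s in self.stride)
        if self.up_kernel is not None:
            self.up_kernel = tuple(int(k) for k in self.up_kernel)


@dataclass
class NetworkSpec:
    """Full architecture description."""

    layers: list[LayerSpec]
    in_channels: int = 2
    num_classes: int = 2
    deep_supervision: bool = True
    n_segments: int = 4
    # initial logit bias of the last class; setting it to the log-odds of the
    # foreground prior keeps early cross-entropy near its optimum under heavy
    # class imbalance so gradients concentrate on the lesions
    head_bias: float = 0.0

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")

    @property
    def channel_chain(self) -> list[int]:
        return [self.in_channels] + [l.channels for l in self.layers]

    def to_json(self) -> str:
        return json.dumps(
            {
                "in_channels": self.in_channels,
                "num_classes": self.num_classes,
                "deep_supervision": self.deep_supervision,
                "n_segments": self.n_segments,
                "layers": [asdict(l) for l in self.layers],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        layers = [LayerSpec(**l) for l in d.pop("layers")]
        return cls(layers=layers, **d)


def default_network_spec(in_channels: int = 2, num_classes: int = 2) -> NetworkSpec:
    """The published six-layer configuration."""
    rows = [
        ((3, 3, 1), (1, 1, 1), 32, (2, 2, 1)),
        ((3, 3, 1), (2, 2, 1), 64, (2, 2, 1)),
        ((3, 3, 1), (2, 2, 1), 128, (2, 2, 1)),
        ((3, 3, 3), (2, 2, 2), 256, (2, 2, 2)),
        ((3, 3, 3), (2, 2, 2), 320, (2, 2, 2)),
        ((3, 3, 3), (2, 2, 1), 320, (2, 2, 1)),
    ]
    return NetworkSpec(
        layers=[LayerSpec(k, s, c, up_kernel=u) for k, s, c, u in rows],
        in_channels=in_channels,
        num_classes=num_classes,
    )


def small_network_spec(
    in_channels: int = 1,
    num_classes: int = 2,
    channels: tuple[int, ...] = (8, 16),
    d_state: int = 4,
) -> NetworkSpec:
    """Reduced-width shallow variant for desk-scale training."""
    layers = [
        LayerSpec(
            (3, 3, 1),
            (1, 1, 1) if i == 0 else (2, 2, 1),
            c,
            d_state=d_state,
            up_kernel=(2, 2, 1),
        )
        for i, c in enumerate(channels)
    ]
    return NetworkSpec(layers=layers, in_channels=in_channels,
                       num_classes=num_classes, head_bias=-4.6)


@dataclass
class SegmentationOutput:
    """Primary logits at input resolution plus auxiliary decoder logits."""

    logits: np.ndarray                 # (num_classes, X, Y, Z)
    aux_logits: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Layers


class ConvBlock3d(Module):
    """Depthwise conv -> pointwise conv -> instance norm -> LeakyReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        stride: tuple[int, int, int],
        rng: np.random.Generator,
        negative_slope: float = 0.01,
        eps: float = 1e-5,
    ):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.negative_slope = negative_slope
        self.eps = eps
        K = int(np.prod(kernel))
        self.w_depth = Parameter(rng.normal(0.0, (2.0 / K) ** 0.5, (in_channels, K)))
        self.w_point = Parameter(
            rng.normal(0.0, (2.0 / in_channels) ** 0.5, (out_channels, in_channels))
        )
        self.b_point = Parameter(np.zeros((out_channels, 1, 1, 1)), decay=False)
        self.gamma = Parameter(np.ones((out_channels, 1, 1, 1)), decay=False)
        self.beta = Parameter(np.zeros((out_channels, 1, 1, 1)), decay=False)

    def forward(self, g: Tensor) -> Tensor:
        if g.shape[0] != self.w_depth.shape[0]:
            raise ValueError(
                f"expected {self.w_depth.shape[0]} input channels, got {g.shape[0]}"
            )
        patches = ad.unfold3d(g, self.kernel, self.stride)      # (C, K, X', Y', Z')
        dw = ad.einsum("ck,ckxyz->cxyz", self.w_depth, patches)
        pw = ad.einsum("oc,cxyz->oxyz", self.w_point, dw) + self.b_point
        mu = pw.mean(axis=(1, 2, 3), keepdims=True)
        xc = pw - mu
        var = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
        normed = xc / (var + self.eps).sqrt() * self.gamma + self.beta
        return normed.leaky_relu(self.negative_slope)

    def __call__(self, g: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.asarray(g, dtype=float))).data


def conv_block(
    g: np.ndarray,
    kernel: tuple[int, int, int],
    stride: tuple[int, int, int],
    channels: int,
    seed: int = 0,
) -> np.ndarray:
    """Apply a freshly initialized conv block (functional convenience)."""
    g = np.asarray(g, dtype=float)
    block = ConvBlock3d(g.shape[0], channels, kernel, stride,
                        np.random.default_rng(seed))
    return block(g)


class TransposedConvUp(Module):
    """Transposed 3-D convolution with kernel == stride (exact up-sampling)."""

    def __init__(self, in_channels: int, out_channels: int,
                 factor: tuple[int, int, int], rng: np.random.Generator):
        self.factor = tuple(factor)
        K = int(np.prod(factor))
        self.w = Parameter(
            rng.normal(0.0, (2.0 / (in_channels * K)) ** 0.5,
                       (out_channels, in_channels) + self.factor)
        )
        self.b = Parameter(np.zeros((out_channels, 1, 1, 1)), decay=False)

    def forward(self, g: Tensor) -> Tensor:
        O = self.w.shape[0]
        _, X, Y, Z = g.shape
        fx, fy, fz = self.factor
        out = ad.einsum("ocijk,cxyz->oxiyjzk", self.w, g)
        return out.reshape((O, X * fx, Y * fy, Z * fz)) + self.b


class PointwiseHead(Module):
    """1x1x1 convolution to class logits."""

    def __init__(self, in_channels: int, num_classes: int,
                 rng: np.random.Generator, last_class_bias: float = 0.0):
        self.w = Parameter(rng.normal(0.0, 0.01, (num_classes, in_channels)))
        b = np.zeros((num_classes, 1, 1, 1))
        b[-1] = last_class_bias
        self.b = Parameter(b, decay=False)

    def forward(self, g: Tensor) -> Tensor:
        return ad.einsum("oc,cxyz->oxyz", self.w, g) + self.b


# ---------------------------------------------------------------------------
# The network


class Network(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        n = len(spec.layers)
        ch = spec.channel_chain                       # [in, c1, ..., cn]
        self.enc_conv1: list[ConvBlock3d] = []
        self.enc_msms: list[MSMSBlock] = []
        self.enc_down: list[ConvBlock3d] = []
        for i, l in enumerate(spec.layers):
            self.enc_conv1.append(
                ConvBlock3d(ch[i], l.channels, l.kernel, (1, 1, 1), rng)
            )
            self.enc_msms.append(
                MSMSBlock(l.channels, l.d_state, l.expansion, rng,
                          n_segments=spec.n_segments, d_conv=l.d_conv)
            )
            self.enc_down.append(
                ConvBlock3d(l.channels, l.channels, l.kernel, l.stride, rng)
            )
        # decoder step for level i up-samples by the level's encoder stride;
        # transposed conv maps c_{i+1} (c_{n} for the bottleneck step) -> c_i
        self.dec_up: list[TransposedConvUp] = []
        self.dec_conv: list[ConvBlock3d] = []
        self.heads: list[PointwiseHead] = []
        for i, l in enumerate(spec.layers):
            c_above = ch[i + 2] if i + 2 <= n else ch[n]
            self.dec_up.append(
                TransposedConvUp(c_above, l.channels, l.stride, rng)
            )
            self.dec_conv.append(
                ConvBlock3d(2 * l.channels, l.channels, l.kernel, (1, 1, 1), rng)
            )
            self.heads.append(
                PointwiseHead(l.channels, spec.num_classes, rng,
                              last_class_bias=spec.head_bias)
            )

    # -- forward -----------------------------------------------------------

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        spec = self.spec
        if x.shape[0] != spec.in_channels:
            raise ValueError(
                f"expected {spec.in_channels} input channels, got {x.shape[0]}"
            )
        skips: list[Tensor] = []
        for i, l in enumerate(spec.layers):
            shape = x.shape[1:]
            if any(s % st for s, st in zip(shape, l.stride)):
                raise InputSizeError(
                    f"spatial shape {shape} not divisible by stride {l.stride} "
                    f"at layer {i + 1}"
                )
            h = self.enc_conv1[i].forward(x)
            h = self.enc_msms[i].forward(h)
            skips.append(h)
            x = self.enc_down[i].forward(h)
        aux: list[Tensor] = []
        for i in reversed(range(len(spec.layers))):
            x = self.dec_up[i].forward(x)
            skip = skips[i]
            assert x.shape[1:] == skip.shape[1:], (
                f"decoder/encoder shape mismatch at level {i + 1}: "
                f"{x.shape[1:]} vs {skip.shape[1:]}"
            )
            x = self.dec_conv[i].forward(ad.concat([x, skip], axis=0))
            if i > 0 and spec.deep_supervision:
                aux.append(self.heads[i].forward(x))
        logits = self.heads[0].forward(x)
        aux.reverse()   # order: nearest-to-primary first (weight 1/2^1, ...)
        return logits, aux

    def segment(self, volume: np.ndarray) -> SegmentationOutput:
        """Run a single-volume forward pass (numpy in / numpy out)."""
        v = np.asarray(volume, dtype=float)
        if v.ndim == 3:
            v = v[None]
        logits, aux = self.forward(Tensor(v))
        return SegmentationOutput(logits.data, [a.data for a in aux])


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate the network with seeded initialization."""
    return Network(spec, np.random.default_rng(seed))


def predict(net: Network, data: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Voxel-wise label prediction for one preprocessed volume.

    ``data`` is ``(X, Y, Z)`` or ``(C, X, Y, Z)``; returns integer labels of
    the same spatial shape.  Intensities are z-scored per channel unless the
    caller already normalized.
    """
    v = np.asarray(data, dtype=float)
    if v.ndim == 3:
        v = v[None]
    if normalize:
        v = _zscore(v)
    total = np.prod([l.stride for l in net.spec.layers], axis=0)
    if any(s < t for s, t in zip(v.shape[1:], total)):
        raise InputSizeError(
            f"spatial shape {v.shape[1:]} smaller than total down-sampling "
            f"factor {tuple(total)}"
        )
    out = net.segment(v)
    return np.argmax(out.logits, axis=0).astype(np.uint8)


def _zscore(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v, dtype=float)
    for c in range(v.shape[0]):
        sd = v[c].std()
        out[c] = (v[c] - v[c].mean()) / (sd if sd > 0 else 1.0)
    return out


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(net: Network, path) -> None:
    state = net.state_arrays()
    np.savez(path, __spec__=np.frombuffer(
        net.spec.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> Network:
    with np.load(path) as z:
        spec = NetworkSpec.from_json(bytes(z["__spec__"].tobytes()).decode())
        net = build_network(spec, seed=0)
        state = {k: z[k] for k in z.files if k != "__spec__"}
    net.load_state_arrays(state)
    return net
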