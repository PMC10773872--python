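"""U-Net family architectures for binary gland segmentation.

Three encoder–decoder families are built from shared blocks:

* ``unet``   — plain U-Net: forward convolutional units (two 3x3 conv + ReLU)
  on both paths, skip connections by plain concatenation.
* ``aunet``  — Attention U-Net: the same units, but each skip connection is
  gated by an additive attention gate driven by the coarser decoder signal.
* ``arunet`` — Attention-Residual U-Net: residual convolutional units
  (conv path plus identity/projection shortcut) together with attention gates.

The prediction head is a 1x1 convolution to 2 channels followed by a softmax,
so every patch yields an H x W x 2 per-pixel probability field for the
benign (0) / malignant (1) classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, Module, Conv2D, BatchNorm2D, concat

__all__ = [
    "ModelSpec",
    "ForwardConvUnit",
    "ResidualUnit",
    "AttentionGate",
    "SegmentationModel",
    "build_model",
    "predict_patch",
    "forward_conv_unit",
    "residual_unit",
    "attention_gate",
]

FAMILIES = ("unet", "aunet", "arunet")


@dataclass
class ModelSpec:
    """Architecture hyper-parameters.

    ``depth`` counts encoder levels (including the bottleneck); feature widths
    double per level starting from ``base_filters``.  ``input_size`` must be
    divisible by ``2**(depth-1)`` so pooling/upsampling round-trips exactly.
    """

    family: str = "arunet"
    depth: int = 5
    base_filters: int = 16
    input_size: int = 256
    n_classes: int = 2
    seed: int = 0
    batch_norm: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^(depth-1) = "
                f"{2 ** (self.depth - 1)}"
            )
        if self.n_classes != 2:
            raise ValueError("binary segmentation: n_classes is fixed at 2")


class ForwardConvUnit(Module):
    """Two successive 3x3 convolutions, each followed by (BN and) ReLU."""

    def __init__(self, cin: int, filters: int, rng: np.random.Generator,
                 batch_norm: bool = True):
        if filters <= 0:
            raise ValueError("filters must be positive")
        bias = not batch_norm
        self.conv1 = Conv2D(cin, filters, 3, rng, bias=bias)
        self.conv2 = Conv2D(filters, filters, 3, rng, bias=bias)
        self.bn1 = BatchNorm2D(filters) if batch_norm else None
        self.bn2 = BatchNorm2D(filters) if batch_norm else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h, training)
        h = h.relu()
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h, training)
        return h.relu()


class ResidualUnit(Module):
    """Residual convolutional unit: conv path + shortcut.

    The conv path is two 3x3 conv(+BN)+ReLU stages; the shortcut is the
    identity when channel counts match, otherwise a 1x1 projection (+BN).
    The unit output is the plain sum of the two branches.
    """

    def __init__(self, cin: int, filters: int, rng: np.random.Generator,
                 batch_norm: bool = True):
        if filters <= 0:
            raise ValueError("filters must be positive")
        bias = not batch_norm
        self.conv1 = Conv2D(cin, filters, 3, rng, bias=bias)
        self.conv2 = Conv2D(filters, filters, 3, rng, bias=bias)
        self.bn1 = BatchNorm2D(filters) if batch_norm else None
        self.bn2 = BatchNorm2D(filters) if batch_norm else None
        if cin != filters:
            self.proj = Conv2D(cin, filters, 1, rng, bias=bias)
            self.bn_proj = BatchNorm2D(filters) if batch_norm else None
        else:
            self.proj = None
            self.bn_proj = None

    def conv_path(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h, training)
        h = h.relu()
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h, training)
        return h.relu()

    def shortcut(self, x: Tensor, training: bool = False) -> Tensor:
        if self.proj is None:
            return x
        s = self.proj(x)
        if self.bn_proj is not None:
            s = self.bn_proj(s, training)
        return s

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.conv_path(x, training) + self.shortcut(x, training)


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    The skip feature is downsampled to the gating signal's (coarser) grid,
    both are projected to an intermediate width, summed, passed through ReLU
    and a 1x1 convolution with sigmoid to yield attention coefficients
    alpha in [0, 1], which are upsampled and multiply the skip feature.
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator):
        inter = max(skip_ch // 2, 1)
        self.theta_x = Conv2D(skip_ch, inter, 1, rng, bias=False)
        self.phi_g = Conv2D(gate_ch, inter, 1, rng, bias=True)
        self.psi = Conv2D(inter, 1, 1, rng, bias=True)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        """Attention map alpha at the skip's resolution (N, H, W, 1)."""
        sh, gh = skip.shape[1], gate.shape[1]
        if sh != 2 * gh:
            raise ValueError(
                f"gate must be at half the skip resolution: skip {sh}, gate {gh}"
            )
        q = self.theta_x(skip.avgpool2()) + self.phi_g(gate)
        alpha = self.psi(q.relu()).sigmoid()
        return alpha.upsample2()

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        return skip * self.coefficients(skip, gate)


class _UpBlock(Module):
    """2x nearest-neighbour upsampling followed by a 3x3 convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 batch_norm: bool = True):
        bias = not batch_norm
        self.conv = Conv2D(cin, cout, 3, rng, bias=bias)
        self.bn = BatchNorm2D(cout) if batch_norm else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.conv(x.upsample2())
        if self.bn is not None:
            h = self.bn(h, training)
        return h.relu()


class SegmentationModel(Module):
    """Encoder–decoder segmentation network built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        unit_cls = ResidualUnit if spec.family == "arunet" else ForwardConvUnit
        widths = [spec.base_filters * 2 ** i for i in range(spec.depth)]
        bn = spec.batch_norm

        self.encoder = []
        cin = 3
        for w in widths:
            self.encoder.append(unit_cls(cin, w, rng, batch_norm=bn))
            cin = w

        self.use_attention = spec.family in ("aunet", "arunet")
        self.up_blocks, self.dec_units, self.gates = [], [], []
        for i in range(spec.depth - 2, -1, -1):
            w = widths[i]
            self.up_blocks.append(_UpBlock(widths[i + 1], w, rng, batch_norm=bn))
            if self.use_attention:
                self.gates.append(AttentionGate(w, widths[i + 1], rng))
            self.dec_units.append(unit_cls(2 * w, w, rng, batch_norm=bn))
        self.head = Conv2D(widths[0], spec.n_classes, 1, rng, bias=True)

    def forward(self, x, training: bool = False) -> Tensor:
        """Input NHWC float in [0, 1]; output per-pixel softmax (N, H, W, 2)."""
        x = nn.as_tensor(x)
        skips = []
        h = x
        for i, unit in enumerate(self.encoder):
            h = unit(h, training)
            if i < len(self.encoder) - 1:
                skips.append(h)
                h = h.maxpool2()
        for j, (up, unit) in enumerate(zip(self.up_blocks, self.dec_units)):
            skip = skips[-(j + 1)]
            if self.use_attention:
                skip = self.gates[j](skip, h)
            h = up(h, training)
            h = unit(concat([skip, h], axis=-1), training)
        return self.head(h).softmax(axis=-1)

    __call__ = forward

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(spec: ModelSpec) -> SegmentationModel:
    """Construct a segmentation network; same spec (incl. seed) gives
    identical initial parameters."""
    return SegmentationModel(spec)


def predict_patch(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities for one RGB patch.

    ``image`` is H x W x 3, uint8 or float; uint8 is normalized to [0, 1].
    Returns an H x W x 2 probability field (rows sum to 1).
    """
    image = np.asarray(image)
    expected = model.spec.input_size
    if image.shape[:2] != (expected, expected):
        raise ValueError(
            f"patch size {image.shape[:2]} does not match model input size "
            f"({expected}, {expected})"
        )
    x = image.astype(np.float32)
    if image.dtype == np.uint8:
        x = x / 255.0
    out = model.forward(x[None], training=False)
    return out.data[0]


# Functional wrappers over the shared blocks: build a freshly seeded block and
# apply it to an input feature map (NHWC numpy array or Tensor).

def forward_conv_unit(x, filters: int, seed: int = 0, batch_norm: bool = True):
    x = nn.as_tensor(x)
    unit = ForwardConvUnit(x.shape[-1], filters, np.random.default_rng(seed),
                           batch_norm=batch_norm)
    return unit, unit(x)


def residual_unit(x, filters: int, seed: int = 0, batch_norm: bool = True):
    x = nn.as_tensor(x)
    unit = ResidualUnit(x.shape[-1], filters, np.random.default_rng(seed),
                        batch_norm=batch_norm)
    return unit, unit(x)


def attention_gate(skip, gate, seed: int = 0):
    skip, gate = nn.as_tensor(skip), nn.as_tensor(gate)
    ag = AttentionGate(skip.shape[-1], gate.shape[-1], np.random.default_rng(seed))
    return ag, ag(skip, gate)
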