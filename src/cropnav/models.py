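"""Encoder–decoder segmentation networks for crop-row extraction.

Two architectures are provided:

* :func:`build_classic_enet` — the original lightweight ENet layout: an
  initial 2x-downsampling block, a stage-1 encoder at 1/4 resolution, a
  stage-2 encoder at 1/8 resolution with dilated and asymmetric bottlenecks,
  a repeated stage 3 at the same scale, and a decoder that restores
  resolution with max-unpooling indices saved by the encoder.

* :func:`build_improved_enet` — the variant this package is built around.
  Stage 3 is removed (model compression), the three bottlenecks 1.2–1.4 are
  replaced by dilation-2, asymmetric-5 and dilation-4 convolutions
  (convolution replacement), and a second processing pathway — the residual
  stream — accumulates the low-dimensional boundary information produced by
  each stage-1 bottleneck.  The pooling and residual streams are channel
  fused before stage 2 (with a stride-2 3x3 convolution bringing the
  residual map to the post-downsampling size), the decoder upsamples both
  streams by bilinear interpolation instead of max-unpooling, and a final
  1x1 classifier over the concatenated streams yields per-class score maps.

Both networks map an (N, 3, H, W) input, H and W divisible by 8, to
(N, n_classes, H, W) scores.  With ``n_classes = 2`` the crop logit fed to
the sigmoid is ``scores[crop] - scores[background]``, i.e. the single-logit
formulation of binary classification.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import CheckpointError, ParameterError, ShapeError
from .nn import Tensor
from .nn import autograd as ag

__all__ = [
    "BottleneckSpec",
    "ArchitectureSpec",
    "NetworkHandle",
    "build_improved_enet",
    "build_classic_enet",
    "count_trainable_parameters",
    "receptive_field_side",
    "normalize_image",
    "segment_image",
    "save_checkpoint",
    "load_checkpoint",
]

_KINDS = {"regular", "dilated", "asymmetric", "downsample", "upsample"}
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BottleneckSpec:
    """Declarative description of one bottleneck module."""

    kind: str
    dilation: int = 1
    asym_kernel: int = 5
    internal_ratio: int = 4
    dropout_p: float = 0.1

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown bottleneck kind {self.kind!r}")
        if self.dilation < 1:
            raise ParameterError("dilation must be >= 1")
        if self.kind == "dilated" and self.dilation < 2:
            raise ParameterError("dilated bottleneck requires dilation >= 2")
        if self.asym_kernel % 2 == 0 or self.asym_kernel < 3:
            raise ParameterError("asym_kernel must be odd and >= 3")
        if self.internal_ratio < 1:
            raise ParameterError("internal_ratio must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ParameterError("dropout_p must lie in [0, 1)")


def _stage2_kinds(dropout_p: float = 0.1) -> tuple[BottleneckSpec, ...]:
    """The dilated/asymmetric mix of ENet's second encoder stage."""
    return (
        BottleneckSpec("downsample", dropout_p=dropout_p),
        BottleneckSpec("regular", dropout_p=dropout_p),
        BottleneckSpec("dilated", dilation=2, dropout_p=dropout_p),
        BottleneckSpec("asymmetric", asym_kernel=5, dropout_p=dropout_p),
        BottleneckSpec("dilated", dilation=4, dropout_p=dropout_p),
        BottleneckSpec("regular", dropout_p=dropout_p),
        BottleneckSpec("dilated", dilation=8, dropout_p=dropout_p),
        BottleneckSpec("asymmetric", asym_kernel=5, dropout_p=dropout_p),
        BottleneckSpec("dilated", dilation=16, dropout_p=dropout_p),
    )


_DECODER = (
    BottleneckSpec("upsample", dropout_p=0.1),
    BottleneckSpec("regular", dropout_p=0.1),
    BottleneckSpec("regular", dropout_p=0.1),
    BottleneckSpec("upsample", dropout_p=0.1),
    BottleneckSpec("regular", dropout_p=0.1),
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a full segmentation network."""

    in_channels: int = 3
    n_classes: int = 2
    initial_width: int = 16
    stage1_width: int = 64
    stage2_width: int = 128
    width_multiplier: float = 1.0
    residual_stream: bool = True
    stage1: tuple[BottleneckSpec, ...] = ()
    stage2: tuple[BottleneckSpec, ...] = ()
    stage3: tuple[BottleneckSpec, ...] = ()
    decoder: tuple[BottleneckSpec, ...] = _DECODER
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def improved(cls, width_multiplier: float = 1.0, n_classes: int = 2) -> "ArchitectureSpec":
        """Default improved architecture: convolution replacement in 1.2–1.4,
        no stage 3, residual stream on."""
        stage1 = (
            BottleneckSpec("downsample", dropout_p=0.01),
            BottleneckSpec("regular", dropout_p=0.01),
            BottleneckSpec("dilated", dilation=2, dropout_p=0.01),
            BottleneckSpec("asymmetric", asym_kernel=5, dropout_p=0.01),
            BottleneckSpec("dilated", dilation=4, dropout_p=0.01),
        )
        return cls(
            width_multiplier=width_multiplier,
            n_classes=n_classes,
            residual_stream=True,
            stage1=stage1,
            stage2=_stage2_kinds(),
            stage3=(),
            decoder=_DECODER,
        )

    @classmethod
    def classic(cls, width_multiplier: float = 1.0, n_classes: int = 2) -> "ArchitectureSpec":
        """The original ENet layout, rebuilt as the comparison baseline."""
        stage1 = (BottleneckSpec("downsample", dropout_p=0.01),) + tuple(
            BottleneckSpec("regular", dropout_p=0.01) for _ in range(4)
        )
        return cls(
            width_multiplier=width_multiplier,
            n_classes=n_classes,
            residual_stream=False,
            stage1=stage1,
            stage2=_stage2_kinds(),
            stage3=_stage2_kinds()[1:],
            decoder=_DECODER,
        )

    # -- helpers ------------------------------------------------------------
    def width(self, base: int) -> int:
        return max(4, int(round(base * self.width_multiplier)))

    def validate(self) -> None:
        for b in (*self.stage1, *self.stage2, *self.stage3, *self.decoder):
            b.validate()
        if self.n_classes not in (1, 2):
            raise ParameterError("n_classes must be 1 or 2 (binary segmentation)")
        if self.width_multiplier <= 0:
            raise ParameterError("width_multiplier must be positive")
        if self.width(self.initial_width) <= self.in_channels:
            raise ParameterError("initial_width too small for the initial block")
        down = [b.kind for b in (*self.stage1, *self.stage2, *self.stage3)].count("downsample")
        if down != 2 or self.stage1[0].kind != "downsample" or self.stage2[0].kind != "downsample":
            raise ParameterError("encoder must open stage 1 and stage 2 with its two downsamples")
        if [b.kind for b in self.decoder].count("upsample") != 2:
            raise ParameterError("decoder must contain exactly two upsample bottlenecks")
        if self.residual_stream and self.stage3:
            raise ParameterError("the residual-stream model removes stage 3")
        if not self.residual_stream and not self.stage3:
            raise ParameterError("the classic baseline retains stage 3")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        for key in ("stage1", "stage2", "stage3", "decoder"):
            d[key] = tuple(BottleneckSpec(**b) for b in d.get(key, ()))
        return cls(**d)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


class _InitialBlock(nn.Module):
    """3x3/2 convolution concatenated with a 2x2 max-pool of the input."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch - in_ch, 3, rng, stride=2, padding=1, bias=False, dtype=dtype)
        self.bn = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.act = nn.PReLU(dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        pooled, _ = ag.max_pool2x2(x)
        out = ag.concat([self.conv(x), pooled], axis=1)
        return self.act(self.bn(out))


def _main_conv(spec: BottleneckSpec, internal: int, rng, dtype) -> nn.Module:
    if spec.kind == "asymmetric":
        k = spec.asym_kernel
        return nn.Sequential(
            nn.Conv2d(internal, internal, (k, 1), rng, padding=(k // 2, 0), bias=False, dtype=dtype),
            nn.Conv2d(internal, internal, (1, k), rng, padding=(0, k // 2), bias=False, dtype=dtype),
        )
    dilation = spec.dilation if spec.kind == "dilated" else 1
    return nn.Conv2d(internal, internal, 3, rng, padding=dilation, dilation=dilation, bias=False, dtype=dtype)


class _RegularBottleneck(nn.Module):
    """1x1 reduce → main convolution (regular/dilated/asymmetric) → 1x1 expand."""

    def __init__(self, channels: int, spec: BottleneckSpec, rng, rng_box, dtype):
        super().__init__()
        internal = max(1, channels // spec.internal_ratio)
        self.reduce = nn.Conv2d(channels, internal, 1, rng, bias=False, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(internal, dtype=dtype)
        self.act1 = nn.PReLU(dtype=dtype)
        self.main = _main_conv(spec, internal, rng, dtype)
        self.bn2 = nn.BatchNorm2d(internal, dtype=dtype)
        self.act2 = nn.PReLU(dtype=dtype)
        self.expand = nn.Conv2d(internal, channels, 1, rng, bias=False, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(channels, dtype=dtype)
        self.dropout = nn.Dropout2d(spec.dropout_p, rng_box)
        self.out_act = nn.PReLU(dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        ext = self.act1(self.bn1(self.reduce(x)))
        ext = self.act2(self.bn2(self.main(ext)))
        ext = self.dropout(self.bn3(self.expand(ext)))
        return self.out_act(ag.add(x, ext))


class _DownsampleBottleneck(nn.Module):
    """Strided bottleneck; the main branch max-pools and zero-pads channels."""

    def __init__(self, in_ch: int, out_ch: int, spec: BottleneckSpec, rng, rng_box, dtype):
        super().__init__()
        internal = max(1, max(in_ch, out_ch) // spec.internal_ratio)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.reduce = nn.Conv2d(in_ch, internal, 2, rng, stride=2, bias=False, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(internal, dtype=dtype)
        self.act1 = nn.PReLU(dtype=dtype)
        self.main = nn.Conv2d(internal, internal, 3, rng, padding=1, bias=False, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(internal, dtype=dtype)
        self.act2 = nn.PReLU(dtype=dtype)
        self.expand = nn.Conv2d(internal, out_ch, 1, rng, bias=False, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.dropout = nn.Dropout2d(spec.dropout_p, rng_box)
        self.out_act = nn.PReLU(dtype=dtype)

    def forward(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        pooled, idx = ag.max_pool2x2(x)
        if self.out_ch > self.in_ch:
            pad = Tensor(
                np.zeros(
                    (pooled.shape[0], self.out_ch - self.in_ch, *pooled.shape[2:]),
                    dtype=pooled.data.dtype,
                )
            )
            pooled = ag.concat([pooled, pad], axis=1)
        ext = self.act1(self.bn1(self.reduce(x)))
        ext = self.act2(self.bn2(self.main(ext)))
        ext = self.dropout(self.bn3(self.expand(ext)))
        return self.out_act(ag.add(pooled, ext)), idx


class _UpsampleBottleneck(nn.Module):
    """Decoder bottleneck; restores resolution by max-unpooling (classic) or
    bilinear interpolation (improved)."""

    def __init__(self, in_ch: int, out_ch: int, spec: BottleneckSpec, rng, rng_box, dtype, use_unpool: bool):
        super().__init__()
        # the extended branch works at a quarter of the wider interface width
        internal = max(1, max(in_ch, out_ch) // spec.internal_ratio)
        self.use_unpool = use_unpool
        self.main_conv = nn.Conv2d(in_ch, out_ch, 1, rng, bias=False, dtype=dtype)
        self.main_bn = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.reduce = nn.Conv2d(in_ch, internal, 1, rng, bias=False, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(internal, dtype=dtype)
        self.act1 = nn.PReLU(dtype=dtype)
        if use_unpool:
            self.mid = nn.ConvTranspose2d(internal, internal, 3, rng, stride=2, padding=1, output_padding=1, bias=False, dtype=dtype)
        else:
            self.mid = nn.Conv2d(internal, internal, 3, rng, padding=1, bias=False, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(internal, dtype=dtype)
        self.act2 = nn.PReLU(dtype=dtype)
        self.expand = nn.Conv2d(internal, out_ch, 1, rng, bias=False, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.dropout = nn.Dropout2d(spec.dropout_p, rng_box)
        self.out_act = nn.PReLU(dtype=dtype)

    def forward(self, x: Tensor, indices: np.ndarray | None = None) -> Tensor:
        main = self.main_bn(self.main_conv(x))
        out_h, out_w = 2 * x.shape[2], 2 * x.shape[3]
        if self.use_unpool:
            if indices is None:
                raise ShapeError("classic upsample bottleneck requires pooling indices")
            main = ag.max_unpool2x2(main, indices)
        else:
            main = ag.bilinear_resize(main, out_h, out_w)
        ext = self.act1(self.bn1(self.reduce(x)))
        if self.use_unpool:
            ext = self.mid(ext)
        else:
            ext = self.mid(ag.bilinear_resize(ext, out_h, out_w))
        ext = self.act2(self.bn2(ext))
        ext = self.dropout(self.bn3(self.expand(ext)))
        return self.out_act(ag.add(main, ext))


def _check_input(x: np.ndarray | Tensor, in_channels: int) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.data.ndim != 4 or t.data.shape[1] != in_channels:
        raise ShapeError(f"expected (N, {in_channels}, H, W) input, got {t.data.shape}")
    h, w = t.data.shape[2:]
    if h % 8 or w % 8:
        raise ShapeError(f"spatial dimensions must be divisible by 8, got {h}x{w}")
    return t


class ImprovedENet(nn.Module):
    """ENet with residual boundary stream, convolution replacement and no stage 3."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        super().__init__()
        spec.validate()
        if not spec.residual_stream:
            raise ParameterError("ImprovedENet requires residual_stream=True")
        self.spec = spec
        self.rng_box = nn.RngBox(np.random.default_rng(seed))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        iw, s1w, s2w = (spec.width(v) for v in (spec.initial_width, spec.stage1_width, spec.stage2_width))
        box, dt = self.rng_box, dtype

        self.initial = _InitialBlock(spec.in_channels, iw, rng, dt)
        self.down1 = _DownsampleBottleneck(iw, s1w, spec.stage1[0], rng, box, dt)
        self.stage1 = nn.ModuleList(
            _RegularBottleneck(s1w, b, rng, box, dt) for b in spec.stage1[1:]
        )
        # channel fusion of pooling + residual maps at the stage-2 entry
        self.fuse_conv = nn.Conv2d(2 * s1w, s1w, 1, rng, bias=False, dtype=dt)
        self.fuse_bn = nn.BatchNorm2d(s1w, dtype=dt)
        self.fuse_act = nn.PReLU(dtype=dt)
        # stride-2 3x3 convolution matching the residual map to the new scale
        self.res_conv = nn.Conv2d(s1w, s1w, 3, rng, stride=2, padding=1, bias=False, dtype=dt)
        self.res_bn = nn.BatchNorm2d(s1w, dtype=dt)
        self.down2 = _DownsampleBottleneck(s1w, s2w, spec.stage2[0], rng, box, dt)
        self.stage2 = nn.ModuleList(
            _RegularBottleneck(s2w, b, rng, box, dt) for b in spec.stage2[1:]
        )
        self.decoder = nn.ModuleList()
        ch = s2w
        widths = iter((s1w, iw))
        for b in spec.decoder:
            if b.kind == "upsample":
                nxt = next(widths)
                self.decoder.append(_UpsampleBottleneck(ch, nxt, b, rng, box, dt, use_unpool=False))
                ch = nxt
            else:
                self.decoder.append(_RegularBottleneck(ch, b, rng, box, dt))
        self.head = nn.Conv2d(ch + s1w, spec.n_classes, 1, rng, bias=True, dtype=dt)

    def forward(self, x) -> Tensor:
        x = _check_input(x, self.spec.in_channels)
        h, w = x.shape[2:]
        p = self.initial(x)
        p, _ = self.down1(p)
        r = p  # initial residual feature map
        for block in self.stage1:
            p = block(p)
            r = ag.add(r, p)  # accumulate boundary information
        p = self.fuse_act(self.fuse_bn(self.fuse_conv(ag.concat([p, r], axis=1))))
        p, _ = self.down2(p)
        r = self.res_bn(self.res_conv(r))
        for block in self.stage2:
            p = block(p)
        for block in self.decoder:
            if isinstance(block, _UpsampleBottleneck):
                p = block(p)
                r = ag.bilinear_resize(r, p.shape[2], p.shape[3])
            else:
                p = block(p)
        scores = self.head(ag.concat([p, r], axis=1))
        return ag.bilinear_resize(scores, h, w)


class ClassicENet(nn.Module):
    """The original ENet baseline with stage 3 and max-unpooling decoder."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        super().__init__()
        spec.validate()
        if spec.residual_stream:
            raise ParameterError("ClassicENet requires residual_stream=False")
        self.spec = spec
        self.rng_box = nn.RngBox(np.random.default_rng(seed))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        iw, s1w, s2w = (spec.width(v) for v in (spec.initial_width, spec.stage1_width, spec.stage2_width))
        box, dt = self.rng_box, dtype

        self.initial = _InitialBlock(spec.in_channels, iw, rng, dt)
        self.down1 = _DownsampleBottleneck(iw, s1w, spec.stage1[0], rng, box, dt)
        self.stage1 = nn.ModuleList(_RegularBottleneck(s1w, b, rng, box, dt) for b in spec.stage1[1:])
        self.down2 = _DownsampleBottleneck(s1w, s2w, spec.stage2[0], rng, box, dt)
        self.stage2 = nn.ModuleList(_RegularBottleneck(s2w, b, rng, box, dt) for b in spec.stage2[1:])
        self.stage3 = nn.ModuleList(_RegularBottleneck(s2w, b, rng, box, dt) for b in spec.stage3)
        self.decoder = nn.ModuleList()
        ch = s2w
        widths = iter((s1w, iw))
        for b in spec.decoder:
            if b.kind == "upsample":
                nxt = next(widths)
                self.decoder.append(_UpsampleBottleneck(ch, nxt, b, rng, box, dt, use_unpool=True))
                ch = nxt
            else:
                self.decoder.append(_RegularBottleneck(ch, b, rng, box, dt))
        self.fullconv = nn.ConvTranspose2d(ch, spec.n_classes, 3, rng, stride=2, padding=1, output_padding=1, bias=True, dtype=dt)

    def forward(self, x) -> Tensor:
        x = _check_input(x, self.spec.in_channels)
        p = self.initial(x)
        p, idx1 = self.down1(p)
        for block in self.stage1:
            p = block(p)
        p, idx2 = self.down2(p)
        for block in self.stage2:
            p = block(p)
        for block in self.stage3:
            p = block(p)
        indices = iter((idx2, idx1))
        for block in self.decoder:
            if isinstance(block, _UpsampleBottleneck):
                p = block(p, next(indices))
            else:
                p = block(p)
        return self.fullconv(p)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


@dataclass
class NetworkHandle:
    """A built network together with its spec and trainable-parameter count."""

    net: nn.Module
    spec: ArchitectureSpec
    parameter_count: int

    def __call__(self, x) -> Tensor:
        return self.net(x)

    def train(self, mode: bool = True) -> "NetworkHandle":
        self.net.train(mode)
        return self

    def eval(self) -> "NetworkHandle":
        self.net.eval()
        return self


def count_trainable_parameters(net) -> int:
    """Exact number of trainable scalar weights in a module or handle."""
    module = net.net if isinstance(net, NetworkHandle) else net
    return int(sum(p.data.size for p in module.parameters() if p.requires_grad))


def build_improved_enet(spec: ArchitectureSpec | None = None, seed: int = 0, dtype=np.float32) -> NetworkHandle:
    spec = spec if spec is not None else ArchitectureSpec.improved()
    net = ImprovedENet(spec, seed=seed, dtype=dtype)
    return NetworkHandle(net=net, spec=spec, parameter_count=count_trainable_parameters(net))


def build_classic_enet(spec: ArchitectureSpec | None = None, seed: int = 0, dtype=np.float32) -> NetworkHandle:
    spec = spec if spec is not None else ArchitectureSpec.classic()
    net = ClassicENet(spec, seed=seed, dtype=dtype)
    return NetworkHandle(net=net, spec=spec, parameter_count=count_trainable_parameters(net))


def receptive_field_side(kernel: int, dilation: int = 1) -> int:
    """Side length of the receptive field of a (possibly dilated) square kernel.

    A kernel of odd size k with dilation rate d covers d*(k - 1) + 1 pixels
    per side: dilation inserts d - 1 zeros between taps, widening the field
    without adding parameters.
    """
    if int(kernel) != kernel or kernel < 1 or kernel % 2 == 0:
        raise ParameterError("kernel must be a positive odd integer")
    if int(dilation) != dilation or dilation < 1:
        raise ParameterError("dilation must be a positive integer")
    return int(dilation) * (int(kernel) - 1) + 1


#: Per-channel normalisation applied to 8-bit imagery before the network.
IMAGE_MEAN = 0.5
IMAGE_STD = 0.25


def normalize_image(image: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(H, W, 3) 8-bit image -> (3, H, W) float in the training convention."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError(f"expected (H, W, 3) image, got {img.shape}")
    x = img.astype(np.float64) / 255.0
    x = (x - IMAGE_MEAN) / IMAGE_STD
    return x.transpose(2, 0, 1).astype(dtype)


def crop_logit(scores: Tensor) -> Tensor:
    """Reduce per-class score maps to the single crop logit."""
    if scores.shape[1] == 1:
        data = scores.data[:, 0]

        def backward(grad):
            scores._accumulate(grad[:, None])

        return Tensor._result(data, (scores,), backward)
    data = scores.data[:, 1] - scores.data[:, 0]

    def backward(grad):
        g = np.stack([-grad, grad], axis=1)
        scores._accumulate(g)

    return Tensor._result(data, (scores,), backward)


def segment_image(net: NetworkHandle, image: np.ndarray) -> np.ndarray:
    """Per-pixel crop probability for an (H, W, 3) image, in [0, 1].

    Runs the network in inference mode and applies the sigmoid to the crop
    logit; thresholding the result at 0.5 yields the binary mask consumed by
    the line-fitting stage.
    """
    was_training = net.net.training
    net.eval()
    try:
        x = normalize_image(image)[None]
        scores = net(x)
        logit = crop_logit(scores)
        prob = 1.0 / (1.0 + np.exp(-np.clip(logit.data[0].astype(np.float64), -60, 60)))
    finally:
        net.net.train(was_training)
    return prob


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(net: NetworkHandle, path) -> Path:
    """Serialize weights plus the architecture spec (versioned JSON sidecar)."""
    path = Path(path)
    state = net.net.state_dict()
    payload = {f"param::{k}": v for k, v in state.items()}
    payload["spec_json"] = np.frombuffer(
        json.dumps(net.spec.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path, seed: int = 0) -> NetworkHandle:
    path = Path(path)
    if not path.exists():
        candidate = path.with_suffix(path.suffix + ".npz")
        if candidate.exists():
            path = candidate
        else:
            raise CheckpointError(f"checkpoint not found: {path}")
    try:
        with np.load(path) as data:
            spec = ArchitectureSpec.from_dict(json.loads(bytes(data["spec_json"]).decode()))
            state = {
                key[len("param::") :]: data[key] for key in data.files if key.startswith("param::")
            }
    except (OSError, KeyError, ValueError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if spec.schema_version != SCHEMA_VERSION:
        raise CheckpointError(
            f"checkpoint schema v{spec.schema_version} unsupported (expected v{SCHEMA_VERSION})"
        )
    handle = build_improved_enet(spec, seed=seed) if spec.residual_stream else build_classic_enet(spec, seed=seed)
    try:
        handle.net.load_state_dict(state)
    except (KeyError, ValueError) as exc:
        raise CheckpointError(f"checkpoint incompatible with its spec: {exc}") from exc
    return handle
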