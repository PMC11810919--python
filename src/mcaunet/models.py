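"""The segmentation model family.

Four architectures built from one encoder–decoder skeleton:

* **U-Net** — the classic baseline: five encoder stages of two 3x3 convolutions
  (ReLU, biased, same padding) with 2x2 max-pooling between them, a decoder of
  2x2 transposed convolutions with skip concatenation, and a 1x1 sigmoid output.
  No normalization layers.  With channel widths 16/32/64/128/256 and one input
  channel this configuration has exactly 1,940,817 parameters.
* **SEU-Net** — the same baseline with a channel squeeze-and-excitation (cSE)
  block appended after each encoder stage's convolutions.
* **MCA block** — the multi-scale channel attention block: parallel convolutions
  with kernels 3/5/7 (or 5/7/9) fused by a 1x1 convolution, followed by channel
  attention whose descriptor pools the fused map globally and at average-pooled
  scales 2 and 4.  Either half can be ablated independently.
* **MCAU-Net** — U-Net whose first 1–3 encoder stages are replaced by MCA
  blocks; its decoder stages add batch normalization and a 1x1-projection
  residual shortcut.

All models are fully convolutional: parameter counts are independent of the
input size, and any input with height/width divisible by 2^(depth-1) (and by 4
at the stages holding MCA blocks) is mapped to a same-sized probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import nn
from .nn import Module, Tensor


class SpecError(ValueError):
    """Invalid architecture specification."""


@dataclass
class ArchitectureSpec:
    """Full hyperparameterization of one model variant."""

    variant: str = "unet"  # {"unet", "seunet", "mcau"}
    input_size: tuple[int, int] = (256, 256)
    input_channels: int = 1
    depth: int = 5
    channel_schedule: tuple[int, ...] = (16, 32, 64, 128, 256)
    n_mca_blocks: int = 0
    kernel_set: tuple[int, int, int] = (3, 5, 7)
    pooling_factors: tuple[int, int] = (2, 4)
    attention_reduction: int = 4
    descriptor_combine: str = "mean"  # {"mean", "sum", "concat"}
    enable_multiscale_conv: bool = True
    enable_channel_attention: bool = True

    def __post_init__(self):
        self.channel_schedule = tuple(self.channel_schedule)
        self.kernel_set = tuple(self.kernel_set)
        self.pooling_factors = tuple(self.pooling_factors)
        self.input_size = tuple(self.input_size)
        if self.variant not in ("unet", "seunet", "mcau"):
            raise SpecError(f"unknown variant {self.variant!r}")
        if len(self.channel_schedule) != self.depth:
            raise SpecError("channel_schedule length must equal depth")
        base = self.channel_schedule[0]
        if any(c != base * 2**i for i, c in enumerate(self.channel_schedule)):
            raise SpecError("channel_schedule must double at each stage")
        ks = self.kernel_set
        if any(k % 2 == 0 for k in ks) or list(ks) != sorted(set(ks)):
            raise SpecError("kernel_set must be odd and strictly increasing")
        if not 0 <= self.n_mca_blocks <= self.depth - 1:
            raise SpecError("n_mca_blocks must lie in {0..depth-1}")
        if self.descriptor_combine not in ("mean", "sum", "concat"):
            raise SpecError(f"unknown descriptor_combine {self.descriptor_combine!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls(**yaml.safe_load(text))


def unet_spec(base: int = 16, depth: int = 5, **kw) -> ArchitectureSpec:
    sched = tuple(base * 2**i for i in range(depth))
    return ArchitectureSpec(variant="unet", depth=depth, channel_schedule=sched, **kw)


def seunet_spec(base: int = 16, depth: int = 5, **kw) -> ArchitectureSpec:
    sched = tuple(base * 2**i for i in range(depth))
    return ArchitectureSpec(variant="seunet", depth=depth, channel_schedule=sched, **kw)


def mcau_spec(n_blocks: int = 2, base: int = 16, depth: int = 5, **kw) -> ArchitectureSpec:
    if not 1 <= n_blocks <= 3:
        raise SpecError("MCAU-Net supports 1 to 3 MCA blocks")
    sched = tuple(base * 2**i for i in range(depth))
    return ArchitectureSpec(
        variant="mcau", depth=depth, channel_schedule=sched, n_mca_blocks=n_blocks, **kw
    )


@dataclass
class LayerCount:
    total: int
    trainable: int
    non_trainable: int


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class DoubleConv(Module):
    """Two same-padded 3x3 convolutions with ReLU (the baseline encoder stage)."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.relu(self.c2(nn.relu(self.c1(x))))


class CSEBlock(Module):
    """Channel squeeze-and-excitation: GAP -> FC(C->C/r) -> ReLU -> FC(C/r->C)
    -> sigmoid -> per-channel gate.

    ``force_identity_gate`` replaces the sigmoid output with ones; used to
    verify that attention reduces to the identity when fully open.
    """

    def __init__(self, channels, reduction, rng, in_features=None):
        if channels % reduction != 0:
            raise SpecError(
                f"channels ({channels}) must be divisible by reduction ({reduction})"
            )
        hidden = channels // reduction
        self.fc1 = nn.Dense(in_features or channels, hidden, rng)
        self.fc2 = nn.Dense(hidden, channels, rng)
        self.force_identity_gate = False

    def excite(self, desc: Tensor) -> Tensor:
        s = nn.sigmoid(self.fc2(nn.relu(self.fc1(desc))))
        if self.force_identity_gate:
            s = Tensor(np.ones_like(s.data))
        return s

    def __call__(self, x: Tensor) -> Tensor:
        return nn.channel_gate(x, self.excite(nn.global_avgpool(x)))


def build_cse_block(channels: int, reduction: int, rng=None) -> CSEBlock:
    return CSEBlock(channels, reduction, rng or np.random.default_rng(0))


class MCABlock(Module):
    """Multi-scale channel attention block (replaces an encoder stage's two
    convolutions).

    Part A — multi-scale feature extraction: parallel same-padded convolutions
    with the spec's kernel sizes, each emitting ``cout`` channels with ReLU,
    concatenated and fused back to ``cout`` channels by a 1x1 convolution.
    Part B — multi-scale channel attention: the fused map is average-pooled at
    the spec's factors; global average pooling of the fused map and of each
    pooled map yields one descriptor per scale; descriptors are combined
    (mean/sum/concat) and drive a cSE excitation whose weights gate the fused
    map.  Either part can be disabled, in which case the block degrades
    gracefully toward the plain two-convolution stage.
    """

    def __init__(self, cin, cout, spec: ArchitectureSpec, rng):
        self.enable_ms = spec.enable_multiscale_conv
        self.enable_att = spec.enable_channel_attention
        self.pooling_factors = spec.pooling_factors
        self.combine = spec.descriptor_combine
        if self.enable_ms:
            self.branches = [nn.Conv2d(cin, cout, k, rng) for k in spec.kernel_set]
            self.fuse = nn.Conv2d(cout * len(spec.kernel_set), cout, 1, rng)
        else:
            self.extract = DoubleConv(cin, cout, rng)
        if self.enable_att:
            n_scales = 1 + len(self.pooling_factors)
            in_features = cout * n_scales if self.combine == "concat" else cout
            self.cse = CSEBlock(
                cout, spec.attention_reduction, rng, in_features=in_features
            )

    def __call__(self, x: Tensor) -> Tensor:
        if self.enable_ms:
            feats = [nn.relu(b(x)) for b in self.branches]
            y = nn.relu(self.fuse(nn.concat(feats, axis=1)))
        else:
            y = self.extract(x)
        if not self.enable_att:
            return y
        descs = [nn.global_avgpool(y)]
        for f in self.pooling_factors:
            descs.append(nn.global_avgpool(nn.avgpool(y, f)))
        if self.combine == "mean":
            desc = nn.average(descs)
        elif self.combine == "sum":
            desc = nn.sum_tensors(descs)
        else:  # concat
            desc = nn.concat(descs, axis=1)
        return nn.channel_gate(y, self.cse.excite(desc))


def build_mca_block(channels: int, spec: ArchitectureSpec, rng=None) -> MCABlock:
    """Standalone MCA block with ``channels`` in and out."""
    return MCABlock(channels, channels, spec, rng or np.random.default_rng(0))


class DecoderStage(Module):
    """Plain U-Net decoder stage: upsample, concat skip, two 3x3 convolutions."""

    def __init__(self, cin, cout, rng):
        self.up = nn.ConvTranspose2d(cin, cout, rng)
        self.convs = DoubleConv(2 * cout, cout, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        return self.convs(nn.concat([self.up(x), skip], axis=1))


class ResidualDecoderStage(Module):
    """MCAU-Net decoder stage: upsample, concat skip, two 3x3 conv+BN, and a
    1x1-projection shortcut added to the second convolution's output before the
    final ReLU."""

    def __init__(self, cin, cout, rng):
        self.up = nn.ConvTranspose2d(cin, cout, rng)
        self.c1 = nn.Conv2d(2 * cout, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.proj = nn.Conv2d(2 * cout, cout, 1, rng)

    def __call__(self, x: Tensor, skip: Tensor, training: bool) -> Tensor:
        cat = nn.concat([self.up(x), skip], axis=1)
        y = nn.relu(self.bn1(self.c1(cat), training))
        y = self.bn2(self.c2(y), training)
        return nn.relu(nn.add(y, self.proj(cat)))


class SegmentationNet(Module):
    """Encoder–decoder network assembled from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, rng):
        self.spec = spec
        ch = spec.channel_schedule
        cins = (spec.input_channels,) + ch[:-1]
        self.encoders = []
        self.cse_blocks = []  # SEU-Net only
        for i in range(spec.depth):
            if spec.variant == "mcau" and i < spec.n_mca_blocks:
                self.encoders.append(MCABlock(cins[i], ch[i], spec, rng))
            else:
                self.encoders.append(DoubleConv(cins[i], ch[i], rng))
            if spec.variant == "seunet":
                self.cse_blocks.append(
                    CSEBlock(ch[i], spec.attention_reduction, rng)
                )
        self.decoders = []
        for i in range(spec.depth - 1, 0, -1):
            stage = (
                ResidualDecoderStage(ch[i], ch[i - 1], rng)
                if spec.variant == "mcau"
                else DecoderStage(ch[i], ch[i - 1], rng)
            )
            self.decoders.append(stage)
        self.head = nn.Conv2d(ch[0], 1, 1, rng)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        skips = []
        for i, enc in enumerate(self.encoders):
            y = enc(x)
            if self.cse_blocks:
                y = self.cse_blocks[i](y)
            if i < len(self.encoders) - 1:
                skips.append(y)
                x = nn.maxpool2(y)
            else:
                x = y
        for dec, skip in zip(self.decoders, reversed(skips)):
            if isinstance(dec, ResidualDecoderStage):
                x = dec(x, skip, training)
            else:
                x = dec(x, skip)
        return nn.sigmoid(self.head(x))


class ModelHandle:
    """A built network plus its forward convenience wrapper.

    ``forward`` accepts a (N, H, W) or (H, W) float array of normalized
    intensities and returns per-pixel foreground probabilities of the same
    spatial shape.
    """

    def __init__(self, net: SegmentationNet, spec: ArchitectureSpec):
        self.net = net
        self.spec = spec
        self.training = False

    def forward(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        images = np.asarray(images, dtype=nn.DEFAULT_DTYPE)
        single = images.ndim == 2
        if single:
            images = images[None]
        outs = []
        for i in range(0, len(images), batch_size):
            x = Tensor(images[i : i + batch_size, None])
            outs.append(self.net(x, training=self.training).data[:, 0])
        probs = np.concatenate(outs, axis=0)
        return probs[0] if single else probs

    __call__ = forward

    def set_force_identity_gates(self, value: bool) -> None:
        """Force every attention gate fully open (for ablation checks)."""
        for m in self.net.modules():
            if isinstance(m, CSEBlock):
                m.force_identity_gate = value

    def summary(self) -> str:
        c = count_parameters(self)
        return (
            f"{self.spec.variant} depth={self.spec.depth} "
            f"channels={self.spec.channel_schedule} "
            f"params total={c.total:,} trainable={c.trainable:,} "
            f"non-trainable={c.non_trainable:,}"
        )


def _build(spec: ArchitectureSpec, seed: int = 0) -> ModelHandle:
    rng = np.random.default_rng(seed)
    return ModelHandle(SegmentationNet(spec, rng), spec)


def build_unet(spec: ArchitectureSpec | None = None, seed: int = 0) -> ModelHandle:
    spec = spec or unet_spec()
    if spec.variant != "unet":
        raise SpecError("build_unet requires variant 'unet'")
    return _build(spec, seed)


def build_seunet(spec: ArchitectureSpec | None = None, seed: int = 0) -> ModelHandle:
    spec = spec or seunet_spec()
    if spec.variant != "seunet":
        raise SpecError("build_seunet requires variant 'seunet'")
    return _build(spec, seed)


def build_mcau_net(spec: ArchitectureSpec | None = None, seed: int = 0) -> ModelHandle:
    spec = spec or mcau_spec(2)
    if spec.variant != "mcau":
        raise SpecError("build_mcau_net requires variant 'mcau'")
    if not 1 <= spec.n_mca_blocks <= 3:
        raise SpecError("MCAU-Net requires 1 to 3 MCA blocks")
    return _build(spec, seed)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ModelHandle:
    return {
        "unet": build_unet,
        "seunet": build_seunet,
        "mcau": build_mcau_net,
    }[spec.variant](spec, seed)


def count_parameters(model: ModelHandle | Module) -> LayerCount:
    """Exact parameter totals, split into trainable weights and non-trainable
    state (batch-normalization running statistics)."""
    net = model.net if isinstance(model, ModelHandle) else model
    trainable = int(sum(p.data.size for p in net.parameters()))
    non_trainable = int(sum(b.size for b in net.buffers()))
    return LayerCount(trainable + non_trainable, trainable, non_trainable)


# printed reference bound for the transformer-hybrid baseline (not reimplemented)
TRANSUNET_TOTAL_PARAMS = 103_239_195
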