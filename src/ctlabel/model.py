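"""2-D encoder-decoder segmentation networks.

A residual ("ResNet"-style basic-block) encoder feeds either a U-Net decoder
(skip concatenation at every resolution) or a Feature Pyramid Network (FPN)
decoder (lateral 1x1 projections merged top-down). The network maps a
single-channel CT slice, normalised to [0, 1], to a per-pixel probability map
through a sigmoid. Input height and width must be divisible by 32 (five
2x downsampling stages).

The default configuration is the 34-layer encoder with a U-Net decoder;
``width_multiplier`` scales every channel count so that desk-scale tests can
train a tiny variant of the same architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np

from . import nn
from .nn import Tensor

# basic-block counts per stage for the supported residual encoder depths
_ENCODER_STAGES = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}
_UNET_DECODER_CHANNELS = (256, 128, 64, 32, 16)
_FPN_PYRAMID_CHANNELS = 256
_FPN_SEGMENTATION_CHANNELS = 128


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the network."""


class NoInputError(ValueError):
    """An operation received an empty input sequence."""


class IncompatibleWeightsError(ValueError):
    """Serialized weights do not match the model being loaded into."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture configuration.

    encoder_depth: 18 or 34 (basic-block residual encoder).
    decoder: "unet" (skip concatenation) or "fpn" (feature pyramid).
    width_multiplier: scales all channel counts; 1.0 is the full-size net.
    pretrained: hook for externally supplied encoder weights; off by default
        so the package builds with no downloads.
    """

    encoder_depth: int = 34
    decoder: str = "unet"
    in_channels: int = 1
    out_channels: int = 1
    pretrained: bool = False
    width_multiplier: float = 1.0

    def __post_init__(self):
        if self.decoder not in ("unet", "fpn"):
            raise ValueError(f"decoder must be 'unet' or 'fpn', got {self.decoder!r}")
        if self.encoder_depth not in _ENCODER_STAGES:
            raise ValueError(
                f"encoder_depth must be one of {sorted(_ENCODER_STAGES)}"
            )
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


@dataclass
class ProbabilityMap:
    """Per-pixel foreground probabilities for one slice."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        self.pixels = p


def _check_divisible(h: int, w: int):
    if h % 32 or w % 32:
        raise ShapeError(f"spatial dims must be divisible by 32, got {h}x{w}")


class _BasicBlock(nn.Module):
    def __init__(self, c_in, c_out, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def __call__(self, x):
        identity = x
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class _ResNetEncoder(nn.Module):
    """Residual encoder emitting features at 1/2, 1/4, 1/8, 1/16, 1/32 scale."""

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        w = spec.scaled
        self.channels = [w(64), w(64), w(128), w(256), w(512)]
        self.stem_conv = nn.Conv2d(
            spec.in_channels, self.channels[0], 7, stride=2, padding=3, bias=False, rng=rng
        )
        self.stem_bn = nn.BatchNorm2d(self.channels[0])
        blocks = _ENCODER_STAGES[spec.encoder_depth]
        stages = []
        c_in = self.channels[0]
        for stage_idx, n_blocks in enumerate(blocks):
            c_out = self.channels[stage_idx + 1]
            stage = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage_idx > 0) else 1
                stage.append(_BasicBlock(c_in, c_out, stride, rng))
                c_in = c_out
            stages.append(nn.ModuleList(stage))
        self.stages = nn.ModuleList(stages)

    def __call__(self, x: Tensor) -> List[Tensor]:
        f1 = self.stem_bn(self.stem_conv(x)).relu()  # 1/2
        feats = [f1]
        h = nn.maxpool2x2(f1)  # 1/4
        for stage in self.stages:
            for block in stage:
                h = block(h)
            feats.append(h)  # 1/4, 1/8, 1/16, 1/32
        return feats


class _ConvBnRelu(nn.Module):
    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, padding=1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class _UnetDecoder(nn.Module):
    def __init__(self, spec: ModelSpec, encoder_channels, rng):
        super().__init__()
        dec = [spec.scaled(c) for c in _UNET_DECODER_CHANNELS]
        # skips consumed deepest-first: 1/16, 1/8, 1/4, 1/2, then none
        skips = list(reversed(encoder_channels[:-1])) + [0]
        c_in = encoder_channels[-1]
        blocks = []
        for c_skip, c_out in zip(skips, dec):
            blocks.append(
                nn.ModuleList(
                    [_ConvBnRelu(c_in + c_skip, c_out, rng), _ConvBnRelu(c_out, c_out, rng)]
                )
            )
            c_in = c_out
        self.blocks = nn.ModuleList(blocks)
        self.head = nn.Conv2d(dec[-1], spec.out_channels, 1, rng=rng)

    def __call__(self, feats: List[Tensor]) -> Tensor:
        skips = list(reversed(feats[:-1]))
        h = feats[-1]
        for i, block in enumerate(self.blocks):
            h = nn.upsample2x(h)
            if i < len(skips):
                h = nn.concat_channels([h, skips[i]])
            h = block[1](block[0](h))
        return self.head(h)


class _FpnDecoder(nn.Module):
    """Lateral 1x1 projections merged top-down, fused at 1/4 scale."""

    def __init__(self, spec: ModelSpec, encoder_channels, rng):
        super().__init__()
        p = spec.scaled(_FPN_PYRAMID_CHANNELS)
        s = spec.scaled(_FPN_SEGMENTATION_CHANNELS)
        # pyramid over 1/4 .. 1/32 features
        self.laterals = nn.ModuleList(
            [nn.Conv2d(c, p, 1, rng=rng) for c in encoder_channels[1:]]
        )
        self.seg_convs = nn.ModuleList([_ConvBnRelu(p, s, rng) for _ in range(4)])
        self.fuse = _ConvBnRelu(s, s, rng)
        self.head = nn.Conv2d(s, spec.out_channels, 1, rng=rng)

    def __call__(self, feats: List[Tensor]) -> Tensor:
        pyramid_feats = feats[1:]  # 1/4, 1/8, 1/16, 1/32
        laterals = [lat(f) for lat, f in zip(self.laterals, pyramid_feats)]
        merged = [laterals[-1]]
        for lat in reversed(laterals[:-1]):
            merged.append(lat + nn.upsample2x(merged[-1]))
        merged.reverse()  # back to fine-to-coarse order
        fused = None
        for level, (m, seg) in enumerate(zip(merged, self.seg_convs)):
            h = seg(m)
            for _ in range(level):  # bring every level to 1/4 scale
                h = nn.upsample2x(h)
            fused = h if fused is None else fused + h
        h = self.fuse(fused)
        h = nn.upsample2x(nn.upsample2x(h))  # 1/4 -> full resolution
        return self.head(h)


class SegmentationModel(nn.Module):
    """Encoder-decoder network; callable on (N, C, H, W) arrays."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.encoder = _ResNetEncoder(spec, rng)
        if spec.decoder == "unet":
            self.decoder = _UnetDecoder(spec, self.encoder.channels, rng)
        else:
            self.decoder = _FpnDecoder(spec, self.encoder.channels, rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if c != self.spec.in_channels:
            raise ShapeError(
                f"expected {self.spec.in_channels} input channels, got {c}"
            )
        _check_divisible(h, w)
        return self.decoder(self.encoder(x))

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=nn.DTYPE))
        return self.forward_logits(x).sigmoid()


def build_model(spec: ModelSpec, seed: int = 0) -> SegmentationModel:
    """Construct a segmentation model with seeded random initialisation.

    With ``pretrained=False`` (the default) every encoder and decoder weight
    is drawn from a generator seeded with ``seed``, so two builds with the
    same spec and seed are bit-identical. ``pretrained=True`` is an optional
    hook: it requires externally supplied encoder weights via
    ``load_weights`` and performs no download.
    """
    return SegmentationModel(spec, seed=seed)


def predict_probabilities(model: SegmentationModel, slices: Sequence[np.ndarray],
                          y_max: int = 65535, batch_size: int = 8) -> List[ProbabilityMap]:
    """Run inference on stored-intensity slices (normalised by ``y_max``)."""
    slices = list(slices)
    if not slices:
        raise NoInputError("no slices to predict on")
    model.eval()
    maps: List[ProbabilityMap] = []
    for start in range(0, len(slices), batch_size):
        chunk = slices[start : start + batch_size]
        x = np.stack([np.asarray(s, dtype=nn.DTYPE) / float(y_max) for s in chunk])
        out = model(x[:, None, :, :])
        for k in range(out.data.shape[0]):
            maps.append(ProbabilityMap(np.clip(out.data[k, 0], 0.0, 1.0)))
    return maps


def predict_mask(model: SegmentationModel, slices: Sequence[np.ndarray],
                 threshold: float = 0.5, y_max: int = 65535,
                 batch_size: int = 8) -> List[np.ndarray]:
    """Threshold probability maps into boolean masks, slice order preserved.

    A pixel with probability exactly equal to ``threshold`` is included
    (>= convention).
    """
    maps = predict_probabilities(model, slices, y_max=y_max, batch_size=batch_size)
    return [threshold_probabilities(m, threshold) for m in maps]


def threshold_probabilities(pmap: ProbabilityMap, threshold: float = 0.5) -> np.ndarray:
    return pmap.pixels >= threshold


def save_weights(model: SegmentationModel, path) -> None:
    """Serialize spec + weights to an .npz archive."""
    state = model.state_dict()
    np.savez(path, __spec__=np.frombuffer(model.spec.to_json().encode(), np.uint8),
             **state)


def load_weights(model: SegmentationModel, path) -> SegmentationModel:
    """Load weights saved by :func:`save_weights` into a compatible model."""
    path = Path(path)
    with np.load(path) as archive:
        stored = {k: archive[k] for k in archive.files}
    spec_raw = stored.pop("__spec__", None)
    if spec_raw is not None:
        saved_spec = ModelSpec.from_json(bytes(spec_raw.tobytes()).decode())
        if saved_spec != model.spec:
            raise IncompatibleWeightsError(
                f"weights were saved for {saved_spec}, model is {model.spec}"
            )
    try:
        model.load_state_dict(stored)
    except (KeyError, ValueError) as exc:
        raise IncompatibleWeightsError(str(exc)) from exc
    return model
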