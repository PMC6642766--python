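"""Encoder-decoder segmentation network for CSF in axial CT slices.

A U-Net whose encoder follows the ResNet34 basic-block layout (configurable
block counts so a desk-scale variant runs quickly on CPU) and whose decoder
mirrors it stage by stage: pixel-shuffle upsampling with ICNR ("subpixel
convolution") initialization to avoid checkerboard artifacts, skip
connections from the matching encoder stage, and one self-attention block in
the decoder stage going from stride 16 to stride 8. The head is a 1×1
convolution followed by a per-pixel softmax, so the output is a per-voxel
class-probability map at input resolution.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .preprocess import DEFAULT_WINDOW, preprocess_slice
from .volume_io import CTVolume, MaskVolume

__all__ = [
    "SegModelConfig",
    "DESK_PROFILE",
    "ProbabilityVolume",
    "SegmentationModel",
    "build_model",
    "icnr_init",
    "predict_exam",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-size configuration (512×512 inputs, ResNet34
    block layout [3, 4, 6, 3], 64 base channels); ``DESK_PROFILE`` is the
    small CPU-friendly variant used by the automated tests.
    """

    input_size: int = 512
    encoder_blocks: tuple[int, int, int, int] = (3, 4, 6, 3)
    base_channels: int = 64
    n_classes: int = 2
    self_attention: bool = True
    pretrained_weights_path: str | None = None

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.encoder_blocks) != 4 or any(b < 1 for b in self.encoder_blocks):
            raise ValueError(f"encoder_blocks must be 4 positive counts, got {self.encoder_blocks}")


#: small profile used by all automated tests: 64 px, one block per stage, 16 channels
DESK_PROFILE = SegModelConfig(input_size=64, encoder_blocks=(1, 1, 1, 1), base_channels=16)


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities aligned to a CT volume.

    ``probs`` has shape ``(n_slices, rows, cols, n_classes)``; probabilities
    on each voxel sum to 1.
    """

    probs: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""
    exam_id: str = ""

    def csf_probability(self) -> np.ndarray:
        return self.probs[..., 1]


def icnr_init(
    out_channels: int,
    in_channels: int,
    kernel_size: int,
    scale: int = 2,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ICNR kernel for a convolution feeding a pixel shuffle.

    A He-initialized sub-kernel with ``out_channels / scale²`` filters is
    repeated ``scale²`` times along the output-channel axis, so that at
    initialization pixel-shuffling the convolution output reproduces
    nearest-neighbour upsampling of the sub-kernel's convolution output
    (every ``scale × scale`` output block is constant).
    """
    r2 = scale * scale
    if out_channels % r2 != 0:
        raise ValueError(f"out_channels {out_channels} not divisible by scale² = {r2}")
    rng = rng or np.random.default_rng(0)
    std = np.sqrt(2.0 / (in_channels * kernel_size * kernel_size))
    sub = rng.normal(0.0, std, size=(out_channels // r2, in_channels, kernel_size, kernel_size))
    return np.repeat(sub, r2, axis=0).astype(np.float32)


class PixelShuffleUpsample(nn.Module):
    """1×1 conv (ICNR init) + pixel shuffle: doubles spatial size."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels * 4, 1, rng=rng)
        self.conv.weight.data = icnr_init(out_channels * 4, in_channels, 1, scale=2, rng=rng)
        self.shuffle = nn.PixelShuffle(2)

    def forward(self, x: Tensor) -> Tensor:
        return self.shuffle(self.conv(x))


def _conv_bn_relu(cin: int, cout: int, k: int, stride: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class BasicBlock(nn.Module):
    """Two 3×3 convs with a residual shortcut (ResNet basic block)."""

    def __init__(self, cin: int, cout: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout),
            )
        else:
            self.shortcut = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + self.shortcut(x)).relu()


class DecoderStage(nn.Module):
    """Pixel-shuffle upsample ×2, concatenate the encoder skip, fuse with conv."""

    def __init__(self, cin: int, c_skip: int, cout: int, rng, attention: bool = False):
        super().__init__()
        self.up = PixelShuffleUpsample(cin, cin // 2, rng)
        self.fuse = _conv_bn_relu(cin // 2 + c_skip, cout, 3, 1, rng)
        self.attention = nn.SelfAttention2d(cout, rng=rng) if attention else nn.Identity()

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.up(x)
        x = nn.concat([x, skip], axis=1)
        return self.attention(self.fuse(x))


class SegmentationModel(nn.Module):
    """U-Net over preprocessed (3, H, W) slices → (n_classes, H, W) probabilities."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        b = config.base_channels

        self.stem = _conv_bn_relu(3, b, 7, 2, rng)  # stride 2
        self.pool = nn.MaxPool2d(3, 2, 1)  # stride 4
        widths = (b, 2 * b, 4 * b, 8 * b)
        strides = (1, 2, 2, 2)
        self.stages = []
        cin = b
        for n_blocks, cout, s in zip(config.encoder_blocks, widths, strides):
            blocks = [BasicBlock(cin, cout, s, rng)]
            blocks += [BasicBlock(cout, cout, 1, rng) for _ in range(n_blocks - 1)]
            self.stages.append(nn.Sequential(*blocks))
            cin = cout

        self.dec16 = DecoderStage(8 * b, 4 * b, 4 * b, rng)  # stride 32 → 16
        self.dec8 = DecoderStage(4 * b, 2 * b, 2 * b, rng, attention=config.self_attention)
        self.dec4 = DecoderStage(2 * b, b, b, rng)  # stride 8 → 4
        self.dec2 = DecoderStage(b, b, b, rng)  # stride 4 → 2
        self.final_up = PixelShuffleUpsample(b, b, rng)  # stride 2 → 1
        self.final_conv = _conv_bn_relu(b, b, 3, 1, rng)
        self.head = nn.Conv2d(b, config.n_classes, 1, rng=rng)

    def logits(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError(f"spatial size ({H}, {W}) must be divisible by 32")
        s2 = self.stem(x)
        s4 = self.stages[0](self.pool(s2))
        s8 = self.stages[1](s4)
        s16 = self.stages[2](s8)
        s32 = self.stages[3](s16)
        d16 = self.dec16(s32, s16)
        d8 = self.dec8(d16, s8)
        d4 = self.dec4(d8, s4)
        d2 = self.dec2(d4, s2)
        d1 = self.final_conv(self.final_up(d2))
        return self.head(d1)

    def forward(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=1)

    def upsample_blocks(self) -> list[PixelShuffleUpsample]:
        """All pixel-shuffle upsampling blocks (for the ICNR init property)."""
        return [m for m in self.modules() if isinstance(m, PixelShuffleUpsample)]


def build_model(config: SegModelConfig, seed: int = 0) -> SegmentationModel:
    """Build the network; optionally load weights from ``pretrained_weights_path``."""
    model = SegmentationModel(config, seed=seed)
    if config.pretrained_weights_path:
        _load_weights_into(model, config.pretrained_weights_path)
    return model


def predict_exam(
    model: SegmentationModel,
    volume: CTVolume,
    window: tuple[float, float] = DEFAULT_WINDOW,
    batch_size: int = 10,
    resize: bool = False,
) -> tuple[ProbabilityVolume, MaskVolume]:
    """Segment every slice of an exam independently (2D inference).

    Each slice is preprocessed (window → equalize → 3-channel) and pushed
    through the network; the mask is the per-voxel argmax class. Slice size
    must equal ``config.input_size`` unless ``resize`` is set, in which case
    slices are bilinearly resized for inference and the probabilities are
    resized back to the native grid.
    """
    from scipy import ndimage

    size = model.config.input_size
    H, W = volume.shape[1], volume.shape[2]
    if (H, W) != (size, size) and not resize:
        raise ValueError(
            f"slice size ({H}, {W}) incompatible with model input {size}; "
            "pass resize=True to rescale"
        )
    model.eval()
    slices = [preprocess_slice(s, *window) for s in volume.voxels]
    x_all = np.stack(slices, axis=0)
    if (H, W) != (size, size) and resize:
        zoom = (1, size / H, size / W)
        x_all = np.stack([ndimage.zoom(s, zoom, order=1) for s in x_all], axis=0)
    probs_out = []
    with nn.no_grad():
        for start in range(0, len(x_all), batch_size):
            batch = Tensor(x_all[start : start + batch_size].astype(np.float32))
            probs_out.append(model(batch).data)
    probs = np.concatenate(probs_out, axis=0)  # (S, C, h, w)
    if probs.shape[2:] != (H, W):
        zoom = (1, H / probs.shape[2], W / probs.shape[3])
        probs = np.stack([ndimage.zoom(p, zoom, order=1) for p in probs], axis=0)
        probs = np.clip(probs, 1e-8, None)
        probs /= probs.sum(axis=1, keepdims=True)
    probs = np.moveaxis(probs, 1, -1).astype(np.float32)  # (S, H, W, C)
    labels = (probs.argmax(axis=-1) == 1).astype(np.uint8)
    pvol = ProbabilityVolume(
        probs=probs,
        spacing=volume.spacing,
        patient_id=volume.patient_id,
        exam_id=volume.exam_id,
    )
    mask = MaskVolume(
        labels=labels,
        spacing=volume.spacing,
        patient_id=volume.patient_id,
        exam_id=volume.exam_id,
    )
    return pvol, mask


# ---------------------------------------------------------------------------
# checkpoints: npz of named parameters + BN buffers, config embedded as JSON


def save_model(model: SegmentationModel, path: str | os.PathLike) -> None:
    arrays = {"param." + k: p.data for k, p in model.named_parameters()}
    arrays.update({"buffer." + k: b for k, b in model.named_buffers()})
    cfg = asdict(model.config)
    cfg["encoder_blocks"] = list(cfg["encoder_blocks"])
    arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez_compressed(os.fspath(path), **arrays)


def load_model(path: str | os.PathLike) -> SegmentationModel:
    with np.load(os.fspath(path)) as data:
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["encoder_blocks"] = tuple(cfg["encoder_blocks"])
        model = SegmentationModel(SegModelConfig(**cfg))
        _assign_weights(model, data)
    return model


def _assign_weights(model: SegmentationModel, data) -> None:
    params = dict(model.named_parameters())
    buffers = dict(model.named_buffers())
    for key in data.files:
        if key.startswith("param."):
            params[key[6:]].data = data[key].copy()
        elif key.startswith("buffer."):
            buffers[key[7:]][...] = data[key]


def _load_weights_into(model: SegmentationModel, path) -> None:
    """Optional hook for loading externally trained weights (same npz layout)."""
    with np.load(os.fspath(path)) as data:
        _assign_weights(model, data)
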