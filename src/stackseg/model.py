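"""U-Net segmentation model: ResNet34-topology encoder, pixel-shuffle decoder.

The descending arc follows the classic ResNet34 layout (7x7 stem at
stride 2, 3x3 max pool, four stages of basic blocks with 3/4/6/3 blocks
and widths 64/128/256/512), giving a total downsampling factor of 32.
The ascending arc upsamples with pixel shuffle — a 1x1 convolution
expands channels by r^2 = 4 and a pure index rearrangement doubles the
spatial resolution, which avoids the checkerboard artifacts of strided
transposed convolutions — and consumes encoder features through
concatenation skip connections, one per resolution level.  A final
pixel-shuffle stage restores full resolution and a 1x1 head emits
two-class logits (channel 0 = background, channel 1 = cell).

``width_multiplier`` and ``blocks_per_stage`` scale the topology down for
CPU-scale experiments; the defaults reproduce the full ResNet34 shape.
Encoder weights are randomly initialized by default; a user-supplied
encoder checkpoint can be injected via ``init_encoder_from``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BasicBlock,
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    MaxPool2d,
    Module,
    PixelShuffle,
    ReLU,
    Sequential,
    pixel_shuffle,
    pixel_unshuffle,
)
from .stack_io import MaskLabel

RESNET34_BLOCKS = (3, 4, 6, 3)
DOWNSAMPLE_FACTOR = 32  # stem (2) * pool (2) * three strided stages (2^3)


@dataclass(frozen=True)
class ModelConfig:
    input_channels: int = 3
    n_classes: int = 2
    width_multiplier: float = 1.0
    blocks_per_stage: tuple[int, int, int, int] = RESNET34_BLOCKS
    base_width: int = 64
    decoder_widths: tuple[int, int, int, int] | None = None  # derived if None
    head_width: int | None = None
    bn_momentum: float = 0.02   # running-stat update rate; small values
                                # suit the short epochs of desk-scale runs
    init_encoder_from: str | None = None  # optional weight file hook

    def __post_init__(self):
        if self.n_classes != 2:
            raise ValueError("the segmentation head is two-class (cell/background)")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if len(self.blocks_per_stage) != 4 or min(self.blocks_per_stage) < 1:
            raise ValueError("blocks_per_stage must be four counts >= 1")

    def _scale(self, w: int) -> int:
        return max(4, int(round(w * self.width_multiplier)))

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        b = self.base_width
        return tuple(self._scale(w) for w in (b, b, 2 * b, 4 * b, 8 * b))

    @property
    def resolved_decoder_widths(self) -> tuple[int, ...]:
        if self.decoder_widths is not None:
            return self.decoder_widths
        b = self.base_width
        return tuple(self._scale(w) for w in (4 * b, 2 * b, b, b))

    @property
    def resolved_head_width(self) -> int:
        return self.head_width or self._scale(self.base_width // 2)


class ResNetEncoder(Module):
    """Descending arc; exposes one feature map per resolution level."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        w = config.encoder_widths  # (stem, s1, s2, s3, s4)
        self.stem = self.add_child(ConvBNReLU(
            config.input_channels, w[0], k=7, stride=2, rng=rng))
        self.pool = self.add_child(MaxPool2d(3, 2, 1))
        self.stages: list[Sequential] = []
        cin = w[0]
        for s, (width, n_blocks) in enumerate(zip(w[1:], config.blocks_per_stage)):
            stride = 1 if s == 0 else 2
            blocks = [BasicBlock(cin, width, stride, rng=rng)]
            blocks += [BasicBlock(width, width, 1, rng=rng)
                       for _ in range(n_blocks - 1)]
            stage = Sequential(*blocks)
            self.stages.append(self.add_child(stage))
            cin = width

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        f1 = self.stem.forward(x)          # 1/2
        f = self.pool.forward(f1)          # 1/4
        feats = [f1]
        for stage in self.stages:
            f = stage.forward(f)           # 1/4, 1/8, 1/16, 1/32
            feats.append(f)
        return feats

    def backward(self, dfeats: list[np.ndarray]) -> np.ndarray:
        d = dfeats[-1]
        for stage, dskip in zip(reversed(self.stages), reversed(dfeats[1:-1])):
            d = stage.backward(d)
            d = d + dskip
        d = self.stages[0].backward(d)
        d = self.pool.backward(d)
        d = d + dfeats[0]
        return self.stem.backward(d)


class UnetBlock(Module):
    """One decoder level: pixel-shuffle upsample, concat skip, refine."""

    def __init__(self, cin: int, skip_c: int, out_c: int,
                 rng: np.random.Generator):
        super().__init__()
        up_c = max(4, out_c // 2)
        self.up_c = up_c
        self.upconv = self.add_child(Conv2d(cin, 4 * up_c, 1, pad=0, rng=rng))
        self.shuffle = self.add_child(PixelShuffle(2))
        self.conv1 = self.add_child(ConvBNReLU(up_c + skip_c, out_c, rng=rng))
        self.conv2 = self.add_child(ConvBNReLU(out_c, out_c, rng=rng))

    def forward(self, x: np.ndarray, skip: np.ndarray) -> np.ndarray:
        u = self.shuffle.forward(self.upconv.forward(x))
        cat = np.concatenate([u, skip], axis=1)
        return self.conv2.forward(self.conv1.forward(cat))

    def backward(self, dout: np.ndarray):
        dcat = self.conv1.backward(self.conv2.backward(dout))
        du, dskip = dcat[:, :self.up_c], dcat[:, self.up_c:]
        dx = self.upconv.backward(self.shuffle.backward(du))
        return dx, dskip


class UNet(Module):
    """The full network; ``forward`` keeps caches for ``backward``."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.encoder = self.add_child(ResNetEncoder(config, rng))
        enc_w = config.encoder_widths
        dec_w = config.resolved_decoder_widths
        # decoder consumes (f5, skip f4), ..., down to (out, skip f1)
        skips = [enc_w[3], enc_w[2], enc_w[1], enc_w[0]]
        cin = enc_w[4]
        self.blocks: list[UnetBlock] = []
        for skip_c, out_c in zip(skips, dec_w):
            self.blocks.append(self.add_child(UnetBlock(cin, skip_c, out_c, rng)))
            cin = out_c
        hw = config.resolved_head_width
        self.final_upconv = self.add_child(Conv2d(cin, 4 * hw, 1, pad=0, rng=rng))
        self.final_shuffle = self.add_child(PixelShuffle(2))
        self.final_conv = self.add_child(ConvBNReLU(hw, hw, rng=rng))
        self.head = self.add_child(Conv2d(hw, config.n_classes, 1, pad=0, rng=rng))
        self._encoder_frozen = False

    # -- training-phase control -------------------------------------------
    def freeze_encoder(self) -> None:
        self.encoder.set_trainable(False)
        self._encoder_frozen = True

    def unfreeze_encoder(self) -> None:
        self.encoder.set_trainable(True)
        self._encoder_frozen = False

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        N, C, H, W = x.shape
        if C != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} channels, got {C}")
        if H % DOWNSAMPLE_FACTOR or W % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"input size {H}x{W} not divisible by {DOWNSAMPLE_FACTOR}; "
                f"pad the input to a multiple of {DOWNSAMPLE_FACTOR}")
        feats = self.encoder.forward(x)
        y = feats[-1]
        for block, skip in zip(self.blocks, reversed(feats[:-1])):
            y = block.forward(y, skip)
        y = self.final_conv.forward(
            self.final_shuffle.forward(self.final_upconv.forward(y)))
        return self.head.forward(y)

    def backward(self, dlogits: np.ndarray) -> np.ndarray | None:
        d = self.head.backward(dlogits)
        d = self.final_upconv.backward(self.final_shuffle.backward(
            self.final_conv.backward(d)))
        dskips = []
        for block in reversed(self.blocks):
            d, dskip = block.backward(d)
            dskips.append(dskip)
        if self._encoder_frozen:
            return None  # no need to run the frozen encoder's backward
        dfeats = dskips + [d]  # grads for [f1, f2, f3, f4] + bottleneck
        return self.encoder.backward(dfeats)

    # -- parameter groups for discriminative learning rates ----------------
    def parameter_groups(self) -> list[list]:
        """Three groups: early encoder, late encoder, decoder + head."""
        enc_children = self.encoder._children  # stem, pool, 4 stages
        early = [p for m in enc_children[:4] for p in m.parameters()]
        late = [p for m in enc_children[4:] for p in m.parameters()]
        dec = [p for m in self._children[1:] for p in m.parameters()]
        return [early, late, dec]


def build_model(config: ModelConfig, seed: int | None = None) -> UNet:
    """Construct (and optionally warm-start the encoder of) a UNet."""
    rng = np.random.default_rng(seed)
    model = UNet(config, rng)
    for bn in _batchnorms(model):
        bn.momentum = config.bn_momentum
    if config.init_encoder_from:
        load_encoder_weights(model, config.init_encoder_from)
    return model


def predict_mask(model: UNet, sub: np.ndarray) -> MaskLabel:
    """Argmax segmentation; logit ties go to background.

    Biasing ties toward background errs on the side of fewer
    false-positive pixels.
    """
    x = np.asarray(sub, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    was_training = model.training
    model.set_training(False)
    logits = model.forward(x)
    model.set_training(was_training)
    cell = logits[:, 1] > logits[:, 0]
    return MaskLabel(cell[0].astype(np.uint8))


def logits_to_mask(logits: np.ndarray) -> np.ndarray:
    """(N, 2, H, W) logits -> (N, H, W) binary masks, ties to background."""
    return (logits[:, 1] > logits[:, 0]).astype(np.uint8)


# ---------------------------------------------------------------------------
# Checkpoints: single .npz with parameter arrays + BN buffers + config JSON
# ---------------------------------------------------------------------------

def _state_arrays(model: UNet) -> dict[str, np.ndarray]:
    out = {}
    for i, p in enumerate(model.parameters()):
        out[f"param_{i:04d}"] = p.data
    for i, bn in enumerate(_batchnorms(model)):
        out[f"bn_{i:04d}_mean"] = bn.running_mean
        out[f"bn_{i:04d}_var"] = bn.running_var
    return out


def _batchnorms(module: Module) -> list[BatchNorm2d]:
    found = []
    if isinstance(module, BatchNorm2d):
        found.append(module)
    for c in module._children:
        found.extend(_batchnorms(c))
    return found


def save_checkpoint(model: UNet, path) -> None:
    arrays = _state_arrays(model)
    arrays["_config"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path, seed: int | None = None) -> UNet:
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["_config"].tobytes()).decode())
        cfg_dict["blocks_per_stage"] = tuple(cfg_dict["blocks_per_stage"])
        if cfg_dict.get("decoder_widths"):
            cfg_dict["decoder_widths"] = tuple(cfg_dict["decoder_widths"])
        model = build_model(ModelConfig(**cfg_dict), seed=seed)
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i:04d}"].copy()
        for i, bn in enumerate(_batchnorms(model)):
            bn.running_mean = data[f"bn_{i:04d}_mean"].copy()
            bn.running_var = data[f"bn_{i:04d}_var"].copy()
    return model


def load_encoder_weights(model: UNet, path) -> None:
    """Inject user-supplied encoder weights (the transfer-learning hook).

    The file must be an .npz whose ``param_*`` arrays match the encoder's
    parameter shapes in traversal order (e.g. written by
    :func:`save_encoder_weights`).
    """
    params = model.encoder.parameters()
    with np.load(Path(path)) as data:
        keys = sorted(k for k in data.files if k.startswith("param_"))
        if len(keys) != len(params):
            raise ValueError(
                f"encoder weight file has {len(keys)} arrays, model encoder "
                f"has {len(params)} parameters")
        for key, p in zip(keys, params):
            arr = data[key]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: file {arr.shape} vs "
                    f"model {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()
        bns = _batchnorms(model.encoder)
        for i, bn in enumerate(bns):
            if f"bn_{i:04d}_mean" in data.files:
                bn.running_mean = data[f"bn_{i:04d}_mean"].copy()
                bn.running_var = data[f"bn_{i:04d}_var"].copy()


def save_encoder_weights(model: UNet, path) -> None:
    arrays = {}
    for i, p in enumerate(model.encoder.parameters()):
        arrays[f"param_{i:04d}"] = p.data
    for i, bn in enumerate(_batchnorms(model.encoder)):
        arrays[f"bn_{i:04d}_mean"] = bn.running_mean
        arrays[f"bn_{i:04d}_var"] = bn.running_var
    np.savez(Path(path), **arrays)
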