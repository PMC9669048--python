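"""The separable-convolution encoder-decoder with atrous spatial pyramid pooling.

Encoder: a conventional stride-2 stem convolution followed by four
preactivation residual stages, each built from three separable convolutions
(the third with stride 2) and a stride-2 pointwise shortcut — 5 downsamplings
in total, so the bottleneck runs at 1/32 of the input length.  The cardiac
refractory period (no two peaks within 200 ms) is what licenses compressing
this far: the bottleneck needs to carry at most one peak per ~2 frames.

ASPP at the bottleneck: parallel branches with dilations [1, 3, 6, 9] (the
rate-1 branch is a pointwise convolution) plus a segment-pooling branch that
averages features over blocks of bottleneck frames corresponding to 2048
input samples, broadcast back; branches are concatenated and projected.

Decoder: x8 linear upsampling, concatenation with a pointwise-reduced skip
from the stride-4 encoder stage, two separable convolutions, x4 upsampling,
and a pointwise head with a sigmoid — per-sample peak probabilities at the
input length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autodiff as F
from .nn.autodiff import Tensor, no_grad
from .nn.layers import Conv1d, ConvBnElu, Module, SeparableConv1d

__all__ = [
    "ModelConfig",
    "PeakNet",
    "build_model",
    "count_parameters",
    "dice_loss",
    "dice_loss_grad",
    "save_checkpoint",
    "load_checkpoint",
]

DOWNSAMPLE = 32  # stride of the bottleneck relative to the input


@dataclass
class ModelConfig:
    in_channels: int = 2
    stem_channels: int = 16
    block_channels: tuple = (32, 64, 128, 256)
    aspp_channels: int = 128
    skip_channels: int = 32
    decoder_channels: int = 64
    aspp_dilations: tuple = (1, 3, 6, 9)
    pooling_unit: int = 2048    # input samples averaged by the ASPP pool branch
    kernel_size: int = 3
    downsample_count: int = 5
    separable: bool = True      # False swaps in conventional convolutions
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if tuple(self.aspp_dilations) != (1, 3, 6, 9):
            raise ValueError("ASPP dilations are fixed at (1, 3, 6, 9)")
        if self.downsample_count != 5:
            raise ValueError("the encoder downsamples exactly 5 times")
        if len(self.block_channels) != 4:
            raise ValueError("need one channel count per residual stage (4)")
        channels = (self.stem_channels, *self.block_channels, self.aspp_channels,
                    self.skip_channels, self.decoder_channels)
        if any(c <= 0 for c in channels):
            raise ValueError("channel counts must be positive")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.pooling_unit % DOWNSAMPLE != 0:
            raise ValueError(f"pooling_unit must be a multiple of {DOWNSAMPLE}")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _spatial_conv(cin, cout, separable, *, k=3, stride=1, dilation=1, rng, dtype):
    if separable:
        return SeparableConv1d(cin, cout, k, stride, dilation, rng=rng, dtype=dtype)
    return Conv1d(cin, cout, k, stride, dilation, rng=rng, dtype=dtype)


class ResidualStage(Module):
    """Preactivation residual block: ELU, three separable convolutions
    (conv -> BN -> ELU each, the third at stride 2), plus a stride-2
    pointwise shortcut."""

    def __init__(self, cin, cout, separable, *, k=3, rng, dtype):
        super().__init__()
        self.conv1 = ConvBnElu(_spatial_conv(cin, cout, separable, k=k, rng=rng, dtype=dtype), cout, dtype=dtype)
        self.conv2 = ConvBnElu(_spatial_conv(cout, cout, separable, k=k, rng=rng, dtype=dtype), cout, dtype=dtype)
        self.conv3 = ConvBnElu(
            _spatial_conv(cout, cout, separable, k=k, stride=2, rng=rng, dtype=dtype), cout, dtype=dtype
        )
        self.shortcut = Conv1d(cin, cout, 1, stride=2, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        h = F.elu(x)
        main = self.conv3(self.conv2(self.conv1(h)))
        return F.add(main, self.shortcut(h))


class ASPP(Module):
    def __init__(self, cin, cout, dilations, seg_frames, separable, *, k=3, rng, dtype):
        super().__init__()
        self.seg_frames = seg_frames
        self.branch1 = ConvBnElu(Conv1d(cin, cout, 1, rng=rng, dtype=dtype), cout, dtype=dtype)
        self.dilated = [
            ConvBnElu(_spatial_conv(cin, cout, separable, k=k, dilation=d, rng=rng, dtype=dtype), cout, dtype=dtype)
            for d in dilations[1:]
        ]
        self.pool_proj = ConvBnElu(Conv1d(cin, cout, 1, rng=rng, dtype=dtype), cout, dtype=dtype)
        n_branches = 2 + len(self.dilated)
        self.project = ConvBnElu(Conv1d(n_branches * cout, cout, 1, rng=rng, dtype=dtype), cout, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        branches = [self.branch1(x)]
        branches += [b(x) for b in self.dilated]
        branches.append(self.pool_proj(F.segment_pool(x, self.seg_frames)))
        return self.project(F.concat(branches, axis=1))


class PeakNet(Module):
    """Per-sample R-peak probability model for (B, 2, L) feature windows."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype
        sep = cfg.separable

        k = cfg.kernel_size
        self.stem = ConvBnElu(
            Conv1d(cfg.in_channels, cfg.stem_channels, k, stride=2, rng=rng, dtype=dt),
            cfg.stem_channels, dtype=dt,
        )
        chans = [cfg.stem_channels, *cfg.block_channels]
        self.stages = [
            ResidualStage(chans[i], chans[i + 1], sep, k=k, rng=rng, dtype=dt) for i in range(4)
        ]
        self.aspp = ASPP(
            cfg.block_channels[-1], cfg.aspp_channels, cfg.aspp_dilations,
            cfg.pooling_unit // DOWNSAMPLE, sep, k=k, rng=rng, dtype=dt,
        )
        self.skip = ConvBnElu(
            Conv1d(cfg.block_channels[0], cfg.skip_channels, 1, rng=rng, dtype=dt),
            cfg.skip_channels, dtype=dt,
        )
        dec_in = cfg.aspp_channels + cfg.skip_channels
        self.dec1 = ConvBnElu(
            _spatial_conv(dec_in, cfg.decoder_channels, sep, k=k, rng=rng, dtype=dt),
            cfg.decoder_channels, dtype=dt,
        )
        self.dec2 = ConvBnElu(
            _spatial_conv(cfg.decoder_channels, cfg.decoder_channels, sep, k=k, rng=rng, dtype=dt),
            cfg.decoder_channels, dtype=dt,
        )
        self.head = Conv1d(cfg.decoder_channels, 1, 1, rng=rng, dtype=dt)

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.ascontiguousarray(x, dtype=self.cfg.np_dtype))
        if x.data.ndim != 3 or x.data.shape[1] != self.cfg.in_channels:
            raise ValueError("input must have shape (batch, channels, length)")
        if x.data.shape[2] % DOWNSAMPLE != 0:
            raise ValueError(f"input length must be a multiple of {DOWNSAMPLE}")
        h = self.stem(x)                      # L/2
        skip_src = None
        for i, stage in enumerate(self.stages):
            h = stage(h)                      # L/4, L/8, L/16, L/32
            if i == 0:
                skip_src = h                  # stride-4 features for the decoder
        h = self.aspp(h)
        h = F.upsample_linear(h, 8)           # L/32 -> L/4
        h = F.concat([h, self.skip(skip_src)], axis=1)
        h = self.dec2(self.dec1(h))
        h = F.upsample_linear(h, 4)           # L/4 -> L
        return F.squeeze_channel(F.sigmoid(self.head(h)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference probabilities for (B, 2, L) inputs (eval statistics)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self(x).data
        finally:
            self.train(was_training)
        return np.asarray(out, dtype=float)


def build_model(cfg: ModelConfig, seed: int = 0) -> PeakNet:
    """Construct a model with seed-deterministic initial parameters."""
    return PeakNet(cfg, seed)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s), averaged over the batch."""
    return dice_loss_grad(pred, target, smooth)[0]


def dice_loss_grad(pred, target, smooth: float = 1.0):
    """Loss value and its gradient with respect to the predictions."""
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    t = np.atleast_2d(np.asarray(target, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1) + smooth
    num = 2.0 * inter + smooth
    loss = float(np.mean(1.0 - num / denom))
    B = p.shape[0]
    grad = (num[:, None] / denom[:, None] ** 2 - 2.0 * t / denom[:, None]) / B
    return loss, grad


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str, model: PeakNet, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights, BN statistics and embedded config."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.cfg),
        "extra": extra or {},
    }
    arrays = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> tuple[PeakNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_d = meta["config"]
        cfg_d["block_channels"] = tuple(cfg_d["block_channels"])
        cfg_d["aspp_dilations"] = tuple(cfg_d["aspp_dilations"])
        cfg = ModelConfig(**cfg_d)
        model = PeakNet(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta["extra"]
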