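"""Training loop: per-epoch noise augmentation, dice loss, Adam, and early
stopping on the F1 score of an internal validation pass.

Each epoch draws a fresh set of augmented windows (so the model never sees
the same waveform twice), optimizes the dice loss in mini-batches, then runs
the full detection pipeline — sliding inference, 150 ms moving-window
average, thresholded refractory peak picking, tolerance matching — on the
un-augmented records.  The checkpoint with the best validation F1 wins;
training stops after `patience` epochs without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentConfig, NoiseTemplates, draw_training_window
from .evaluation import Metrics, compute_metrics, evaluate_record, pool_counts
from .localization import LocalizeConfig, localize
from .network import ModelConfig, PeakNet, build_model, dice_loss_grad
from .nn.autodiff import Tensor, backward
from .nn.layers import Adam
from .preprocess import featurize, preprocess_record
from .records import BeatAnnotations, ECGRecord

__all__ = ["TrainConfig", "TrainResult", "train", "validate_internal"]


@dataclass
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    windows_per_epoch: int | None = None  # default: total samples / window
    lr: float = 1e-3
    lr_patience: int = 5         # halve the learning rate on an F1 plateau
    lr_factor: float = 0.5
    dice_smooth: float = 1.0
    min_improve: float = 1e-5    # strict-increase tolerance for early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainResult:
    model: PeakNet
    history: list[dict]
    best_f1: float
    best_epoch: int


def validate_internal(
    model: PeakNet,
    records: list[ECGRecord],
    annotations: list[BeatAnnotations],
    features: list[np.ndarray] | None = None,
    exclusions=None,
    fs: float = 360.0,
) -> Metrics:
    """Full-pipeline F1 on un-augmented records; counts pooled across records."""
    cfg = LocalizeConfig(mwa_ms=150.0, fs=fs)
    counts = []
    for i, (rec, ann) in enumerate(zip(records, annotations)):
        feats = features[i] if features is not None else featurize(rec)
        det = localize(model, feats, cfg)
        excl = exclusions[i] if exclusions is not None else None
        counts.append(evaluate_record(ann, det, fs, excl))
    return compute_metrics(pool_counts(counts))


def train(
    records: list[ECGRecord],
    annotations: list[BeatAnnotations],
    templates: NoiseTemplates,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    augment_cfg: AugmentConfig,
    preprocessed: bool = False,
    log=None,
    validate_fn=None,
) -> TrainResult:
    """Fit a peak model on annotated records with per-epoch augmentation.

    `records` are raw unless ``preprocessed=True``; filtering (baseline
    removal + 40 Hz lowpass) is applied once up front.  `log`, if given, is
    called with one dict per epoch (epoch, loss, val_f1, lr).  `validate_fn`
    replaces the internal-validation pass (signature
    ``fn(model, records, annotations, features) -> Metrics``), e.g. to
    monitor a custom hold-out.
    """
    if not records:
        raise ValueError("empty training set")
    if len(records) != len(annotations):
        raise ValueError("records and annotations must align")

    filtered = records if preprocessed else [preprocess_record(r) for r in records]
    val_features = [featurize(r) for r in filtered]
    lengths = np.array([len(r) for r in filtered], dtype=float)
    weights = lengths / lengths.sum()

    n_windows = train_cfg.windows_per_epoch
    if n_windows is None:
        n_windows = max(1, int(lengths.sum()) // augment_cfg.window)

    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)

    history: list[dict] = []
    best_f1, best_epoch = -np.inf, -1
    best_state: dict | None = None
    bad, lr_bad = 0, 0

    for epoch in range(train_cfg.max_epochs):
        model.train()
        losses = []
        drawn = 0
        while drawn < n_windows:
            bsize = min(train_cfg.batch_size, n_windows - drawn)
            xb = np.empty((bsize, 2, augment_cfg.window), dtype=model.cfg.np_dtype)
            yb = np.empty((bsize, augment_cfg.window), dtype=np.float64)
            for b in range(bsize):
                ri = int(rng.choice(len(filtered), p=weights))
                feats, labels = draw_training_window(
                    filtered[ri], annotations[ri], templates, augment_cfg, rng
                )
                xb[b] = feats.T
                yb[b] = labels
            drawn += bsize

            pred = model(xb)
            loss, grad = dice_loss_grad(pred.data, yb, train_cfg.dice_smooth)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite dice loss at epoch {epoch}: {loss}; aborting"
                )
            opt.zero_grad()
            backward(pred, grad.astype(model.cfg.np_dtype))
            opt.step()
            losses.append(loss)

        if validate_fn is None:
            metrics = validate_internal(model, filtered, annotations, val_features)
        else:
            metrics = validate_fn(model, filtered, annotations, val_features)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "val_f1": metrics.f1,
            "lr": opt.lr,
        }
        history.append(entry)
        if log is not None:
            log(entry)

        if metrics.f1 > best_f1 + train_cfg.min_improve:
            best_f1, best_epoch = metrics.f1, epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            bad = lr_bad = 0
        else:
            bad += 1
            lr_bad += 1
            if bad >= train_cfg.patience:
                break
            if lr_bad >= train_cfg.lr_patience:
                opt.lr *= train_cfg.lr_factor
                lr_bad = 0

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainResult(model, history, float(best_f1), best_epoch)
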