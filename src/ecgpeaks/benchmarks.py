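"""Reference experiment: end-to-end recovery on synthetic ECG.

Trains the detection pipeline on synthetic lead-II-like ECG with synthetic
noise templates and scores a held-out record, clean and with
amplitude-matched electrode-motion noise.  Used both by the test suite and
by ``scripts/acceptance.py``; all randomness derives from one seed.

Problem sizes (20 min of training signal, a 5 min held-out record, 2000
augmented windows per epoch, at most 12 epochs with early stopping) keep a
full run on one CPU core in the minutes range while still covering several
thousand beats.
"""

from __future__ import annotations

import numpy as np

from .augment import AugmentConfig, NoiseTemplates, estimate_amplitude
from .evaluation import Metrics, compute_metrics, evaluate_record
from .localization import LocalizeConfig, localize
from .network import ModelConfig
from .preprocess import featurize, preprocess_record
from .records import BeatAnnotations, ECGRecord
from .synth import SynthConfig, gen_ecg, gen_noise_templates
from .training import TrainConfig, TrainResult, train

__all__ = ["make_templates", "add_em_noise", "synthetic_recovery"]

TEMPLATE_LEN_S = 300.0


def make_templates(seed: int, fs: float = 360.0, length_s: float = TEMPLATE_LEN_S) -> NoiseTemplates:
    """The three synthetic noise-stress-test templates from one seed."""
    n = int(length_s * fs)
    return NoiseTemplates(
        baseline_wander=gen_noise_templates("baseline_wander", n, fs, seed),
        muscle=gen_noise_templates("muscle", n, fs, seed + 1),
        electrode_motion=gen_noise_templates("electrode_motion", n, fs, seed + 2),
    )


def add_em_noise(rec: ECGRecord, scale: float, seed: int) -> ECGRecord:
    """Add electrode-motion noise, amplitude-matched like the augmentation.

    The template realization is drawn from its own seed (an "unused area":
    never the one used for training templates) and normalized to unit
    estimated amplitude, then scaled by ``scale`` times the record's
    estimated amplitude.
    """
    em = gen_noise_templates("electrode_motion", len(rec), rec.fs, seed)
    amp = estimate_amplitude(em)
    if amp > 0:
        em = em / amp
    noisy = rec.samples + scale * estimate_amplitude(rec.samples) * em
    return ECGRecord(rec.record_id + "+em", rec.fs, noisy, rec.lead)


def _score(model, rec: ECGRecord, ann: BeatAnnotations) -> Metrics:
    """Test-mode scoring: preprocess, detect with the 75 ms window, match."""
    filtered = preprocess_record(rec)
    det = localize(model, featurize(filtered), LocalizeConfig(mwa_ms=75.0, fs=rec.fs))
    return compute_metrics(evaluate_record(ann, det, rec.fs))


def train_synthetic(
    seed: int,
    noise_sd: float,
    train_minutes: float = 20.0,
    windows_per_epoch: int = 2000,
    max_epochs: int = 12,
    patience: int = 3,
    log=None,
) -> tuple[TrainResult, NoiseTemplates]:
    """Train the default-width model on synthetic ECG with given noise_sd."""
    rec, ann = gen_ecg(SynthConfig(duration_s=train_minutes * 60.0, seed=seed))
    templates = make_templates(seed + 1000)
    result = train(
        [rec],
        [ann],
        templates,
        ModelConfig(),
        TrainConfig(
            max_epochs=max_epochs,
            patience=patience,
            windows_per_epoch=windows_per_epoch,
            seed=seed,
        ),
        AugmentConfig(noise_sd=noise_sd),
        log=log,
    )
    return result, templates


def synthetic_recovery(
    seed: int,
    noise_sds: tuple[float, float] = (0.05, 0.5),
    em_scale: float = 1.0,
    train_minutes: float = 20.0,
    test_minutes: float = 5.0,
    windows_per_epoch: int = 2000,
    max_epochs: int = 12,
    patience: int = 3,
    log=None,
) -> dict:
    """Full recovery experiment; returns clean and noisy metrics per noise_sd.

    One model is trained per entry of `noise_sds`; every model is scored on
    the same held-out record, clean and with electrode-motion noise at
    `em_scale`.  Returns a dict with per-model metrics, the held-out beat
    count, and the training histories.
    """
    seed = int(seed) % (2**31 - 10_000)
    test_rec, test_ann = gen_ecg(
        SynthConfig(duration_s=test_minutes * 60.0, seed=seed + 5000)
    )
    noisy_rec = add_em_noise(test_rec, em_scale, seed + 6000)

    out: dict = {"n_test_beats": len(test_ann), "models": {}}
    for noise_sd in noise_sds:
        result, _ = train_synthetic(
            seed,
            noise_sd,
            train_minutes=train_minutes,
            windows_per_epoch=windows_per_epoch,
            max_epochs=max_epochs,
            patience=patience,
            log=log,
        )
        clean = _score(result.model, test_rec, test_ann)
        noisy = _score(result.model, noisy_rec, test_ann)
        out["models"][noise_sd] = {
            "clean": clean,
            "noisy": noisy,
            "epochs": len(result.history),
            "internal_val_f1": result.best_f1,
        }
    return out
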