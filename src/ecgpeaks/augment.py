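"""Two-step noise augmentation producing fresh 2048-sample training windows.

Step 1 varies peak shape: time-rescaling (heart-rate change), a small
Gaussian perturbation (up to +-10% of the waveform amplitude at 3 sigma),
and multiplication by a slow sinusoid ranging over [0.5, 1.5].  Step 2 adds,
with 50% probability, an amplitude-matched mixture of baseline-wander /
muscle / electrode-motion noise templates scaled by |N(0, noise_sd)|
truncated at 2.  The window is then flipped and/or time-reversed with
independent 50% coins before feature extraction, so each epoch sees
different waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import featurize, make_labels
from .records import BeatAnnotations, ECGRecord

__all__ = [
    "AugmentConfig",
    "NoiseTemplates",
    "estimate_amplitude",
    "shape_transform",
    "sample_noise_scale",
    "mix_templates",
    "add_noise",
    "flip_reverse",
    "draw_training_window",
]


@dataclass
class AugmentConfig:
    noise_sd: float = 0.05           # sigma of the truncated-normal noise scale
    noise_prob: float = 0.5          # probability of adding template noise
    mod_depth_max: float = 0.5       # sinusoid modulation in [1-d, 1+d]
    mod_freq_range: tuple = (0.05, 0.5)  # Hz, drawn log-uniform
    gauss_frac: float = 0.10         # max Gaussian excursion as amplitude fraction
    timescale_range: tuple = (0.8, 1.25)  # drawn log-uniform
    flip_prob: float = 0.5
    reverse_prob: float = 0.5
    window: int = 2048
    fs: float = 360.0

    def __post_init__(self) -> None:
        for p in (self.noise_prob, self.flip_prob, self.reverse_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.mod_depth_max <= 1.0:
            raise ValueError("mod_depth_max must lie in [0, 1]")
        if self.window % 32 != 0:
            raise ValueError("window must be a multiple of 32")


@dataclass
class NoiseTemplates:
    """The three noise-stress-test classes as raw sample sequences at `fs`."""

    baseline_wander: np.ndarray
    muscle: np.ndarray
    electrode_motion: np.ndarray
    fs: float = 360.0

    def as_list(self) -> list[np.ndarray]:
        return [self.baseline_wander, self.muscle, self.electrode_motion]


def estimate_amplitude(x: np.ndarray) -> float:
    """Waveform amplitude: the 99.9th minus the 0.1th percentile."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    p_lo, p_hi = np.percentile(x, [0.1, 99.9])
    return float(p_hi - p_lo)


def sample_noise_scale(noise_sd: float, rng: np.random.Generator) -> float:
    """|z| with z ~ N(0, noise_sd), rejection-sampled until |z| < 2."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    while True:
        z = abs(rng.normal(0.0, noise_sd))
        if z < 2.0:
            return z


def shape_transform(
    x: np.ndarray,
    peaks: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Step-1 shape augmentation; returns the new window and remapped peaks.

    Draw order is fixed (timescale factor, Gaussian sigma, noise vector,
    modulation depth/frequency/phase) so a seeded generator reproduces the
    same window.
    """
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=np.int64)
    w = cfg.window

    lo, hi = cfg.timescale_range
    factor = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if factor != 1.0:
        new_len = max(2, int(round(x.size / factor)))
        grid = np.arange(new_len) * factor
        y = np.interp(grid, np.arange(x.size), x)
        peaks = np.round(peaks / factor).astype(np.int64)
    else:
        y = x.copy()
        new_len = x.size
    if new_len >= w:
        y = y[:w]
    else:
        y = np.pad(y, (0, w - new_len))
    peaks = peaks[(peaks >= 0) & (peaks < w)]

    amp = estimate_amplitude(y)
    sigma = rng.uniform(0.0, cfg.gauss_frac * amp / 3.0)
    y = y + rng.normal(0.0, 1.0, w) * sigma

    depth = rng.uniform(0.0, cfg.mod_depth_max)
    f_lo, f_hi = cfg.mod_freq_range
    f = float(np.exp(rng.uniform(np.log(f_lo), np.log(f_hi))))
    phase = rng.uniform(0.0, 2 * np.pi)
    t = np.arange(w) / cfg.fs
    y = y * (1.0 + depth * np.sin(2 * np.pi * f * t + phase))
    return y, peaks


def mix_templates(
    templates: NoiseTemplates, window: int, rng: np.random.Generator
) -> np.ndarray:
    """Sum random window-length slices of the templates, unit amplitude.

    Each template is included independently with probability 1/2; at least
    one is always forced.  The mixture is rescaled so its estimated
    amplitude (99.9th-0.1th percentile span) is exactly 1.
    """
    parts = templates.as_list()
    include = rng.random(3) < 0.5
    if not include.any():
        include[rng.integers(0, 3)] = True
    mix = np.zeros(window)
    for tpl, inc in zip(parts, include):
        if not inc:
            continue
        if tpl.size < window:
            raise ValueError("noise template shorter than the training window")
        start = int(rng.integers(0, tpl.size - window + 1))
        mix += tpl[start : start + window]
    amp = estimate_amplitude(mix)
    if amp == 0:
        return mix
    return mix / amp


def add_noise(
    x: np.ndarray,
    templates: NoiseTemplates,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Step-2 noise injection, amplitude-matched to the waveform."""
    x = np.asarray(x, dtype=float)
    if rng.random() >= cfg.noise_prob:
        return x
    s = sample_noise_scale(cfg.noise_sd, rng)
    mix = mix_templates(templates, x.size, rng)
    return x + s * estimate_amplitude(x) * mix


def flip_reverse(
    x: np.ndarray,
    peaks: np.ndarray,
    rng: np.random.Generator,
    flip_prob: float = 0.5,
    reverse_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude flip and/or time reversal, two independent 50% coins."""
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=np.int64)
    if rng.random() < flip_prob:
        x = -x
    if rng.random() < reverse_prob:
        x = x[::-1].copy()
        peaks = np.sort(x.size - 1 - peaks)
    return x, peaks


def draw_training_window(
    rec: ECGRecord,
    ann: BeatAnnotations,
    templates: NoiseTemplates,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One augmented (features, labels) pair from a filtered record.

    Pipeline: random window-length crop -> shape_transform -> add_noise ->
    flip_reverse -> window-local feature extraction -> 150 ms labels.
    Features are normalized with the augmented window's own statistics, so
    the amplitude variation introduced by augmentation is what the model
    sees at global scale 1/16.
    """
    x = rec.samples
    w = cfg.window
    if x.size < w:
        raise ValueError(f"record shorter than the training window ({x.size} < {w})")
    start = int(rng.integers(0, x.size - w + 1))
    crop = x[start : start + w]
    peaks = ann.peak_indices
    peaks = peaks[(peaks >= start) & (peaks < start + w)] - start

    y, peaks = shape_transform(crop, peaks, cfg, rng)
    y = add_noise(y, templates, cfg, rng)
    y, peaks = flip_reverse(y, peaks, rng, cfg.flip_prob, cfg.reverse_prob)

    features = featurize(y)
    labels = make_labels(peaks, w, cfg.fs)
    return features, labels
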