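"""Synthetic lead-II-like ECG and noise templates with exact ground truth.

The beat model is a sum of Gaussian bumps (P, Q, R, S, T) placed at
physiologic offsets around each R time, with per-beat amplitude jitter,
occasional inverted or widened (ectopic-like) beats, and RR intervals drawn
from a truncated normal.  It is deliberately transparent rather than
biophysical: every R index used for rendering is returned as ground truth.

Noise templates emulate the three classic noise-stress-test classes:
baseline wander (sub-0.5 Hz sinusoids with slowly drifting phase), muscle
artifact (20-100 Hz bandpassed Gaussian noise), and electrode motion
(piecewise baseline steps plus exponentially decaying spikes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .records import BeatAnnotations, ECGRecord

__all__ = ["SynthConfig", "gen_ecg", "gen_noise_templates"]

# (offset s, amplitude mV, width s) of each wave relative to the R apex;
# textbook lead-II morphology.
_WAVES = {
    "P": (-0.16, 0.15, 0.022),
    "Q": (-0.030, -0.12, 0.008),
    "R": (0.0, 1.0, 0.012),
    "S": (0.030, -0.25, 0.010),
    "T": (0.30, 0.35, 0.060),
}


@dataclass
class SynthConfig:
    """Generator settings; defaults give a clean resting lead-II rhythm."""

    duration_s: float = 300.0
    fs: float = 360.0
    hr_bpm: float = 75.0
    rr_jitter_sd: float = 0.05      # s, normal jitter on each RR interval
    amp_jitter: float = 0.10        # relative per-beat amplitude spread
    qrs_width_scale: float = 1.0    # multiplies Q/R/S widths
    inverted_prob: float = 0.05     # probability of an inverted QRS
    ectopic_prob: float = 0.03      # probability of a wide, P-less beat
    white_noise_mv: float = 0.005   # tiny sensor noise floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.hr_bpm <= 0:
            raise ValueError("duration, fs and heart rate must be positive")


# RR intervals below the cardiac refractory period are rejected so the
# ground truth stays consistent with the 200 ms minimal-interval assumption.
_RR_FLOOR_S = 0.25


def gen_ecg(cfg: SynthConfig) -> tuple[ECGRecord, BeatAnnotations]:
    """Render a synthetic record and the exact R indices used."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    rr_mean = 60.0 / cfg.hr_bpm

    times = []
    t = 0.4 + (rng.normal(0.0, cfg.rr_jitter_sd) if cfg.rr_jitter_sd else 0.0)
    margin = 0.45  # keep the last T wave inside the record
    while t < cfg.duration_s - margin:
        times.append(t)
        rr = rng.normal(rr_mean, cfg.rr_jitter_sd) if cfg.rr_jitter_sd else rr_mean
        while rr <= _RR_FLOOR_S:
            rr = rng.normal(rr_mean, cfg.rr_jitter_sd)
        t += rr
    if not times:
        raise ValueError("configuration yields zero beats")

    r_idx = np.round(np.asarray(times) * cfg.fs).astype(np.int64)
    r_idx = r_idx[r_idx < n]
    x = np.zeros(n)
    grid = np.arange(n)

    for idx in r_idx:
        amp = 1.0 + rng.normal(0.0, cfg.amp_jitter)
        amp = max(amp, 0.3)
        inverted = rng.random() < cfg.inverted_prob
        ectopic = rng.random() < cfg.ectopic_prob
        center = idx / cfg.fs
        for name, (off, a, sig) in _WAVES.items():
            if ectopic and name == "P":
                continue
            a = a * amp
            if name in ("Q", "R", "S"):
                sig = sig * cfg.qrs_width_scale
                if ectopic:
                    sig *= 2.2
                    a *= 1.1
                if inverted:
                    a = -a
            mu = center + off
            lo = max(0, int((mu - 4 * sig) * cfg.fs))
            hi = min(n, int((mu + 4 * sig) * cfg.fs) + 1)
            if hi <= lo:
                continue
            tt = grid[lo:hi] / cfg.fs
            x[lo:hi] += a * np.exp(-0.5 * ((tt - mu) / sig) ** 2)

    if cfg.white_noise_mv:
        x += rng.normal(0.0, cfg.white_noise_mv, n)

    rec = ECGRecord(f"synth-{cfg.seed}", cfg.fs, x, "II")
    ann = BeatAnnotations(rec.record_id, r_idx)
    return rec, ann


def gen_noise_templates(kind: str, length: int, fs: float, seed: int) -> np.ndarray:
    """One synthetic noise template of the requested class.

    ``baseline_wander``: 2-4 sinusoids below 0.5 Hz with slowly drifting
    phase.  ``muscle``: Gaussian noise bandpassed to 20-100 Hz (capped below
    Nyquist).  ``electrode_motion``: piecewise random baseline steps plus
    exponential-decay spikes at Poisson times.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(length) / fs

    if kind == "baseline_wander":
        out = np.zeros(length)
        for _ in range(rng.integers(2, 5)):
            f = rng.uniform(0.05, 0.4)
            a = rng.uniform(0.3, 1.0)
            # phase random walk ~0.001 rad/sample: audible drift, negligible
            # spectral broadening
            drift = np.cumsum(rng.normal(0.0, 1e-3, length))
            out += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi) + drift)
        return out

    if kind == "muscle":
        lo, hi = 20.0, min(100.0, 0.45 * fs)
        b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
        return filtfilt(b, a, rng.normal(0.0, 1.0, length))

    if kind == "electrode_motion":
        out = np.zeros(length)
        # baseline steps: contact-shift events at ~0.5 /s
        n_steps = rng.poisson(0.5 * length / fs)
        for pos in rng.integers(0, length, max(n_steps, 1)):
            out[pos:] += rng.normal(0.0, 1.0)
        # transient spikes with exponential decay at ~0.3 /s
        n_spikes = rng.poisson(0.3 * length / fs)
        for pos in rng.integers(0, length, max(n_spikes, 1)):
            tau = rng.uniform(0.05, 0.2) * fs
            amp = rng.normal(0.0, 2.0)
            k = min(length - pos, int(6 * tau))
            out[pos : pos + k] += amp * np.exp(-np.arange(k) / tau)
        out -= out.mean()
        return out

    raise ValueError(f"unknown noise kind {kind!r}")
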