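"""Noise filtering, SWT peak enhancement, and label construction.

The preprocessing chain for a 360 Hz single-lead ECG is:

1. baseline-wander removal: multilevel DWT to level 9, zero the level-9
   approximation, reconstruct;
2. 40 Hz zero-phase lowpass (4th-order Butterworth, forward-backward) to
   suppress powerline noise;
3. feature channels: the level-4 SWT detail coefficient (Symlet 4) and the
   backward first difference, each divided by 16x its RMS.

Binary targets mark 150 ms windows centered on annotated R-peaks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy.signal import butter, filtfilt

from .records import BeatAnnotations, ECGRecord

__all__ = [
    "remove_baseline_dwt",
    "atrous_filter_bank",
    "lowpass_powerline",
    "swt_detail",
    "first_derivative",
    "normalize_rms16",
    "featurize",
    "preprocess_record",
    "make_labels",
]

TARGET_FS = 360.0
LABEL_MS = 150.0


def remove_baseline_dwt(x: np.ndarray, fs: float, wavelet: str = "sym4") -> np.ndarray:
    """Attenuate baseline wander by zeroing the level-9 DWT approximation.

    At 360 Hz the level-9 approximation band is roughly [0, 0.35] Hz, so
    respiration-rate drift is removed while the QRS band is untouched.
    Signals shorter than 2**9 samples are symmetrically padded and trimmed.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    n = x.size
    pad = max(0, 512 - n)
    if pad:
        x = np.pad(x, (0, pad), mode="symmetric")
    with warnings.catch_warnings():
        # short inputs make every level-9 coefficient boundary-affected;
        # accepted, since only the coarse approximation is altered
        warnings.filterwarnings("ignore", message="Level value of .* is too high")
        coeffs = pywt.wavedec(x, wavelet, level=9, mode="symmetric")
    coeffs[0] = np.zeros_like(coeffs[0])
    y = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return y[:n]


def lowpass_powerline(x: np.ndarray, fs: float, cutoff: float = 40.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth lowpass (applied forward-backward)."""
    if not fs > 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    b, a = butter(4, cutoff / (fs / 2.0), btype="low")
    return filtfilt(b, a, np.asarray(x, dtype=float))


def atrous_filter_bank(wavelet: str, level: int):
    """Per-level (lowpass, highpass) decomposition filter pairs.

    Level-1 filters are the base wavelet's decomposition pair; each
    subsequent level's filters are the previous level's upsampled by two
    (zeros interleaved), as the undecimated transform prescribes.
    """
    w = pywt.Wavelet(wavelet)
    lo, hi = np.asarray(w.dec_lo), np.asarray(w.dec_hi)
    banks = []
    for k in range(1, level + 1):
        dil = 2 ** (k - 1)
        lo_k = np.zeros(dil * (lo.size - 1) + 1)
        hi_k = np.zeros_like(lo_k)
        lo_k[::dil], hi_k[::dil] = lo, hi
        banks.append((lo_k, hi_k))
    return banks


def swt_detail(
    x: np.ndarray, level: int = 4, wavelet: str = "sym4", mode: str = "symmetric"
) -> np.ndarray:
    """Level-`level` SWT detail coefficients, same length as the input.

    `mode="symmetric"` pads the tail to the next multiple of ``2**level`` and
    trims after the transform; `mode="periodic"` requires the length to be an
    exact multiple and is exactly shift-invariant under circular shifts.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    block = 2**level
    pad = (-n) % block
    if mode == "periodic":
        if pad:
            raise ValueError(f"periodic mode needs a length multiple of {block}")
        xp = x
    elif mode == "symmetric":
        xp = np.pad(x, (0, pad), mode="symmetric") if pad else x
    else:
        raise ValueError(f"unknown padding mode {mode!r}")
    coeffs = pywt.swt(xp, wavelet, level=level)
    cd = coeffs[0][1]  # list is ordered deepest level first
    return cd[:n]


def first_derivative(x: np.ndarray) -> np.ndarray:
    """Backward difference ``d[n] = x[n] - x[n-1]`` with ``d[0] = 0``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    d = np.empty_like(x)
    d[0] = 0.0
    np.subtract(x[1:], x[:-1], out=d[1:])
    return d


def normalize_rms16(x: np.ndarray) -> np.ndarray:
    """Divide by 16x the RMS, so the output RMS is exactly 1/16."""
    x = np.asarray(x, dtype=float)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("cannot normalize an all-zero waveform")
    return x / (16.0 * rms)


def featurize(rec: ECGRecord | np.ndarray) -> np.ndarray:
    """Two-channel feature array (length, 2) for a filtered record.

    Channel 0 is the normalized level-4 SWT detail; channel 1 the normalized
    first derivative.  Normalization statistics are taken over the full
    waveform passed in.
    """
    x = rec.samples if isinstance(rec, ECGRecord) else np.asarray(rec, dtype=float)
    cd4 = normalize_rms16(swt_detail(x))
    deriv = normalize_rms16(first_derivative(x))
    return np.stack([cd4, deriv], axis=1)


def preprocess_record(rec: ECGRecord) -> ECGRecord:
    """Baseline removal followed by the 40 Hz lowpass; length preserved."""
    y = lowpass_powerline(remove_baseline_dwt(rec.samples, rec.fs), rec.fs)
    return ECGRecord(rec.record_id, rec.fs, y, rec.lead)


def label_window_samples(fs: float, ms: float = LABEL_MS) -> int:
    return int(round(ms / 1000.0 * fs))


def make_labels(
    peaks: BeatAnnotations | np.ndarray, length: int, fs: float
) -> np.ndarray:
    """Binary per-sample mask: 1 on the 150 ms window centered on each peak.

    With ``w = round(0.150 * fs)`` the window is ``[p - w//2, p - w//2 + w)``,
    clipped to the signal; overlapping windows merge.
    """
    idx = peaks.peak_indices if isinstance(peaks, BeatAnnotations) else np.asarray(peaks, np.int64)
    mask = np.zeros(length, dtype=np.int8)
    w = label_window_samples(fs)
    half = w // 2
    for p in idx:
        lo = max(0, int(p) - half)
        hi = min(length, int(p) - half + w)
        mask[lo:hi] = 1
    return mask
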