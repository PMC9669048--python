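"""ECG record and beat-annotation handling.

Data model, file I/O (WFDB-style records and a plain-text CSV fallback),
Fourier resampling to a common rate, and exclusion regions for scoring.

All indices are 0-based and all index intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample as _fft_resample

__all__ = [
    "ECGRecord",
    "BeatAnnotations",
    "ExclusionRegions",
    "read_record",
    "read_wfdb_annotations",
    "write_detections",
    "resample_to_target",
    "map_annotation_fs",
]

# Lead-name aliases: MIT-BIH labels the modified lead II "MLII".
_LEAD_ALIASES = {"II": ("II", "MLII"), "MLII": ("MLII", "II")}


@dataclass
class ECGRecord:
    """One lead of an ECG: samples in mV at a fixed sampling rate."""

    record_id: str
    fs: float
    samples: np.ndarray
    lead: str = "II"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id}: non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass
class BeatAnnotations:
    """Marked R-peak sample indices on a record's own sampling grid."""

    record_id: str
    peak_indices: np.ndarray
    symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.peak_indices.ndim != 1:
            raise ValueError("peak_indices must be 1-D")
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.peak_indices.size and self.peak_indices[0] < 0:
            raise ValueError("peak indices must be non-negative")
        if self.symbols is not None and len(self.symbols) != self.peak_indices.size:
            raise ValueError("symbols must align with peak_indices")

    def __len__(self) -> int:
        return self.peak_indices.size


@dataclass
class ExclusionRegions:
    """Half-open index intervals ``[start, end)`` omitted from training/scoring."""

    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("intervals must satisfy start < end")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def contains(self, indices: np.ndarray) -> np.ndarray:
        """Boolean mask: which of `indices` fall inside an excluded interval."""
        idx = np.asarray(indices, dtype=np.int64)
        mask = np.zeros(idx.shape, dtype=bool)
        for start, end in self.intervals:
            mask |= (idx >= start) & (idx < end)
        return mask


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def read_record(path: str, channel: str = "II", fs: float | None = None) -> ECGRecord:
    """Read one lead from a WFDB record (.hea/.dat), CSV fallback, or NPY.

    The CSV fallback is plain text: a first line ``fs=<Hz>`` (optionally
    ``fs=<Hz>,lead=<name>``) followed by one sample (mV) per line.  NPY input
    requires an explicit ``fs`` argument.  For WFDB records `channel` selects
    the signal whose description matches the lead name (``II`` also matches
    MIT-BIH's ``MLII``).
    """
    base, ext = os.path.splitext(path)
    ext = ext.lower()
    if ext == ".csv":
        return _read_csv_record(path, channel)
    if ext == ".npy":
        if fs is None:
            raise ValueError("NPY input needs an explicit sampling rate (fs=...)")
        data = np.load(path)
        return ECGRecord(os.path.basename(base), float(fs), np.asarray(data, float).ravel(), channel)
    if ext in (".hea", ".dat", ""):
        return _read_wfdb_record(base if ext else path, channel)
    raise ValueError(f"unrecognized record format: {path}")


def _read_csv_record(path: str, channel: str) -> ECGRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise ValueError(f"{path}: CSV fallback must start with a 'fs=<Hz>' line")
        fs = None
        lead = channel
        for tok in header.split(","):
            key, _, val = tok.partition("=")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "lead":
                lead = val.strip()
        if fs is None:
            raise ValueError(f"{path}: header does not declare fs")
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    if channel not in (lead, *(_LEAD_ALIASES.get(lead, ()))):
        raise KeyError(f"{path}: lead {channel!r} not present (file holds {lead!r})")
    return ECGRecord(os.path.splitext(os.path.basename(path))[0], fs, samples, lead)


def _parse_header(hea_path: str):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    name = first[0].split("/")[0]
    nsig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    signals = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fname = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(parts) > 2:
            g = parts[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) or 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        desc = parts[8] if len(parts) > 8 else f"ch{len(signals)}"
        signals.append(
            dict(file=fname, fmt=int(fmt), gain=gain,
                 baseline=baseline if baseline is not None else adc_zero, desc=desc)
        )
    return name, nsig, fs, signals


def _read_wfdb_record(base: str, channel: str) -> ECGRecord:
    hea_path = base + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(hea_path)
    name, nsig, fs, signals = _parse_header(hea_path)
    wanted = _LEAD_ALIASES.get(channel, (channel,))
    try:
        ch = next(i for i, s in enumerate(signals) if s["desc"] in wanted)
    except StopIteration:
        have = [s["desc"] for s in signals]
        raise KeyError(f"lead {channel!r} not found in {base} (have {have})") from None
    sig = signals[ch]
    dat_path = os.path.join(os.path.dirname(base), sig["file"])
    raw = open(dat_path, "rb").read()
    fmt = sig["fmt"]
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        adc = flat[ch::nsig]
    elif fmt == 212:
        adc = _decode_fmt212(raw)[ch::nsig]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt} in {base}")
    phys = (adc - sig["baseline"]) / sig["gain"]
    return ECGRecord(name, fs, phys, sig["desc"])


def _decode_fmt212(raw: bytes) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw[: len(raw) - len(raw) % 3], dtype=np.uint8).astype(np.int64)
    b0, b1, b2 = b[0::3], b[1::3], b[2::3]
    s0 = ((b1 & 0x0F) << 8) | b0
    s1 = ((b1 & 0xF0) << 4) | b2
    out = np.empty(2 * s0.size, dtype=np.int64)
    out[0::2], out[1::2] = s0, s1
    out[out > 2047] -= 4096
    return out


# WFDB annotation type codes that mark QRS complexes (beats).
_BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 38})
_CODE_SYMBOLS = {1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
                 9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 25: "r", 34: "n", 38: "f"}


def read_wfdb_annotations(path: str, beats_only: bool = True) -> BeatAnnotations:
    """Read a WFDB annotation file (MIT format, e.g. ``.atr``)."""
    raw = open(path, "rb").read()
    times, codes = [], []
    t = 0
    i = 0
    while i + 1 < len(raw):
        b0, b1 = raw[i], raw[i + 1]
        i += 2
        code = b1 >> 2
        delta = ((b1 & 0x03) << 8) | b0
        if code == 0 and delta == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if delta == 0:
                hi, lo = struct.unpack("<HH", raw[i : i + 4])
                i += 4
                t += (hi << 16) | lo
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        if code == 63:  # AUX: delta = byte count, padded to even
            i += delta + (delta & 1)
            continue
        t += delta
        times.append(t)
        codes.append(code)
    times = np.asarray(times, dtype=np.int64)
    codes = np.asarray(codes, dtype=np.int64)
    if beats_only:
        keep = np.isin(codes, list(_BEAT_CODES))
        times, codes = times[keep], codes[keep]
    # collapse duplicates (keep first)
    if times.size:
        keep = np.concatenate(([True], np.diff(times) > 0))
        times, codes = times[keep], codes[keep]
    symbols = [_CODE_SYMBOLS.get(int(c), "?") for c in codes]
    rec_id = os.path.splitext(os.path.basename(path))[0]
    return BeatAnnotations(rec_id, times, symbols)


def write_detections(path: str, indices: np.ndarray, probabilities=None) -> None:
    """Write detected peaks as a two-column CSV ``sample_index,probability``."""
    idx = np.asarray(indices, dtype=np.int64)
    prob = np.ones(idx.size) if probabilities is None else np.asarray(probabilities, float)
    with open(path, "w") as fh:
        fh.write("sample_index,probability\n")
        for i, p in zip(idx, prob):
            fh.write(f"{i},{p:.6f}\n")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_target(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample a record to `target_fs` by the Fourier method.

    The spectrum is zero-padded or truncated so that the output has
    ``round(n * target_fs / fs)`` samples; returns the input unchanged when
    the rates already agree.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    n_out = int(round(len(rec) * target_fs / rec.fs))
    if n_out < 1:
        raise ValueError("resampling would produce an empty record")
    samples = _fft_resample(rec.samples, n_out)
    return ECGRecord(rec.record_id, float(target_fs), samples, rec.lead)


def map_annotation_fs(ann: BeatAnnotations, fs_from: float, fs_to: float) -> BeatAnnotations:
    """Rescale annotation indices after resampling; merges collisions (keep first)."""
    if not (fs_from > 0 and fs_to > 0):
        raise ValueError("sampling rates must be positive")
    if fs_from == fs_to:
        return ann
    idx = np.round(ann.peak_indices * (fs_to / fs_from)).astype(np.int64)
    keep = np.concatenate(([True], np.diff(idx) > 0)) if idx.size else np.ones(0, bool)
    symbols = None
    if ann.symbols is not None:
        symbols = [s for s, k in zip(ann.symbols, keep) if k]
    return BeatAnnotations(ann.record_id, idx[keep], symbols)
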