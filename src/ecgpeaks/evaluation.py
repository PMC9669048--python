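"""Tolerance-matched beat-by-beat scoring.

A detection counts as a true positive when it can be paired one-to-one with
a reference beat at most 150 ms away; the pairing is the maximum-cardinality
matching, computed by dynamic programming over the two sorted index lists
(optimal for this interval structure, and deterministic).  Sensitivity, PPV
and F1 follow from the pooled TP/FP/FN counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import BeatAnnotations, ExclusionRegions

__all__ = [
    "EvalCounts",
    "Metrics",
    "match_detections",
    "compute_metrics",
    "evaluate_record",
    "pool_counts",
    "MATCH_TOL_MS",
]

MATCH_TOL_MS = 150.0


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class Metrics:
    sensitivity: float
    ppv: float
    f1: float

    def rounded(self, ndigits: int = 4) -> "Metrics":
        """Half-even rounding to the precision used in printed reports."""
        return Metrics(*(round(v, ndigits) for v in (self.sensitivity, self.ppv, self.f1)))


def _components(ref: np.ndarray, det: np.ndarray, tol: int):
    """Split the matching problem where no cross pair can lie within `tol`."""
    pts = np.concatenate(
        [np.stack([ref, np.zeros_like(ref)], 1), np.stack([det, np.ones_like(det)], 1)]
    )
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    comps = []
    cur_r, cur_d = [], []
    prev = None
    for pos, kind in pts:
        if prev is not None and pos - prev > tol and (cur_r or cur_d):
            comps.append((cur_r, cur_d))
            cur_r, cur_d = [], []
        (cur_d if kind else cur_r).append(int(pos))
        prev = pos
    if cur_r or cur_d:
        comps.append((cur_r, cur_d))
    return comps


def _dp_match(ref: list[int], det: list[int], tol: int) -> int:
    """Max one-to-one matches with |ref - det| <= tol (LCS-style DP)."""
    n, m = len(ref), len(det)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ri = ref[i - 1]
        for j in range(1, m + 1):
            best = max(prev[j], cur[j - 1])
            if abs(ri - det[j - 1]) <= tol:
                best = max(best, prev[j - 1] + 1)
            cur[j] = best
        prev = cur
    return prev[m]


def match_detections(ref, det, tol_samples: int) -> EvalCounts:
    """TP/FP/FN under optimal one-to-one matching within `tol_samples`."""
    ref = np.asarray(ref, dtype=np.int64)
    det = np.asarray(det, dtype=np.int64)
    for arr, name in ((ref, "ref"), (det, "det")):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} indices must be sorted ascending")
    tp = 0
    for r, d in _components(ref, det, int(tol_samples)):
        tp += _dp_match(r, d, int(tol_samples))
    return EvalCounts(tp=tp, fp=int(det.size) - tp, fn=int(ref.size) - tp)


def compute_metrics(c: EvalCounts) -> Metrics:
    """Sensitivity, PPV and F1 from counts.

    Degenerate conventions: sensitivity = 1 when there are no reference
    beats, PPV = 1 when there are no detections, and F1 = 0 when both
    components vanish while beats exist.
    """
    sens = 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)
    ppv = 1.0 if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp)
    if sens + ppv == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * sens * ppv / (sens + ppv)
    return Metrics(sens, ppv, f1)


def evaluate_record(
    ref: BeatAnnotations | np.ndarray,
    det: np.ndarray,
    fs: float,
    exclusions: ExclusionRegions | None = None,
    tol_ms: float = MATCH_TOL_MS,
) -> EvalCounts:
    """Score one record: drop excluded regions, then tolerance-match."""
    ref_idx = ref.peak_indices if isinstance(ref, BeatAnnotations) else np.asarray(ref, np.int64)
    det_idx = np.asarray(det, dtype=np.int64)
    if exclusions is not None and len(exclusions):
        ref_idx = ref_idx[~exclusions.contains(ref_idx)]
        det_idx = det_idx[~exclusions.contains(det_idx)]
    tol = int(round(tol_ms / 1000.0 * fs))
    return match_detections(ref_idx, det_idx, tol)


def pool_counts(counts: list[EvalCounts]) -> EvalCounts:
    """Componentwise sum across records/databases."""
    total = EvalCounts()
    for c in counts:
        total = total + c
    return total
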