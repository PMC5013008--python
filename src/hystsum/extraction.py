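"""Keyframe selection from an attention curve.

Two selection rules:

* threshold — keyframes are the frames whose attention value is strictly
  greater than the mean of the curve (the mean-attention rule used when
  no summary length is prescribed);
* nkf — the user fixes the number of keyframes NKF; the sequence is cut
  into NKF contiguous near-equal shots and the frame with the highest
  attention value in each shot becomes its keyframe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .fusion import AttentionCurve

__all__ = ["KeyframeSet", "extract_by_threshold", "extract_by_nkf", "shot_bounds"]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class KeyframeSet:
    """Strictly increasing frame indices selected as keyframes."""

    indices: Tuple[int, ...]
    mode: str  # "threshold" or "nkf"
    threshold_used: Optional[float] = None
    nkf_used: Optional[int] = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("keyframe indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


def _curve_values(curve) -> np.ndarray:
    v = np.asarray(getattr(curve, "values", curve), dtype=np.float64)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("attention curve must be non-empty and 1-D")
    return v


def extract_by_threshold(curve: AttentionCurve) -> KeyframeSet:
    """Select frames with attention strictly greater than the curve mean."""
    v = _curve_values(curve)
    thr = float(v.mean())
    idx = tuple(int(i) for i in np.flatnonzero(v > thr))
    return KeyframeSet(idx, mode="threshold", threshold_used=thr)


def shot_bounds(n_frames: int, nkf: int) -> List[Tuple[int, int]]:
    """Half-open [start, stop) bounds of min(nkf, n) contiguous shots.

    Shots are as equal as possible; the first ``n mod nkf`` shots carry
    the extra frame.
    """
    if nkf < 1:
        raise ParameterError(f"nkf must be >= 1, got {nkf}")
    k = min(nkf, n_frames)
    base, rem = divmod(n_frames, k)
    bounds = []
    start = 0
    for s in range(k):
        stop = start + base + (1 if s < rem else 0)
        bounds.append((start, stop))
        start = stop
    return bounds


def extract_by_nkf(curve: AttentionCurve, nkf: int) -> KeyframeSet:
    """Select one keyframe per shot: the shot's attention argmax.

    Returns exactly ``min(nkf, n_frames)`` indices; ties within a shot go
    to the earliest frame.
    """
    v = _curve_values(curve)
    idx = []
    for start, stop in shot_bounds(len(v), nkf):
        idx.append(start + int(np.argmax(v[start:stop])))
    return KeyframeSet(tuple(idx), mode="nkf", nkf_used=int(nkf))
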