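"""Seeded synthetic hysteroscopy-like videos with planted ground truth.

Clinical hysteroscopy recordings alternate fast pans over uninteresting
tissue with slow dwells on diagnostically important regions, and a
substantial fraction of pan frames is spoiled by specular glare and motion
blur.  The generator reproduces exactly those statistics so that every
downstream stage (motion, texture-entropy, contrast, curvature saliency,
fusion, extraction, evaluation) can be tested end-to-end against a known
answer:

* a large pinkish tissue canvas carrying band-limited texture noise is
  viewed through a moving window with a circular endoscope vignette;
* the camera path alternates fast pans with ``n_events`` slow dwells, each
  dwell centred on a high-entropy "lesion" patch (raised local texture
  variance);
* a fraction of the *pan* frames is contaminated with saturated white
  glare blobs plus blur, mimicking discarded non-diagnostic frames;
* ground truth is the middle frame of each dwell, matching the premise
  that keyframes lie where inter-frame motion is low.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SyntheticSpec.seed``, so identical specs produce bit-identical videos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi

from .video_io import FrameSequence, GroundTruth

__all__ = ["SyntheticSpec", "SegmentTable", "generate", "describe"]

#: Base tissue color (R, G, B), a desaturated pink typical of endometrium.
_TISSUE_RGB = np.array([196.0, 138.0, 148.0])

#: Camera heading (degrees from the x axis) — fixed so both motion
#: components are exercised while the path stays mostly horizontal.
_HEADING_DEG = 20.0


class ParameterError(ValueError):
    """A synthetic-video specification violates its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic hysteroscopy sequence.

    Defaults describe the study conditions at reduced scale: 30 fps
    capture, three diagnostically important dwell events, fast pans of
    12 px/frame against slow dwells of 1 px/frame, and glare on 30 % of
    pan frames.
    """

    n_frames: int = 240
    height: int = 128
    width: int = 160
    n_events: int = 3
    dwell_length: int = 20
    pan_speed_fast: float = 12.0
    pan_speed_slow: float = 1.0
    glare_fraction: float = 0.3
    lesion_entropy_boost: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.height < 8 or self.width < 8:
            raise ParameterError("n_frames >= 1 and frame size >= 8 px required")
        if self.n_events < 0 or self.dwell_length < 1:
            raise ParameterError("n_events >= 0 and dwell_length >= 1 required")
        if self.n_events * self.dwell_length > self.n_frames:
            raise ParameterError(
                "n_events * dwell_length exceeds n_frames "
                f"({self.n_events} * {self.dwell_length} > {self.n_frames})"
            )
        if not 0.0 <= self.glare_fraction <= 1.0:
            raise ParameterError("glare_fraction must lie in [0, 1]")
        if self.pan_speed_fast < 0 or self.pan_speed_slow < 0:
            raise ParameterError("pan speeds must be non-negative")
        if self.lesion_entropy_boost < 0:
            raise ParameterError("lesion_entropy_boost must be non-negative")


@dataclass(frozen=True)
class SegmentTable:
    """Per-frame labelling of a synthetic sequence, for test assertions."""

    labels: Tuple[str, ...]  # each one of {"fast_pan", "dwell", "contaminated"}
    dwell_windows: Tuple[Tuple[int, int], ...]  # half-open [start, stop)
    contaminated: Tuple[int, ...]
    positions: Tuple[Tuple[float, float], ...]  # camera (x, y) per frame


def _segment_layout(spec: SyntheticSpec) -> Tuple[List[Tuple[int, int]], np.ndarray]:
    """Dwell windows and per-frame dwell mask.

    Pan time is split as evenly as possible into ``n_events + 1`` gaps
    (earlier gaps take the remainder), with one dwell after each of the
    first ``n_events`` gaps.
    """
    n_pan = spec.n_frames - spec.n_events * spec.dwell_length
    n_gaps = spec.n_events + 1
    base, rem = divmod(n_pan, n_gaps)
    pan_lengths = [base + 1] * rem + [base] * (n_gaps - rem)
    dwells = []
    pos = 0
    for e in range(spec.n_events):
        pos += pan_lengths[e]
        dwells.append((pos, pos + spec.dwell_length))
        pos += spec.dwell_length
    is_dwell = np.zeros(spec.n_frames, dtype=bool)
    for a, b in dwells:
        is_dwell[a:b] = True
    return dwells, is_dwell


def _plan(spec: SyntheticSpec, rng: np.random.Generator):
    """Segment layout, camera path and glare-frame selection.

    Draws the glare selection from ``rng`` first so that :func:`describe`
    can reproduce it without rendering any pixels.
    """
    dwells, is_dwell = _segment_layout(spec)
    speeds = np.where(is_dwell, spec.pan_speed_slow, spec.pan_speed_fast)
    theta = math.radians(_HEADING_DEG)
    dx, dy = math.cos(theta), math.sin(theta)
    # position of frame i = sum of speeds of frames 1..i along the heading
    steps = np.concatenate([[0.0], speeds[1:]])
    dist = np.cumsum(steps)
    xs, ys = dist * dx, dist * dy
    pan_idx = np.flatnonzero(~is_dwell)
    n_glare = int(round(spec.glare_fraction * len(pan_idx)))
    glare = (
        np.sort(rng.choice(pan_idx, size=n_glare, replace=False))
        if n_glare
        else np.empty(0, dtype=int)
    )
    return dwells, is_dwell, xs, ys, set(int(g) for g in glare)


def _vignette(height: int, width: int) -> np.ndarray:
    """Soft circular endoscopic field-of-view mask in [0.05, 1]."""
    yy, xx = np.mgrid[0:height, 0:width]
    r = np.hypot(yy - (height - 1) / 2.0, xx - (width - 1) / 2.0)
    r0 = 0.48 * min(height, width)
    m = np.clip((r0 - r) / 4.0, 0.0, 1.0)
    return 0.05 + 0.95 * m


def generate(spec: SyntheticSpec) -> Tuple[FrameSequence, GroundTruth]:
    """Render a synthetic sequence and its planted ground truth.

    Deterministic for a fixed spec (including seed).  Ground truth is the
    middle frame of each dwell segment.
    """
    rng = np.random.default_rng(spec.seed)
    dwells, is_dwell, xs, ys, glare = _plan(spec, rng)
    h, w = spec.height, spec.width

    canvas_h = h + int(math.ceil(ys.max() if len(ys) else 0)) + 2
    canvas_w = w + int(math.ceil(xs.max() if len(xs) else 0)) + 2

    # Band-limited tissue texture: smoothed white noise.  Raw white noise
    # would maximize local entropy everywhere and erase the lesion /
    # background contrast the texture stage must detect.
    noise = rng.standard_normal((canvas_h, canvas_w))
    noise = ndi.gaussian_filter(noise, sigma=3.0, mode="mirror")
    noise *= 20.0 / max(noise.std(), 1e-12)
    canvas = _TISSUE_RGB[None, None, :] + noise[:, :, None] * np.array([0.9, 1.0, 1.1])

    # Lesions: high-frequency luminance noise inside a soft disk centred
    # where the camera window sits at each dwell's middle frame.
    lesion_r = 0.22 * min(h, w)
    for a, b in dwells:
        mid = a + (spec.dwell_length - 1) // 2
        cy = ys[mid] + (h - 1) / 2.0
        cx = xs[mid] + (w - 1) / 2.0
        yy, xx = np.mgrid[0:canvas_h, 0:canvas_w]
        mask = np.clip((lesion_r - np.hypot(yy - cy, xx - cx)) / 3.0, 0.0, 1.0)
        boost = rng.uniform(-1.0, 1.0, (canvas_h, canvas_w)) * spec.lesion_entropy_boost
        canvas += (mask * boost)[:, :, None]

    canvas = np.clip(canvas, 0.0, 255.0)
    vig = _vignette(h, w)[:, :, None]

    frames = np.empty((spec.n_frames, h, w, 3), dtype=np.uint8)
    for i in range(spec.n_frames):
        y0, x0 = int(round(ys[i])), int(round(xs[i]))
        frame = canvas[y0 : y0 + h, x0 : x0 + w, :] * vig
        if i in glare:
            n_blobs = int(rng.integers(1, 4))
            gm = np.zeros((h, w))
            for _ in range(n_blobs):
                by = rng.uniform(0.2 * h, 0.8 * h)
                bx = rng.uniform(0.2 * w, 0.8 * w)
                br = rng.uniform(6.0, 14.0)
                yy, xx = np.mgrid[0:h, 0:w]
                gm = np.maximum(
                    gm, np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * (br / 2) ** 2))
                )
            frame = frame * (1.0 - gm[:, :, None]) + 255.0 * gm[:, :, None]
            frame = ndi.gaussian_filter(frame, sigma=(2.0, 2.0, 0.0), mode="mirror")
        frames[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        tuple(a + (spec.dwell_length - 1) // 2 for a, b in dwells)
    )
    seq = FrameSequence(frames, frame_rate=30.0, source_id=f"synthetic(seed={spec.seed})")
    return seq, truth


def describe(spec: SyntheticSpec) -> SegmentTable:
    """Per-frame labels and dwell boundaries without rendering pixels.

    Labels: ``dwell`` inside a dwell window, ``contaminated`` for a
    glare-affected pan frame, ``fast_pan`` otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    dwells, is_dwell, xs, ys, glare = _plan(spec, rng)
    labels = []
    for i in range(spec.n_frames):
        if is_dwell[i]:
            labels.append("dwell")
        elif i in glare:
            labels.append("contaminated")
        else:
            labels.append("fast_pan")
    return SegmentTable(
        labels=tuple(labels),
        dwell_windows=tuple((int(a), int(b)) for a, b in dwells),
        contaminated=tuple(sorted(glare)),
        positions=tuple((float(x), float(y)) for x, y in zip(xs, ys)),
    )
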