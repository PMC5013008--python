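"""Frame-sequence I/O, color conversion, and annotation parsing.

A hysteroscopy recording is handled as a :class:`FrameSequence`: an ordered
stack of 8-bit RGB frames of uniform size.  Input is either a directory of
raster images (read in lexicographic filename order) or a video container
readable by imageio.  Ground-truth annotations are the gynecologist-style
keyframe index lists used by :mod:`hystsum.evaluation`.

All frame indexing is 0-based, including annotation files and output
filenames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameSequence",
    "GroundTruth",
    "InputError",
    "FormatError",
    "read_frames",
    "to_grayscale",
    "read_ground_truth",
    "write_keyframes",
]

#: File extensions accepted when reading a directory of frames.
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

#: ITU-R BT.601 luma weights for 8-bit video-derived stills.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class InputError(ValueError):
    """Unreadable, empty, or otherwise unusable input."""


class FormatError(ValueError):
    """Input violates a structural invariant (e.g. mixed frame sizes)."""


@dataclass
class FrameSequence:
    """Ordered 8-bit RGB frames of uniform height x width.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width, 3)``, dtype uint8.
    frame_rate
        Frames per second; informational only (default 30, the typical
        hysteroscope capture rate).
    source_id
        Free-text provenance tag.
    """

    frames: np.ndarray
    frame_rate: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise FormatError(
                f"expected (n, h, w, 3) frame stack, got shape {self.frames.shape}"
            )
        if len(self.frames) < 1:
            raise FormatError("a frame sequence must contain at least one frame")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise FormatError("pixel values must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass(frozen=True)
class GroundTruth:
    """Reference keyframe indices selected by a domain expert."""

    keyframe_indices: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.keyframe_indices)
        if any(i < 0 for i in idx):
            raise FormatError("ground-truth indices must be non-negative")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise FormatError("ground-truth indices must be strictly increasing")
        object.__setattr__(self, "keyframe_indices", idx)

    @property
    def total_keyframes(self) -> int:
        return len(self.keyframe_indices)


def read_frames(path, frame_rate: float | None = None) -> FrameSequence:
    """Read a frame sequence from an image directory or video file.

    Directory input is read in lexicographic filename order, which keeps
    ordering deterministic without container metadata.  ``frame_rate``
    overrides container metadata (directories default to 30 fps).
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise InputError(f"no raster images found in directory: {p}")
        frames = []
        shape = None
        for f in files:
            img = np.asarray(iio.imread(f))
            if img.ndim == 2:  # promote grayscale to RGB
                img = np.stack([img] * 3, axis=-1)
            if img.shape[2] == 4:  # drop alpha
                img = img[:, :, :3]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"mixed frame dimensions: {f.name} is {img.shape[:2]}, "
                    f"expected {shape[:2]}"
                )
            frames.append(img)
        return FrameSequence(
            np.stack(frames),
            frame_rate=30.0 if frame_rate is None else frame_rate,
            source_id=str(p),
        )
    # video container
    try:
        stack = np.asarray(iio.imread(p, index=None))
    except Exception as exc:  # codec/plugin failures become input errors
        raise InputError(f"could not read video file {p}: {exc}") from exc
    if stack.ndim == 3:
        stack = stack[None]
    if frame_rate is None:
        try:
            meta = iio.immeta(p)
            frame_rate = float(meta.get("fps", 30.0))
        except Exception:
            frame_rate = 30.0
    return FrameSequence(stack[..., :3], frame_rate=frame_rate, source_id=str(p))


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to a luminance grid in [0, 1].

    Uses BT.601 weights: ``(0.299 R + 0.587 G + 0.114 B) / 255``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise FormatError(f"expected (h, w, 3) RGB frame, got {frame.shape}")
    return frame.astype(np.float64) @ _LUMA_WEIGHTS / 255.0


def read_ground_truth(path, n_frames: int) -> GroundTruth:
    """Parse a keyframe annotation file.

    Accepts one 0-based integer index per line, or a single JSON array.
    Indices are deduplicated and sorted; any index ``>= n_frames`` is a
    validation error.  An empty file yields an empty annotation.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"annotation file does not exist: {p}")
    text = p.read_text().strip()
    if not text:
        indices: list[int] = []
    elif text.startswith("["):
        indices = [int(i) for i in json.loads(text)]
    else:
        indices = [int(line) for line in text.splitlines() if line.strip()]
    bad = sorted({i for i in indices if i >= n_frames})
    if bad:
        raise FormatError(
            f"ground-truth indices out of range for {n_frames} frames: {bad}"
        )
    return GroundTruth(tuple(sorted(set(indices))))


def write_keyframes(seq: FrameSequence, keys, outdir) -> Mapping[int, str]:
    """Write selected keyframes as PNGs named by zero-padded frame index.

    ``keys`` may be a KeyframeSet or any iterable of indices.  Returns and
    writes (``manifest.json``) a mapping of frame index to filename.
    """
    indices = _as_indices(keys)
    bad = [i for i in indices if i < 0 or i >= len(seq)]
    if bad:
        raise InputError(
            f"keyframe indices out of range for {len(seq)}-frame sequence: {bad}"
        )
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for i in indices:
            name = f"frame_{i:06d}.png"
            iio.imwrite(out / name, seq[i])
            manifest[int(i)] = name
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise InputError(f"cannot write keyframes under {out}: {exc}") from exc
    return manifest


def _as_indices(keys) -> Sequence[int]:
    raw: Iterable = getattr(keys, "indices", keys)
    return [int(i) for i in raw]
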