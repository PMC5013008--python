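"""Per-pixel saliency operators for hysteroscopy frames.

Four complementary measures of visual importance, each producing a
non-negative per-pixel map the same size as the input frame:

``MS``   motion saliency — magnitude of the block-matching motion field
         between consecutive frames, sqrt(Mx^2 + My^2);
``TS``   texture saliency — luminance restricted to "injurious" regions
         segmented by thresholding normalized local histogram entropy at
         tau, then morphological closing and hole filling;
``MSCM`` multi-scale color contrast — per-pixel sum of squared
         differences to a 5x5 neighborhood, accumulated over the levels
         of a Gaussian pyramid;
``CM``   curvature saliency — root-sum-square of the second partial
         derivatives of the Gaussian-smoothed luminance, a rotation
         invariant interest measure.

Border handling is mirror reflection (edge pixel not duplicated)
throughout, which avoids spurious saliency at frame borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing as _closing, disk
from skimage.transform import resize

from .video_io import to_grayscale

__all__ = [
    "OperatorParams",
    "SaliencyMap",
    "MotionField",
    "EntropyMap",
    "TextureMask",
    "estimate_motion_field",
    "motion_saliency",
    "local_entropy",
    "texture_saliency",
    "contrast_map_at_scale",
    "multiscale_contrast",
    "gaussian_pyramid",
    "curvature_map",
]

MODEL_TAGS = ("MS", "TS", "MSCM", "CM")


class ParameterError(ValueError):
    """Operator parameters violate their invariants."""


@dataclass(frozen=True)
class OperatorParams:
    """Tunable parameters of the four saliency operators.

    block_size, search_radius
        Block-matching motion estimation: block edge in pixels and the
        maximum displacement searched per axis.
    entropy_window
        Odd edge of the local histogram window.  With a w x w window the
        maximum normalized entropy is log2(w^2)/log2(gray_levels); the
        default 15 keeps the tau = 0.8 segmentation threshold reachable
        for 256 gray levels.
    tau
        Entropy segmentation threshold on the normalized [0, 1] scale.
    closing_radius
        Disk radius of the structuring element smoothing the texture mask.
    gray_levels
        Histogram bin count; 256 for 8-bit-derived luminance.
    contrast_neighborhood
        Odd edge of the contrast window (5 in the reference protocol).
    pyramid_levels
        Gaussian-pyramid depth for multi-scale contrast (level 1 is the
        original resolution).
    sigma
        Scale (pixels) of the Gaussian smoothing the curvature operator.
    """

    block_size: int = 16
    search_radius: int = 8
    entropy_window: int = 15
    tau: float = 0.8
    closing_radius: int = 5
    gray_levels: int = 256
    contrast_neighborhood: int = 5
    pyramid_levels: int = 3
    sigma: float = 1.5

    def __post_init__(self) -> None:
        for name in ("entropy_window", "contrast_neighborhood"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ParameterError(f"{name} must be odd and >= 3, got {v}")
        if not 0.0 < self.tau < 1.0:
            raise ParameterError(f"tau must lie in (0, 1), got {self.tau}")
        if self.pyramid_levels < 1:
            raise ParameterError("pyramid_levels must be >= 1")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.block_size < 1 or self.search_radius < 1:
            raise ParameterError("block_size and search_radius must be >= 1")
        if self.gray_levels < 2:
            raise ParameterError("gray_levels must be >= 2")
        if self.closing_radius < 0:
            raise ParameterError("closing_radius must be >= 0")


@dataclass(frozen=True)
class SaliencyMap:
    """Non-negative per-pixel saliency, same spatial dims as the frame."""

    values: np.ndarray
    model_tag: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("saliency values must be finite and non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MotionField:
    """Per-pixel displacement (pixels) of frame i relative to frame i-1."""

    dx: np.ndarray
    dy: np.ndarray


@dataclass(frozen=True)
class EntropyMap:
    """Local-histogram entropy normalized to [0, 1]."""

    values: np.ndarray


@dataclass(frozen=True)
class TextureMask:
    """Binary injurious-region mask after closing and hole filling."""

    values: np.ndarray


# ---------------------------------------------------------------------------
# motion

def _displacement_order(radius: int):
    """Candidate displacements sorted by (magnitude^2, dy, dx).

    Scanning in this order and keeping the first strict SAD improvement
    implements the tie-break: smallest magnitude, then smallest dy, then
    smallest dx.
    """
    cands = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
    ]
    cands.sort(key=lambda d: (d[0] * d[0] + d[1] * d[1], d[0], d[1]))
    return cands


def estimate_motion_field(
    prev: np.ndarray, cur: np.ndarray, params: OperatorParams = OperatorParams()
) -> MotionField:
    """Exhaustive block-matching motion estimation.

    The current frame is partitioned into ``block_size`` blocks (edge
    blocks may be smaller); for each block the integer displacement
    ``(dy, dx)`` within +/- ``search_radius`` minimizing the sum of
    absolute differences against the (mirror-padded) previous frame is
    found, under the convention ``cur[y, x] ~= prev[y - dy, x - dx]``.
    All pixels of a block share the block's displacement.
    """
    prev = np.asarray(prev, dtype=np.float64)
    cur = np.asarray(cur, dtype=np.float64)
    if prev.shape != cur.shape or prev.ndim != 2:
        raise ValueError(f"frame shape mismatch: {prev.shape} vs {cur.shape}")
    r, b = params.search_radius, params.block_size
    padded = np.pad(prev, r, mode="reflect")
    cands = _displacement_order(r)
    h, w = cur.shape
    fdx = np.zeros((h, w))
    fdy = np.zeros((h, w))
    for by in range(0, h, b):
        for bx in range(0, w, b):
            block = cur[by : by + b, bx : bx + b]
            bh, bw = block.shape
            best = None
            best_d = (0, 0)
            for dy, dx in cands:
                win = padded[
                    by - dy + r : by - dy + r + bh, bx - dx + r : bx - dx + r + bw
                ]
                sad = np.abs(block - win).sum()
                if best is None or sad < best:
                    best, best_d = sad, (dy, dx)
            fdy[by : by + bh, bx : bx + bw] = best_d[0]
            fdx[by : by + bh, bx : bx + bw] = best_d[1]
    return MotionField(dx=fdx, dy=fdy)


def motion_saliency(field: MotionField) -> SaliencyMap:
    """Per-pixel motion magnitude sqrt(dx^2 + dy^2)."""
    return SaliencyMap(np.hypot(field.dx, field.dy), "MS")


# ---------------------------------------------------------------------------
# texture

def _box_counts(indicator: np.ndarray, window: int) -> np.ndarray:
    """Exact integer window sums of a binary grid via an integral image."""
    s = np.zeros((indicator.shape[0] + 1, indicator.shape[1] + 1), dtype=np.int64)
    s[1:, 1:] = indicator.cumsum(0).cumsum(1)
    return (
        s[window:, window:]
        - s[:-window, window:]
        - s[window:, :-window]
        + s[:-window, :-window]
    )


def quantize(gray: np.ndarray, gray_levels: int) -> np.ndarray:
    """Map luminance in [0, 1] to integer bins 0 .. gray_levels - 1."""
    g = np.asarray(gray, dtype=np.float64)
    return np.clip((g * gray_levels).astype(np.int64), 0, gray_levels - 1)


def local_entropy(
    gray: np.ndarray, params: OperatorParams = OperatorParams()
) -> EntropyMap:
    """Normalized local histogram entropy.

    For every pixel, the luminance values in the surrounding
    ``entropy_window`` square (mirror padding at borders) are binned into
    ``gray_levels`` levels; the Shannon entropy of the bin probabilities,
    with 0 log 0 := 0, is divided by log2(gray_levels) so a uniform
    histogram over all levels would score 1.

    Accumulates one term per occupied gray level in ascending level
    order, reproducing a per-pixel histogram loop bit-for-bit.
    """
    w = params.entropy_window
    pad = w // 2
    q = quantize(gray, params.gray_levels)
    qp = np.pad(q, pad, mode="reflect")
    n = float(w * w)
    ent = np.zeros(q.shape, dtype=np.float64)
    for k in np.unique(qp):
        counts = _box_counts(qp == k, w)
        nz = counts > 0
        if not nz.any():
            continue
        p = counts[nz] / n
        term = np.zeros_like(ent)
        term[nz] = p * np.log2(p)
        ent -= term
    ent /= np.log2(params.gray_levels)
    return EntropyMap(ent)


def texture_saliency(
    frame: np.ndarray, params: OperatorParams = OperatorParams()
) -> Tuple[SaliencyMap, TextureMask, float]:
    """Entropy-directed segmentation of injurious (high-texture) regions.

    Pixels whose normalized entropy reaches ``tau`` are marked, the mask
    is smoothed by closing with a disk and its holes are filled; the
    saliency map is the frame luminance inside the mask and zero outside.
    Also returns the injurious area fraction, the frame-level score used
    by the fusion stage.
    """
    gray = to_grayscale(frame)
    ent = local_entropy(gray, params).values
    mask = ent >= params.tau
    if params.closing_radius > 0:
        mask = _closing(mask, footprint=disk(params.closing_radius))
    mask = ndi.binary_fill_holes(mask)
    ts = np.where(mask, gray, 0.0)
    return (
        SaliencyMap(ts, "TS"),
        TextureMask(mask.astype(np.uint8)),
        float(mask.mean()),
    )


# ---------------------------------------------------------------------------
# contrast

def contrast_map_at_scale(
    frame_level: np.ndarray, params: OperatorParams = OperatorParams()
) -> SaliencyMap:
    """Color contrast at a single scale.

    Per pixel P and per color channel, the sum over the
    ``contrast_neighborhood`` window of squared differences between P and
    each neighbor (the P term contributes zero), summed over the three
    channels.  Channel values are on the [0, 1] scale; mirror padding at
    borders.
    """
    img = np.asarray(frame_level, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) image, got {img.shape}")
    if np.issubdtype(np.asarray(frame_level).dtype, np.integer):
        img = img / 255.0
    k = params.contrast_neighborhood
    if min(img.shape[:2]) < k:
        raise ParameterError(
            f"image {img.shape[:2]} smaller than contrast window {k}"
        )
    pad = k // 2
    h, w = img.shape[:2]
    padded = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    out = np.zeros((h, w))
    # explicit neighbor differences: exact zeros on constant input
    for dy in range(k):
        for dx in range(k):
            if dy == pad and dx == pad:
                continue
            diff = img - padded[dy : dy + h, dx : dx + w, :]
            out += (diff * diff).sum(axis=2)
    return SaliencyMap(out, "MSCM")


def gaussian_pyramid(frame: np.ndarray, levels: int) -> list:
    """Gaussian pyramid, level 1 the original image on the [0, 1] scale.

    Each subsequent level is the previous one smoothed with a sigma = 1
    Gaussian (mirror borders) and decimated by 2 along both spatial axes.
    """
    img = np.asarray(frame, dtype=np.float64)
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        img = img / 255.0
    pyr = [img]
    for _ in range(levels - 1):
        smoothed = ndi.gaussian_filter(pyr[-1], sigma=(1.0, 1.0, 0.0), mode="mirror")
        pyr.append(smoothed[::2, ::2, :])
    return pyr


def multiscale_contrast(
    frame: np.ndarray, params: OperatorParams = OperatorParams()
) -> SaliencyMap:
    """Contrast accumulated over the levels of a Gaussian pyramid.

    Each level's contrast map is upsampled back to base resolution by
    bilinear interpolation and the maps are summed, so both fine and
    coarse salient structures contribute.
    """
    img = np.asarray(frame)
    k = params.contrast_neighborhood
    top = min(img.shape[:2])
    for _ in range(params.pyramid_levels - 1):
        top = (top + 1) // 2
    if top < k:
        raise ParameterError(
            f"frame {img.shape[:2]} too small for {params.pyramid_levels} "
            f"pyramid levels with a {k}x{k} contrast window"
        )
    base_shape = img.shape[:2]
    acc = np.zeros(base_shape)
    for lvl, level_img in enumerate(gaussian_pyramid(img, params.pyramid_levels)):
        cm = contrast_map_at_scale(level_img, params).values
        if lvl > 0:
            cm = resize(
                cm, base_shape, order=1, mode="reflect",
                anti_aliasing=False, preserve_range=True,
            )
        acc += cm
    return SaliencyMap(np.maximum(acc, 0.0), "MSCM")


# ---------------------------------------------------------------------------
# curvature

def curvature_map(
    gray: np.ndarray, params: OperatorParams = OperatorParams()
) -> SaliencyMap:
    """Rotation-invariant curvature saliency.

    The luminance is smoothed with a Gaussian of scale ``sigma``
    (truncated at 3 sigma, mirror borders); the four second partial
    derivatives g_xx, g_xy, g_yx, g_yy are taken by central finite
    differences and combined as sqrt(g_xy^2 + g_xx^2 + g_yx^2 + g_yy^2).
    g_xy and g_yx coincide analytically but are computed independently.
    """
    g = ndi.gaussian_filter(
        np.asarray(gray, dtype=np.float64), params.sigma, mode="mirror", truncate=3.0
    )
    gy = np.gradient(g, axis=0)
    gx = np.gradient(g, axis=1)
    gxx = np.gradient(gx, axis=1)
    gxy = np.gradient(gx, axis=0)
    gyx = np.gradient(gy, axis=1)
    gyy = np.gradient(gy, axis=0)
    return SaliencyMap(np.sqrt(gxy**2 + gxx**2 + gyx**2 + gyy**2), "CM")
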