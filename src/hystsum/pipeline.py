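"""End-to-end summarization pipeline.

read frames -> per-frame saliency (MS, TS, MSCM, CM) -> frame scores ->
normalize -> weighted fusion -> keyframe extraction -> outputs (curve
CSV, keyframe PNGs, JSON manifest with full effective parameters).

The motion model scores a frame by its mean motion magnitude; because
diagnostically important segments are the ones examined slowly, the
pipeline by default converts the normalized motion score into a
stillness score (1 - score) before fusion (``motion_as_stillness``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fusion as fu
from . import saliency as sal
from .extraction import KeyframeSet, extract_by_nkf, extract_by_threshold
from .synthetic import SyntheticSpec, generate
from .video_io import FrameSequence, read_frames, to_grayscale, write_keyframes

__all__ = [
    "PipelineConfig",
    "compute_frame_scores",
    "build_attention_curve",
    "summarize_sequence",
    "run_summarize",
]

log = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {tag: 0.25 for tag in sal.MODEL_TAGS}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) a summarization."""

    input: Optional[str] = None  # frame directory or video file
    synthetic: Optional[SyntheticSpec] = None  # used when input is None
    params: sal.OperatorParams = field(default_factory=sal.OperatorParams)
    weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    motion_as_stillness: bool = True
    mode: str = "nkf"
    nkf: int = 3
    tolerance: int = 0
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "nkf"):
            raise ConfigError(f"mode must be 'threshold' or 'nkf', got {self.mode!r}")
        if self.mode == "nkf" and self.nkf < 1:
            raise ConfigError("nkf must be >= 1 in nkf mode")
        if self.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")
        unknown = set(self.weights) - set(sal.MODEL_TAGS)
        if unknown:
            raise ConfigError(f"unknown model tags in weights: {sorted(unknown)}")
        if any(v < 0 for v in self.weights.values()):
            raise ConfigError("fusion weights must be non-negative")
        if not any(v > 0 for v in self.weights.values()):
            raise ConfigError("at least one fusion weight must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("params") is not None and not isinstance(d["params"], sal.OperatorParams):
            d["params"] = sal.OperatorParams(**d["params"])
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], SyntheticSpec):
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def compute_frame_scores(
    seq: FrameSequence,
    params: sal.OperatorParams = sal.OperatorParams(),
    models: Sequence[str] = sal.MODEL_TAGS,
) -> Dict[str, np.ndarray]:
    """Raw (pre-normalization) per-frame scores for each saliency model.

    Motion, contrast and curvature use the mean of the strictly positive
    map values; texture uses the injurious area fraction.  The first
    frame has no predecessor, so its motion field is all zero.
    """
    models = list(models)
    unknown = set(models) - set(sal.MODEL_TAGS)
    if unknown:
        raise ConfigError(f"unknown model tags: {sorted(unknown)}")
    n = len(seq)
    raw = {m: np.zeros(n) for m in models}
    prev_gray = None
    for i in range(n):
        frame = seq[i]
        gray = to_grayscale(frame)
        if "MS" in raw:
            if prev_gray is None:
                raw["MS"][i] = 0.0
            else:
                field_ = sal.estimate_motion_field(prev_gray, gray, params)
                raw["MS"][i] = fu.frame_score(sal.motion_saliency(field_))
        if "TS" in raw:
            _, _, frac = sal.texture_saliency(frame, params)
            raw["TS"][i] = frac
        if "MSCM" in raw:
            raw["MSCM"][i] = fu.frame_score(sal.multiscale_contrast(frame, params))
        if "CM" in raw:
            raw["CM"][i] = fu.frame_score(sal.curvature_map(gray, params))
        prev_gray = gray
        log.debug("frame %d/%d scored", i + 1, n)
    return raw


def build_attention_curve(
    raw_scores: Dict[str, np.ndarray],
    weights: Dict[str, float],
    motion_as_stillness: bool = True,
) -> Tuple[fu.AttentionCurve, Dict[str, np.ndarray]]:
    """Normalize per-model scores and fuse them into the attention curve.

    Returns the curve and the normalized (post-transform) per-model
    score vectors that entered the fusion.
    """
    vectors = []
    normalized = {}
    for tag, scores in raw_scores.items():
        v = fu.normalize_scores(scores, tag)
        if tag == "MS" and motion_as_stillness:
            v = fu.invert_scores(v)
        vectors.append(v)
        normalized[tag] = v.scores
    curve = fu.fuse(vectors, fu.FusionWeights(weights))
    return curve, normalized


def summarize_sequence(
    seq: FrameSequence, config: PipelineConfig
) -> Tuple[KeyframeSet, fu.AttentionCurve, Dict[str, np.ndarray]]:
    """Run scoring, fusion and extraction in memory."""
    raw = compute_frame_scores(seq, config.params)
    curve, normalized = build_attention_curve(
        raw, config.weights, config.motion_as_stillness
    )
    if config.mode == "threshold":
        keys = extract_by_threshold(curve)
    else:
        keys = extract_by_nkf(curve, config.nkf)
    return keys, curve, normalized


def _curve_frame(curve, normalized) -> pd.DataFrame:
    df = pd.DataFrame({"frame_index": np.arange(len(curve))})
    for tag in sal.MODEL_TAGS:
        if tag in normalized:
            df[tag.lower()] = normalized[tag]
    df["fused"] = curve.values
    return df


def run_summarize(config: PipelineConfig):
    """Execute the full pipeline and write its artifacts.

    Writes under ``config.outdir``: ``curve.csv`` (per-frame normalized
    model scores and the fused attention value), ``keyframes/`` with one
    PNG per selected frame, and ``manifest.json`` recording the complete
    effective configuration and the selection — enough to re-run the
    identical summarization from the manifest alone.

    Returns ``(KeyframeSet, AttentionCurve, manifest_dict)``.
    """
    if config.input is not None:
        seq = read_frames(config.input)
    else:
        spec = config.synthetic or SyntheticSpec(seed=config.seed)
        seq, _ = generate(spec)
    keys, curve, normalized = summarize_sequence(seq, config)

    manifest = {
        "config": config.to_dict(),
        "n_frames": len(seq),
        "frame_shape": [seq.height, seq.width],
        "keyframes": {
            "indices": list(keys.indices),
            "mode": keys.mode,
            "threshold_used": keys.threshold_used,
            "nkf_used": keys.nkf_used,
        },
    }
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        _curve_frame(curve, normalized).to_csv(out / "curve.csv", index=False)
        files = write_keyframes(seq, keys, out / "keyframes")
        manifest["keyframes"]["files"] = {str(k): v for k, v in files.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("wrote %d keyframes to %s", len(keys), out)
    return keys, curve, manifest
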