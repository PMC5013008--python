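"""Frame-level scoring and weighted linear fusion into an attention curve.

Each saliency map is collapsed to one scalar per frame (the mean of its
strictly positive values; the texture model uses the injurious area
fraction instead, handled by the pipeline).  Per-model score vectors are
normalized across the sequence by dividing by their maximum — zero stays
zero and the ratio structure is preserved — and combined by a weighted
linear fusion with weights normalized to sum one, yielding the attention
curve from which keyframes are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ScoreVector",
    "FusionWeights",
    "AttentionCurve",
    "frame_score",
    "normalize_scores",
    "invert_scores",
    "fuse",
]


@dataclass(frozen=True)
class ScoreVector:
    """One normalized score in [0, 1] per frame for a single model."""

    model_tag: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 1 or len(s) == 0:
            raise ValueError("scores must be a non-empty 1-D vector")
        if not np.all(np.isfinite(s)) or s.min() < -1e-12 or s.max() > 1 + 1e-12:
            raise ValueError("normalized scores must lie in [0, 1]")
        object.__setattr__(self, "scores", np.clip(s, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class FusionWeights:
    """Non-negative weight per model tag; normalized to sum 1 before use."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = {str(k): float(v) for k, v in dict(self.weights).items()}
        if any(v < 0 for v in w.values()):
            raise ValueError("fusion weights must be non-negative")
        if not any(v > 0 for v in w.values()):
            raise ValueError("at least one fusion weight must be positive")
        object.__setattr__(self, "weights", w)

    def normalized(self, tags: Iterable[str]) -> Mapping[str, float]:
        """Weights restricted to ``tags`` and rescaled to sum 1."""
        tags = list(tags)
        missing = [t for t in tags if t not in self.weights]
        if missing:
            raise ValueError(f"no fusion weight for model(s): {missing}")
        total = sum(self.weights[t] for t in tags)
        if total <= 0:
            raise ValueError(f"all weights over {tags} are zero")
        return {t: self.weights[t] / total for t in tags}


@dataclass(frozen=True)
class AttentionCurve:
    """Fused per-frame saliency in [0, 1] (the attention curve)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("attention curve must be a non-empty 1-D vector")
        if not np.all(np.isfinite(v)) or v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("attention values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.values)


def frame_score(saliency_map) -> float:
    """Mean of the strictly positive map values; 0 for an all-zero map."""
    v = np.asarray(getattr(saliency_map, "values", saliency_map), dtype=np.float64)
    pos = v[v > 0]
    return float(pos.mean()) if pos.size else 0.0


def normalize_scores(raw: Sequence[float], model_tag: str = "") -> ScoreVector:
    """Divide raw per-frame scores by their maximum.

    An all-zero vector normalizes to all zeros (a static video is a
    legitimate input, not an error).  Negative scores are a contract
    violation.
    """
    r = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(r)):
        raise ValueError("raw scores must be finite")
    if r.min() < 0:
        raise ValueError("raw scores must be non-negative")
    m = r.max()
    return ScoreVector(model_tag, r / m if m > 0 else np.zeros_like(r))


def invert_scores(vector: ScoreVector) -> ScoreVector:
    """Map normalized scores s to 1 - s.

    Used to turn motion magnitude into a stillness score: diagnostically
    important segments are the low-motion dwells, so the frames with the
    least inter-frame motion should attract the most attention.
    """
    return ScoreVector(vector.model_tag, 1.0 - vector.scores)


def fuse(vectors: Sequence[ScoreVector], weights: FusionWeights) -> AttentionCurve:
    """Weighted linear fusion of per-model score vectors.

    Weights are normalized to sum 1 over the supplied vectors' tags, so
    the fused value of every frame is a convex combination of its
    per-model scores and stays in [0, 1].
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("fuse requires at least one score vector")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("all score vectors must have equal length")
    tags = [v.model_tag for v in vectors]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate model tags in fusion input: {tags}")
    w = weights.normalized(tags)
    fused = np.zeros(n)
    for v in vectors:
        fused += w[v.model_tag] * v.scores
    return AttentionCurve(fused)
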