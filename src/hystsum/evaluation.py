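"""Scoring extracted keyframes against expert ground truth.

An extracted frame counts as correct when it can be paired one-to-one
with a ground-truth frame no more than ``tolerance`` frames away.
Matching walks the ground-truth indices in increasing order and pairs
each with the earliest still-unmatched extracted index inside the
tolerance window — the classic interval greedy, which attains the
maximum possible number of pairs.

Accuracy follows the convention of summary evaluation against a fixed
expert list: 100 * matched / total ground-truth keyframes, which equals
recall expressed as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

__all__ = ["EvalResult", "match_keyframes", "ablation_report"]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class EvalResult:
    """Counts and derived metrics of a keyframe match."""

    true_positives: int
    false_positives: int
    false_negatives: int
    accuracy: float  # percent, 100 * tp / |ground truth|
    precision: float
    recall: float
    f_measure: float
    tolerance: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tolerance: int) -> "EvalResult":
        n_truth = tp + fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_truth if n_truth else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        accuracy = 100.0 * tp / n_truth if n_truth else 0.0
        return cls(tp, fp, fn, accuracy, precision, recall, f, tolerance)


def _indices(obj) -> List[int]:
    raw: Iterable = getattr(obj, "indices", None)
    if raw is None:
        raw = getattr(obj, "keyframe_indices", obj)
    return sorted(int(i) for i in raw)


def match_keyframes(extracted, truth, tolerance: int = 0) -> EvalResult:
    """Greedy one-to-one matching within a +/- tolerance frame window.

    ``extracted`` and ``truth`` may be KeyframeSet / GroundTruth objects
    or plain index sequences.
    """
    if tolerance < 0:
        raise ParameterError(f"tolerance must be >= 0, got {tolerance}")
    ext = _indices(extracted)
    tru = _indices(truth)
    used = [False] * len(ext)
    tp = 0
    for t in tru:
        for j, e in enumerate(ext):
            if not used[j] and abs(e - t) <= tolerance:
                used[j] = True
                tp += 1
                break
    fp = used.count(False)
    fn = len(tru) - tp
    return EvalResult.from_counts(tp, fp, fn, tolerance)


def ablation_report(seq, truth, model_subsets: Sequence[Sequence[str]], config) -> pd.DataFrame:
    """Run the pipeline per model subset and tabulate its performance.

    For each subset the fusion weights outside the subset are zeroed (the
    within-subset proportions of ``config.weights`` are kept), keyframes
    are extracted with the mean-threshold rule, and the extracted count,
    threshold, accuracy and F-measure are reported — one row per subset.
    """
    from .pipeline import compute_frame_scores, build_attention_curve
    from .extraction import extract_by_threshold

    subsets = [tuple(s) for s in model_subsets]
    if any(len(s) == 0 for s in subsets):
        raise ParameterError("model subsets must be non-empty")

    raw = compute_frame_scores(seq, config.params)
    rows = []
    for subset in subsets:
        weights = {
            tag: (config.weights.get(tag, 0.0) if tag in subset else 0.0)
            for tag in raw
        }
        if not any(weights[t] > 0 for t in subset):
            weights = {tag: (1.0 if tag in subset else 0.0) for tag in raw}
        curve, _ = build_attention_curve(
            raw, weights, motion_as_stillness=config.motion_as_stillness
        )
        keys = extract_by_threshold(curve)
        res = match_keyframes(keys, truth, config.tolerance)
        rows.append(
            {
                "models": "+".join(subset),
                "total_keyframes": getattr(truth, "total_keyframes", len(_indices(truth))),
                "extracted_keyframes": len(keys),
                "attention_threshold": keys.threshold_used,
                "accuracy_pct": res.accuracy,
                "f_measure": res.f_measure,
            }
        )
    return pd.DataFrame(rows)
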