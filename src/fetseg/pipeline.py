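"""Channel-swap complete classification and timeline segmentation.

A *targeting* frame is, by definition, an ablation-looking frame whose
salient blue features are green instead.  The complete classifier therefore
runs the same trained binary ablation detector twice per frame — once on the
original image and once on its green/blue channel-swapped version — giving
two positive-class scores: the ablation score and the targeting score.
Label arbitration:

* both passes negative  -> ``other``
* only the original pass positive -> ``ablation``
* only the swapped pass positive  -> ``targeting``
* both positive -> the label with the maximum score (ties -> ablation,
  the clinically costlier miss; configurable)

Because a frame can only remain *ablation* if the original pass was
positive, the pipeline acts as a filter on the raw binary detections:
filtered positives are always a subset of raw positives, trading a little
recall for precision.  No extra annotation is needed to obtain the third
class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ClassScores, Frame, Phase

__all__ = [
    "CompleteResult",
    "swap_green_blue",
    "classify_binary",
    "classify_complete",
    "classify_frames",
    "filter_binary_predictions",
    "segment_timeline",
    "results_to_frame_table",
    "timeline_to_json",
]


@dataclass(frozen=True)
class CompleteResult:
    """Two-pass scores and the arbitrated three-way label for one frame."""

    ablation_score: float
    targeting_score: float
    final_label: Phase
    index: int = 0

    @property
    def filtered_binary(self) -> bool:
        """Binary ablation decision after the filtering action."""
        return self.final_label is Phase.ABLATION


def swap_green_blue(frame: Frame | np.ndarray) -> Frame | np.ndarray:
    """Exchange the green and blue channels pixelwise; red is untouched.

    An involution: applying it twice restores the input bitwise.  Label
    metadata is dropped — the swapped image is a synthetic inference input,
    not an annotated observation.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else frame
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {pixels.shape}")
    swapped = pixels[..., [0, 2, 1]].copy()
    if isinstance(frame, Frame):
        return Frame(
            pixels=swapped,
            mask=frame.mask.copy(),
            label=None,
            procedure_id=frame.procedure_id,
            index=frame.index,
        )
    return swapped


def classify_binary(
    model, frame: Frame | np.ndarray, threshold: float = 0.5
) -> tuple[bool, ClassScores]:
    """Binary ablation decision: positive iff score >= threshold (ties go
    positive)."""
    scores = model.score_frame(frame)
    return scores.score_positive >= threshold, scores


def classify_complete(
    model,
    frame: Frame | np.ndarray,
    threshold: float = 0.5,
    tie_break: Phase = Phase.ABLATION,
) -> CompleteResult:
    """Run both inference passes on one frame and arbitrate the label."""
    ablation_pos, ablation_scores = classify_binary(model, frame, threshold)
    swapped = swap_green_blue(frame)
    targeting_pos, targeting_scores = classify_binary(model, swapped, threshold)
    a, t = ablation_scores.score_positive, targeting_scores.score_positive
    if not ablation_pos and not targeting_pos:
        final = Phase.OTHER
    elif ablation_pos and not targeting_pos:
        final = Phase.ABLATION
    elif targeting_pos and not ablation_pos:
        final = Phase.TARGETING
    else:
        if a > t:
            final = Phase.ABLATION
        elif t > a:
            final = Phase.TARGETING
        else:
            final = tie_break
    index = frame.index if isinstance(frame, Frame) else 0
    return CompleteResult(a, t, final, index=index)


def classify_frames(
    model, frames, threshold: float = 0.5, tie_break: Phase = Phase.ABLATION
) -> list[CompleteResult]:
    """Complete classification of an ordered frame sequence."""
    return [classify_complete(model, f, threshold, tie_break) for f in frames]


def filter_binary_predictions(results: list[CompleteResult]) -> list[bool]:
    """Binary ablation labels after filtering.

    A frame stays positive only if the original-image pass was positive and
    arbitration kept the *ablation* label, so the filtered positive set is
    always a subset of the raw binary positives.
    """
    return [r.filtered_binary for r in results]


def segment_timeline(results: list[CompleteResult]) -> list[tuple[Phase, int, int]]:
    """Run-length encode per-frame labels into (phase, start, end) runs.

    Runs are maximal constant-label stretches over half-open index ranges
    ``[start, end)``; concatenating them reproduces the input labelling.
    Input must be ordered by frame index.
    """
    if not results:
        return []
    indices = [r.index for r in results]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("results must be strictly ordered by frame index")
    runs: list[tuple[Phase, int, int]] = []
    start = 0
    for i in range(1, len(results) + 1):
        if i == len(results) or results[i].final_label is not results[start].final_label:
            runs.append((results[start].final_label, start, i))
            start = i
    return runs


def results_to_frame_table(results: list[CompleteResult]) -> pd.DataFrame:
    """Per-frame results as a table (the CSV exchange format)."""
    return pd.DataFrame(
        {
            "index": [r.index for r in results],
            "ablation_score": [r.ablation_score for r in results],
            "targeting_score": [r.targeting_score for r in results],
            "final_label": [r.final_label.value for r in results],
            "filtered_binary": [int(r.filtered_binary) for r in results],
        }
    )


def timeline_to_json(runs: list[tuple[Phase, int, int]], path: str | Path | None = None) -> str:
    payload = json.dumps(
        [{"phase": p.value, "start": s, "end": e} for p, s, e in runs], indent=2
    )
    if path is not None:
        Path(path).write_text(payload)
    return payload
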