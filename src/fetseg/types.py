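"""Core domain types shared across the package.

A fetoscopic laser-ablation procedure is segmented frame-by-frame into three
surgical phases:

``targeting``
    The fibre laser projects a low-power green aiming spot on the placenta.
``ablation``
    A vessel is being photocoagulated: the projected light brightens, turns
    blue, and the tissue whitens into a coagulation blob.
``other``
    Ablation could not begin imminently — laser off, the scope too far from
    the placenta, or the view occluded (typically by the umbilical cord).

Ground-truth annotation uses only the binary projection *ablation* vs
*not-ablation*; the three-way phase is recovered at inference time by the
channel-swap pipeline (:mod:`fetseg.pipeline`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phase", "Frame", "ClassScores"]


class Phase(str, enum.Enum):
    """Surgical phase of a single fetoscopic frame."""

    ABLATION = "ablation"
    TARGETING = "targeting"
    OTHER = "other"

    @property
    def binary(self) -> bool:
        """Binary projection used for annotation: ablation vs not-ablation."""
        return self is Phase.ABLATION

    @classmethod
    def parse(cls, text: str) -> "Phase":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown phase {text!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from None


@dataclass
class Frame:
    """One RGB fetoscopic frame with its circular scope mask.

    Attributes
    ----------
    pixels
        ``(H, W, 3)`` uint8 array in red-green-blue channel order.  Pixels
        outside the scope disc are zero.
    mask
        ``(H, W)`` boolean array; True inside the centred scope disc.
    label
        Ground-truth :class:`Phase`, or ``None`` for unannotated frames.
    procedure_id
        Identifier of the procedure (video sequence) the frame belongs to.
    index
        Temporal frame index within its procedure, 0-based.
    """

    pixels: np.ndarray
    mask: np.ndarray
    label: Phase | None = None
    procedure_id: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixel grid")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ClassScores:
    """Normalised two-class softmax scores of the binary ablation classifier."""

    score_positive: float
    score_negative: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.score_negative is None:
            object.__setattr__(self, "score_negative", 1.0 - self.score_positive)
        total = self.score_positive + self.score_negative
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"scores must sum to 1, got {total}")
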