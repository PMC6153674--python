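"""Annotated-dataset handling: loading, class balancing, augmentation, splits.

A complete ablation procedure contains far more *not-ablation* than
*ablation* frames; training sets are therefore built by randomly
subsampling the majority class to parity.  Because the laser fibre keeps a
fixed orientation within any one procedure, training images are randomly
rotated so the classifier cannot overfit to the tool orientations present in
the training procedures.  Evaluation always runs on complete, imbalanced,
unrotated held-out procedures, split leave-one-out at the procedure level.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .simulate import scope_mask
from .types import Frame, Phase

__all__ = [
    "AnnotatedDataset",
    "SplitPlan",
    "load_dataset",
    "balanced_subsample",
    "random_rotation",
    "make_loocv_splits",
    "make_kfold_splits",
]


@dataclass
class AnnotatedDataset:
    """A list of labelled frames spanning one or more procedures."""

    frames: list[Frame] = field(default_factory=list)

    @property
    def procedure_ids(self) -> set[str]:
        return {f.procedure_id for f in self.frames}

    @property
    def counts(self) -> dict[bool, int]:
        """Frames per binary class: True = ablation, False = not-ablation."""
        return dict(Counter(f.label.binary for f in self.frames))

    def __len__(self) -> int:
        return len(self.frames)

    def subset(self, procedure_ids) -> "AnnotatedDataset":
        wanted = set(procedure_ids)
        return AnnotatedDataset([f for f in self.frames if f.procedure_id in wanted])


def load_dataset(root: str | Path) -> AnnotatedDataset:
    """Load a study written by :func:`fetseg.simulate.generate_study`.

    Expects ``<root>/<procedure_id>/frames/*.png`` with a ``labels.csv``
    giving (index, phase, binary) per frame.  Frames are returned sorted by
    (procedure_id, index).  Scope masks are reconstructed from the manifest
    when present, otherwise estimated from the non-black support.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    manifest = None
    mpath = root / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())

    frames: list[Frame] = []
    proc_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not proc_dirs:
        raise ValueError(f"no procedure directories under {root}")
    for pdir in proc_dirs:
        labels_path = pdir / "labels.csv"
        if not labels_path.exists():
            raise ValueError(f"missing labels.csv in {pdir}")
        table = pd.read_csv(labels_path)
        for col in ("index", "phase"):
            if col not in table.columns:
                raise ValueError(f"{labels_path} lacks required column {col!r}")
        radius_frac = None
        if manifest is not None and pdir.name in manifest.get("procedures", {}):
            radius_frac = manifest["procedures"][pdir.name]["scene"]["scope_radius_frac"]
        if len(table) == 0:
            raise ValueError(f"empty label table for procedure {pdir.name}")
        table = table.sort_values("index")
        for frame_index, phase_text in zip(table["index"], table["phase"]):
            phase = Phase.parse(str(phase_text))
            fpath = pdir / "frames" / f"{int(frame_index):06d}.png"
            if not fpath.exists():
                raise FileNotFoundError(f"frame file missing: {fpath}")
            pixels = np.asarray(iio.imread(fpath))
            if radius_frac is not None:
                mask = scope_mask(pixels.shape[0], radius_frac)
            else:
                mask = _estimate_mask(pixels)
            frames.append(
                Frame(
                    pixels=pixels,
                    mask=mask,
                    label=phase,
                    procedure_id=pdir.name,
                    index=int(frame_index),
                )
            )
    frames.sort(key=lambda f: (f.procedure_id, f.index))
    return AnnotatedDataset(frames)


def _estimate_mask(pixels: np.ndarray) -> np.ndarray:
    """Fallback disc mask from the furthest non-black pixel to the centre."""
    s = pixels.shape[0]
    nz = np.argwhere(pixels.any(axis=2))
    if len(nz) == 0:
        return np.zeros(pixels.shape[:2], dtype=bool)
    c = (s - 1) / 2.0
    r = np.sqrt(((nz - c) ** 2).sum(axis=1).max())
    return scope_mask(s, min(1.0, 2.0 * r / s))


def balanced_subsample(ds: AnnotatedDataset, seed: int) -> AnnotatedDataset:
    """Subsample the majority binary class to an exact 1:1 class ratio.

    The minority class is kept whole; a uniform random subset of the
    majority class of equal size is drawn, reproducibly from ``seed``.
    """
    pos = [f for f in ds.frames if f.label.binary]
    neg = [f for f in ds.frames if not f.label.binary]
    if not pos or not neg:
        missing = "ablation" if not pos else "not-ablation"
        raise ValueError(f"cannot balance: class {missing!r} is absent")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        keep = rng.choice(len(pos), size=len(neg), replace=False)
        pos = [pos[i] for i in sorted(keep)]
    elif len(neg) > len(pos):
        keep = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(keep)]
    out = pos + neg
    out.sort(key=lambda f: (f.procedure_id, f.index))
    return AnnotatedDataset(out)


def random_rotation(
    frame: Frame, seed: int | None = None, angle: float | None = None
) -> Frame:
    """Rotate a frame about the image centre by a uniform random angle.

    The label is unchanged and the centred scope disc maps onto itself, so
    the mask is preserved; corners outside the disc stay black.  Exact
    quarter-turns use lossless array rotation; other angles use bilinear
    resampling with black fill.
    """
    if frame.pixels.shape[0] != frame.pixels.shape[1]:
        raise ValueError("random_rotation requires a square frame")
    if angle is None:
        angle = float(np.random.default_rng(seed).uniform(0.0, 360.0))
    pixels = rotate_pixels(frame.pixels, angle)
    pixels[~frame.mask] = 0
    return Frame(
        pixels=pixels,
        mask=frame.mask.copy(),
        label=frame.label,
        procedure_id=frame.procedure_id,
        index=frame.index,
    )


def rotate_pixels(pixels: np.ndarray, angle: float) -> np.ndarray:
    """Rotate an (H, W[, C]) image by ``angle`` degrees about its centre."""
    angle = angle % 360.0
    if angle % 90.0 == 0.0:
        return np.rot90(pixels, k=int(angle // 90), axes=(0, 1)).copy()
    out = sktransform.rotate(
        pixels.astype(np.float64), angle, order=1, mode="constant", cval=0.0,
        preserve_range=True,
    )
    if np.issubdtype(pixels.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(pixels.dtype)
    return out.astype(pixels.dtype)


@dataclass(frozen=True)
class SplitPlan:
    """Cross-validation folds of (training procedure ids, validation id)."""

    folds: tuple[tuple[tuple[str, ...], str], ...]

    def to_json(self) -> str:
        return json.dumps(
            [{"train": list(tr), "validation": va} for tr, va in self.folds], indent=2
        )


def make_loocv_splits(ds: AnnotatedDataset) -> SplitPlan:
    """Leave-one-procedure-out splits: each procedure validates exactly once.

    Class balancing and rotation augmentation apply to the training portion
    only; validation procedures are evaluated complete and imbalanced.
    """
    ids = sorted(ds.procedure_ids)
    if len(ids) < 2:
        raise ValueError("leave-one-out needs at least 2 procedures")
    folds = tuple(
        (tuple(p for p in ids if p != held_out), held_out) for held_out in ids
    )
    return SplitPlan(folds)


def make_kfold_splits(ds: AnnotatedDataset, k: int, seed: int = 0) -> SplitPlan:
    """Procedure-level k-fold splits (k = number of procedures reduces to
    leave-one-out with one validation procedure per fold)."""
    ids = sorted(ds.procedure_ids)
    if not (2 <= k <= len(ids)):
        raise ValueError(f"k must lie in [2, {len(ids)}]")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    folds = []
    for chunk in np.array_split(np.asarray(order, dtype=object), k):
        for held_out in chunk:
            train = tuple(p for p in ids if p not in set(chunk))
            folds.append((train, str(held_out)))
    return SplitPlan(tuple(folds))
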