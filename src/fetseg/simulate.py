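"""Synthetic fetoscopy-frame simulator.

Generates fetoscopic-looking frames and whole laser-ablation "procedures"
with ground-truth phase labels, emulating the appearance factors that make
real TTTS video hard: bright vs dim light sources, amniotic-fluid turbidity,
defocus blur, umbilical-cord occlusion, a laser tool whose orientation is
fixed within one procedure but arbitrary between procedures, and the laser
light itself — a low-power green aiming spot during *targeting* and a
brighter blue spot with a whitening coagulation blob during *ablation*.

The photometric model is deliberately minimal: a Gaussian radial profile for
the projected spot, with the ablation peak at least twice the targeting peak
plus an additive white disc for the coagulated tissue.  *Other* frames are
produced three ways — laser off, the spot hidden behind a cord-like
occluder, or a defocused/faded spot when the scope has drifted away from the
placenta.

All rendering is deterministic given the scene, phase, and seed.  Pixel
arrays are uint8 RGB; everything outside the centred circular scope mask is
black.  Coordinates are row-major with the origin at top-left.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .types import Frame, Phase

__all__ = [
    "SceneParams",
    "ParamRanges",
    "ProcedureScript",
    "render_frame",
    "render_matched_pair",
    "generate_procedure",
    "random_script",
    "generate_study",
    "DEFAULT_RANGES",
]

# Unit RGB tints of the projected laser light.  Targeting is green-dominant,
# ablation blue-dominant; red is kept equal so the two differ only in the
# green/blue exchange plus overall intensity.
_TARGETING_TINT = np.array([0.15, 1.00, 0.30])
_ABLATION_TINT = np.array([0.15, 0.15, 1.00])
# Ablation peak intensity relative to the targeting peak (>= 2).
_ABLATION_GAIN = 2.2

_PLACENTA_RGB = np.array([0.55, 0.25, 0.25])
_GRAY_RGB = np.array([0.36, 0.36, 0.36])
_HAZE_RGB = np.array([0.45, 0.40, 0.40])
_TOOL_GRAY = 0.12
_OCCLUDER_RGB = np.array([0.16, 0.10, 0.10])


@dataclass(frozen=True)
class SceneParams:
    """Static appearance parameters of one procedure's scene.

    ``tool_angle_deg`` is the orientation at which the laser fibre enters the
    circular field of view; it stays constant within a procedure and changes
    arbitrarily between procedures.  ``background_gray`` forces an exactly
    channel-balanced (R=G=B) background so that green/blue channel swaps are
    pixel-exact, which matched-pair tests rely on.
    """

    image_size: int = 448
    scope_radius_frac: float = 0.90
    light_intensity: float = 0.85
    turbidity: float = 0.10
    blur_sigma: float = 1.0
    tool_angle_deg: float = 40.0
    spot_visible: bool = True
    occluder_present: bool = False
    background_gray: bool = False
    texture_seed: int = 0
    spot_strength: float = 0.55
    noise_sigma: float = 0.02

    def validate(self) -> None:
        if int(self.image_size) != self.image_size or self.image_size <= 0:
            raise ValueError(f"image_size must be a positive integer, got {self.image_size}")
        if not (0.0 < self.scope_radius_frac <= 1.0):
            raise ValueError("scope_radius_frac must lie in (0, 1]")
        if not (0.0 < self.light_intensity <= 1.0):
            raise ValueError("light_intensity must lie in (0, 1]")
        if not (0.0 <= self.turbidity <= 1.0):
            raise ValueError("turbidity must lie in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not (0.0 <= self.tool_angle_deg < 360.0):
            raise ValueError("tool_angle_deg must lie in [0, 360)")


def scope_mask(image_size: int, radius_frac: float) -> np.ndarray:
    """Boolean disc mask, centred, radius ``radius_frac`` of the half-width."""
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    return r2 <= (radius_frac * image_size / 2.0) ** 2


def _radial2(size: int, cy: float, cx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2


def _tool_geometry(scene: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (tip position (y, x), inward unit vector) of the laser fibre."""
    s = scene.image_size
    c = (s - 1) / 2.0
    theta = np.deg2rad(scene.tool_angle_deg)
    # Unit vector from centre towards the rim entry point.  Screen y grows
    # downwards, so the angle is measured clockwise from the +x axis.
    u = np.array([np.sin(theta), np.cos(theta)])
    rim = np.array([c, c]) + u * (scene.scope_radius_frac * s / 2.0)
    tip = np.array([c, c]) + u * (0.45 * scene.scope_radius_frac * s / 2.0)
    return tip, -u


def _paint_band(
    img: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    width: float,
    color: np.ndarray,
) -> None:
    """Alpha-blend a soft-edged thick segment from p0 to p1 over ``img``."""
    s = img.shape[0]
    yy, xx = np.mgrid[0:s, 0:s]
    d = p1 - p0
    length2 = float(d @ d)
    py, px = yy - p0[0], xx - p0[1]
    t = np.clip((py * d[0] + px * d[1]) / max(length2, 1e-9), 0.0, 1.0)
    dist = np.hypot(py - t * d[0], px - t * d[1])
    edge = max(1.0, 0.15 * width)
    alpha = np.clip((width - dist) / edge, 0.0, 1.0)[..., None]
    img[:] = (1 - alpha) * img + alpha * color


def render_frame(scene: SceneParams, phase: Phase, rng_seed: int) -> Frame:
    """Render one labelled frame.

    Targeting frames carry a green-dominant Gaussian spot near the tool tip;
    ablation frames a blue-dominant spot at >= 2x the targeting peak plus a
    white coagulation blob.  *Other* frames show no usable spot: the laser is
    off (``spot_visible`` False), hidden behind an occluder, or rendered
    faint and defocused.  Identical ``(scene, phase, rng_seed)`` give
    bitwise-identical frames.
    """
    scene.validate()
    phase = Phase(phase)
    rng = np.random.default_rng(rng_seed)
    s = scene.image_size
    mask = scope_mask(s, scene.scope_radius_frac)

    # --- background: base colour, smooth texture, radial vignette ---
    base = _GRAY_RGB if scene.background_gray else _PLACENTA_RGB
    img = np.ones((s, s, 3)) * base * scene.light_intensity
    trng = np.random.default_rng(scene.texture_seed)
    field = ndimage.gaussian_filter(trng.standard_normal((s, s)), sigma=s / 24.0)
    sd = field.std()
    if sd > 0:
        field = field / sd
    img += (0.06 * scene.light_intensity) * field[..., None]
    c = (s - 1) / 2.0
    r2 = _radial2(s, c, c)
    vignette = 1.0 - 0.35 * r2 / (s / 2.0) ** 2
    img *= vignette[..., None]

    # --- laser fibre, entering from the rim at the fixed per-procedure angle
    tip, inward = _tool_geometry(scene)
    rim = tip - inward * (0.55 * scene.scope_radius_frac * s / 2.0)
    _paint_band(img, rim, tip, width=0.055 * s, color=np.full(3, _TOOL_GRAY))

    # --- projected laser spot ---
    spot_center = None
    if scene.spot_visible and (
        phase is not Phase.OTHER or not scene.occluder_present
    ):
        jitter = rng.uniform(-0.04 * s, 0.04 * s, size=2)
        spot_center = tip + inward * (0.18 * s) + jitter
        lim = 0.70 * scene.scope_radius_frac * s / 2.0
        off = spot_center - np.array([c, c])
        norm = np.hypot(*off)
        if norm > lim:
            spot_center = np.array([c, c]) + off * (lim / norm)
    if scene.spot_visible and spot_center is not None:
        sigma = 0.045 * s
        r2s = _radial2(s, spot_center[0], spot_center[1])
        if phase is Phase.TARGETING:
            g = np.exp(-r2s / (2 * sigma**2))
            img += scene.spot_strength * g[..., None] * _TARGETING_TINT
        elif phase is Phase.ABLATION:
            g = np.exp(-r2s / (2 * sigma**2))
            img += _ABLATION_GAIN * scene.spot_strength * g[..., None] * _ABLATION_TINT
            # white coagulated tissue; amplitude leaves green/red headroom
            # below saturation so the blue spot peak stays strictly dominant
            blob = 0.30 * np.exp(-(r2s**2) / (2 * (0.55 * sigma) ** 4))
            img += blob[..., None]
        else:  # OTHER with the laser nominally on: faint, defocused spot
            g = np.exp(-r2s / (2 * (2.5 * sigma) ** 2))
            img += 0.12 * scene.spot_strength * g[..., None] * _TARGETING_TINT

    # --- umbilical-cord occluder, drawn over the spot ---
    if scene.occluder_present:
        anchor = spot_center if spot_center is not None else tip + inward * (0.18 * s)
        ang = rng.uniform(0, np.pi)
        d = np.array([np.sin(ang), np.cos(ang)])
        _paint_band(img, anchor - d * s, anchor + d * s, width=0.16 * s, color=_OCCLUDER_RGB)

    # --- amniotic-fluid turbidity, defocus, sensor noise ---
    haze = _HAZE_RGB * scene.light_intensity
    img = (1 - 0.6 * scene.turbidity) * img + 0.6 * scene.turbidity * haze
    if scene.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(scene.blur_sigma, scene.blur_sigma, 0))
    if scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    img[~mask] = 0.0
    pixels = np.round(img * 255.0).astype(np.uint8)
    return Frame(pixels=pixels, mask=mask, label=phase)


def render_matched_pair(scene: SceneParams, rng_seed: int) -> tuple[Frame, Frame]:
    """Render a targeting/ablation pair identical up to a green/blue swap.

    The pair shares geometry, background, and noise realisation; the ablation
    member is the exact green/blue channel exchange of the targeting member,
    so ``swap_green_blue`` maps one onto the other with zero pixel error.
    Requires a channel-balanced background (``background_gray=True``); any
    chromatic background would break the exact symmetry.
    """
    if not scene.background_gray:
        raise ValueError("render_matched_pair requires scene.background_gray=True")
    frame_t = render_frame(scene, Phase.TARGETING, rng_seed)
    swapped = frame_t.pixels[..., [0, 2, 1]].copy()
    frame_a = Frame(
        pixels=swapped,
        mask=frame_t.mask.copy(),
        label=Phase.ABLATION,
        procedure_id=frame_t.procedure_id,
        index=frame_t.index,
    )
    return frame_t, frame_a


@dataclass(frozen=True)
class ProcedureScript:
    """Temporal phase script driving the simulation of one procedure."""

    segments: tuple[tuple[Phase, int], ...]
    scene: SceneParams
    seed: int = 0

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("script has no segments")
        phases = [Phase(p) for p, _ in self.segments]
        for _, n in self.segments:
            if n < 1:
                raise ValueError("every segment needs n_frames >= 1")
        for i, p in enumerate(phases):
            if p is Phase.ABLATION:
                neighbours = phases[max(0, i - 1) : i] + phases[i + 1 : i + 2]
                if Phase.TARGETING not in neighbours:
                    raise ValueError(
                        "ablation segments must be temporally adjacent to a "
                        "targeting segment (pass allow_nonadjacent=True to override)"
                    )


def generate_procedure(
    script: ProcedureScript,
    procedure_id: str = "proc",
    allow_nonadjacent: bool = False,
) -> list[Frame]:
    """Render a whole procedure from its script.

    Per-frame variation (spot jitter, light flicker, the particular cause of
    an *other* frame) is drawn deterministically from ``script.seed``; the
    tool orientation stays fixed throughout, as it does within one real
    ablation procedure.
    """
    if not allow_nonadjacent:
        script.validate()
    else:
        for _, n in script.segments:
            if n < 1:
                raise ValueError("every segment needs n_frames >= 1")
    rng = np.random.default_rng(script.seed)
    frames: list[Frame] = []
    idx = 0
    for phase, n in script.segments:
        phase = Phase(phase)
        for _ in range(n):
            flicker = float(rng.uniform(0.97, 1.0))
            scene = dataclasses.replace(
                script.scene,
                light_intensity=min(1.0, script.scene.light_intensity * flicker),
            )
            if phase is Phase.OTHER:
                mode = rng.integers(3)
                if mode == 0:  # laser switched off
                    scene = dataclasses.replace(scene, spot_visible=False)
                elif mode == 1:  # cord occlusion
                    scene = dataclasses.replace(scene, occluder_present=True)
                else:  # scope drifted away: defocus + faded spot
                    scene = dataclasses.replace(
                        scene, blur_sigma=scene.blur_sigma * 3.5 + 2.0
                    )
            frame_seed = int(rng.integers(0, 2**31 - 1))
            f = render_frame(scene, phase, frame_seed)
            f.procedure_id = procedure_id
            f.index = idx
            frames.append(f)
            idx += 1
    return frames


def random_script(
    rng: np.random.Generator,
    n_frames: int,
    scene: SceneParams,
    seed: int,
) -> ProcedureScript:
    """Draw a plausible procedure script: navigation, then targeting/ablation
    cycles, closing with the scope withdrawing (*other*)."""
    if n_frames < 4:
        raise ValueError("a procedure needs at least 4 frames")
    head = min(max(1, int(0.10 * n_frames)), (n_frames - 2) // 2)
    tail = min(max(1, int(0.10 * n_frames)), (n_frames - 2) // 2)
    body = n_frames - head - tail
    n_cycles = max(1, min(int(rng.integers(2, 4)), body // 2))
    segments: list[tuple[Phase, int]] = [(Phase.OTHER, head)]
    # each cycle: targeting then ablation; weights give ~2:1 targeting:ablation
    weights = rng.uniform(0.5, 1.5, size=2 * n_cycles)
    weights[0::2] *= 2.0
    counts = np.ones(2 * n_cycles, dtype=int)
    extra = body - counts.sum()
    share = (extra * weights / weights.sum()).astype(int)
    counts += share
    for i in np.argsort(-weights)[: extra - share.sum()]:
        counts[i] += 1
    for k in range(n_cycles):
        segments.append((Phase.TARGETING, int(counts[2 * k])))
        segments.append((Phase.ABLATION, int(counts[2 * k + 1])))
    segments.append((Phase.OTHER, tail))
    return ProcedureScript(segments=tuple(segments), scene=scene, seed=seed)


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for per-procedure scene parameters.

    Blur is specified at the native 448-pixel scale and rescaled to the
    rendered size so that appearance is comparable across resolutions.
    """

    light_intensity: tuple[float, float] = (0.55, 1.0)
    turbidity: tuple[float, float] = (0.0, 0.3)
    blur_sigma_448: tuple[float, float] = (0.6, 1.6)
    spot_strength: tuple[float, float] = (0.45, 0.65)
    scope_radius_frac: tuple[float, float] = (0.82, 0.95)


DEFAULT_RANGES = ParamRanges()


def generate_study(
    root: str | Path,
    n_procedures: int = 5,
    seed: int = 0,
    image_size: int = 448,
    frames_per_procedure: int = 120,
    ranges: ParamRanges = DEFAULT_RANGES,
    overwrite: bool = False,
) -> dict:
    """Write a multi-procedure synthetic study to disk and return its manifest.

    Each procedure draws its own scene parameters (distinct tool angle,
    lighting, turbidity...).  With five or more procedures the study mirrors
    the clinical variability pattern: one high-turbidity, one dim-light, and
    one weak-laser-spot procedure among otherwise bright sequences.

    Layout: ``<root>/<procedure_id>/frames/%06d.png`` plus
    ``<root>/<procedure_id>/labels.csv`` (columns index, phase, binary) and a
    ``manifest.json`` at the root recording every parameter and seed.
    """
    if n_procedures < 2:
        raise ValueError("a study needs at least 2 procedures")
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{root} exists and is not empty; pass overwrite=True")
    root.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    manifest: dict = {
        "seed": int(seed),
        "image_size": int(image_size),
        "frames_per_procedure": int(frames_per_procedure),
        "procedures": {},
    }
    for i in range(n_procedures):
        pid = f"proc_{i:02d}"
        scene = SceneParams(
            image_size=image_size,
            scope_radius_frac=float(rng.uniform(*ranges.scope_radius_frac)),
            light_intensity=float(rng.uniform(*ranges.light_intensity)),
            turbidity=float(rng.uniform(*ranges.turbidity)),
            blur_sigma=float(rng.uniform(*ranges.blur_sigma_448)) * image_size / 448.0,
            tool_angle_deg=float(rng.uniform(0.0, 360.0)),
            spot_strength=float(rng.uniform(*ranges.spot_strength)),
            texture_seed=int(rng.integers(0, 2**31 - 1)),
        )
        if n_procedures >= 5:
            # mirror the clinical study's hard sequences
            if i == 2:
                scene = dataclasses.replace(scene, turbidity=0.7)
            elif i == 3:
                scene = dataclasses.replace(scene, light_intensity=0.25)
            elif i == 4:
                scene = dataclasses.replace(scene, spot_strength=0.12)
        script_seed = int(rng.integers(0, 2**31 - 1))
        script = random_script(rng, frames_per_procedure, scene, script_seed)
        frames = generate_procedure(script, procedure_id=pid)

        pdir = root / pid
        (pdir / "frames").mkdir(parents=True, exist_ok=True)
        rows = []
        for f in frames:
            iio.imwrite(pdir / "frames" / f"{f.index:06d}.png", f.pixels)
            rows.append(
                {"index": f.index, "phase": f.label.value, "binary": int(f.label.binary)}
            )
        pd.DataFrame(rows).to_csv(pdir / "labels.csv", index=False)
        manifest["procedures"][pid] = {
            "scene": dataclasses.asdict(scene),
            "script_seed": script_seed,
            "segments": [[p.value, int(n)] for p, n in script.segments],
        }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
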