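"""Procedural layered head phantom with one inserted stroke.

The phantom is a stand-in for a segmented anatomical brain slice: nested
ellipses model skin, skull, cerebrospinal fluid and brain (grey matter with a
white-matter core), immersed in a lossy matching medium (ε=23, σ=0.19 S/m).
One circular stroke — ischemic (synthetic surrogate tissue) or hemorrhagic
(blood) — with radius in the 1–2.6 cm range is placed entirely inside the
brain region.  Each tissue's dispersive parameters are multiplied by a
per-sample factor drawn uniformly in [0.9, 1.1] to mimic inter-subject
variability, and layer geometry is jittered a few percent.

Ground truth uses three classes: 0 = background / non-stroke tissue,
1 = ischemic stroke, 2 = hemorrhagic stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..geometry import ImagingGrid, MeasurementConfig, circular_config
from ..scene import PermittivityScene
from .tissues import (
    BLOOD,
    BONE_CORTICAL,
    CSF,
    GREY_MATTER,
    ISCHEMIC,
    SKIN_DRY,
    WHITE_MATTER,
    ColeColeTissue,
    cole_cole_eps,
    matching_medium_eps,
)

STROKE_RADIUS_RANGE = (0.010, 0.026)  # m
PERTURBATION_RANGE = (0.9, 1.1)

ISCHEMIC_CLASS = 1
HEMORRHAGIC_CLASS = 2


@dataclass(frozen=True)
class StrokeSpec:
    kind: str  # "ischemic" | "hemorrhagic"
    center: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class HeadPhantomSpec:
    """Geometry and per-tissue perturbation factors of one phantom sample."""

    skin_axes: tuple[float, float]
    skin_thickness: float
    skull_thickness: float
    csf_thickness: float
    white_fraction: float
    stroke: StrokeSpec
    perturbations: dict[str, float]
    seed: int


@dataclass
class HeadPhantomSample:
    """Per-frequency scenes (with and without the stroke) plus ground truth."""

    stroke_scenes: list[PermittivityScene]
    healthy_scenes: list[PermittivityScene]
    spec: HeadPhantomSpec
    labels: np.ndarray  # (ny, nx) int, 3-class


def brain_config(n_antennas: int = 16, radius: float = 0.25) -> MeasurementConfig:
    """16 Tx/Rx on a ring, 4 evenly spaced frequencies in 0.5–1.25 GHz."""
    return circular_config(n_antennas, n_antennas, radius, [0.5e9, 0.75e9, 1.0e9, 1.25e9])


def brain_grid(n: int = 64) -> ImagingGrid:
    return ImagingGrid(n, n, 0.24)


def _ellipse_mask(grid: ImagingGrid, axes: tuple[float, float]) -> np.ndarray:
    x, y = grid.axes()
    xx, yy = np.meshgrid(x, y)
    return (xx / axes[0]) ** 2 + (yy / axes[1]) ** 2 <= 1.0


def _tissue_masks(grid: ImagingGrid, spec: HeadPhantomSpec) -> dict[str, np.ndarray]:
    a, b = spec.skin_axes
    skin = _ellipse_mask(grid, (a, b))
    skull = _ellipse_mask(grid, (a - spec.skin_thickness, b - spec.skin_thickness))
    csf = _ellipse_mask(
        grid, (a - spec.skin_thickness - spec.skull_thickness,
               b - spec.skin_thickness - spec.skull_thickness)
    )
    brain_axes = _brain_axes(spec)
    brain = _ellipse_mask(grid, brain_axes)
    white = _ellipse_mask(grid, (brain_axes[0] * spec.white_fraction,
                                 brain_axes[1] * spec.white_fraction))
    return {
        "skin-dry": skin & ~skull,
        "bone-cortical": skull & ~csf,
        "csf": csf & ~brain,
        "grey-matter": brain & ~white,
        "white-matter": white,
    }


def _brain_axes(spec: HeadPhantomSpec) -> tuple[float, float]:
    shrink = spec.skin_thickness + spec.skull_thickness + spec.csf_thickness
    return (spec.skin_axes[0] - shrink, spec.skin_axes[1] - shrink)


def sample_head_phantom(
    rng_seed: int,
    grid: ImagingGrid,
    stroke_kind: str,
    frequencies,
    max_tries: int = 1000,
) -> HeadPhantomSample:
    """Draw one randomized head phantom with a single stroke; seed-deterministic."""
    if stroke_kind not in ("ischemic", "hemorrhagic"):
        raise ValueError(f"unknown stroke kind {stroke_kind!r}")
    rng = np.random.default_rng(rng_seed)
    frequencies = np.asarray(frequencies, float)

    scale = rng.uniform(0.95, 1.05)
    spec_geo = HeadPhantomSpec(
        skin_axes=(0.085 * scale, 0.100 * scale),
        skin_thickness=0.004,
        skull_thickness=0.007,
        csf_thickness=0.003,
        white_fraction=0.60,
        stroke=StrokeSpec(stroke_kind, (0.0, 0.0), 0.0),  # placeholder
        perturbations={
            name: float(rng.uniform(*PERTURBATION_RANGE))
            for name in ("skin-dry", "bone-cortical", "csf", "grey-matter",
                         "white-matter", "stroke")
        },
        seed=rng_seed,
    )

    # place the stroke disc entirely inside the brain ellipse
    ba, bb = _brain_axes(spec_geo)
    for _ in range(max_tries):
        r = rng.uniform(*STROKE_RADIUS_RANGE)
        c = rng.uniform(-ba, ba), rng.uniform(-bb, bb)
        if (c[0] / (ba - r)) ** 2 + (c[1] / (bb - r)) ** 2 <= 1.0 and r < min(ba, bb):
            break
    else:
        raise RuntimeError(f"stroke placement failed after {max_tries} tries")
    spec = replace(spec_geo, stroke=StrokeSpec(stroke_kind, (float(c[0]), float(c[1])), float(r)))

    masks = _tissue_masks(grid, spec)
    x, y = grid.axes()
    xx, yy = np.meshgrid(x, y)
    stroke_mask = (xx - spec.stroke.center[0]) ** 2 + (yy - spec.stroke.center[1]) ** 2 <= r**2
    brain_mask = masks["grey-matter"] | masks["white-matter"]
    stroke_mask &= brain_mask

    base_tissues: dict[str, ColeColeTissue] = {
        "skin-dry": SKIN_DRY,
        "bone-cortical": BONE_CORTICAL,
        "csf": CSF,
        "grey-matter": GREY_MATTER,
        "white-matter": WHITE_MATTER,
    }
    perturbed = {
        name: t.scaled(spec.perturbations[name]) for name, t in base_tissues.items()
    }
    stroke_tissue = (ISCHEMIC if stroke_kind == "ischemic" else BLOOD).scaled(
        spec.perturbations["stroke"]
    )

    stroke_scenes, healthy_scenes = [], []
    for f in frequencies:
        eps_b = matching_medium_eps(float(f))
        eps = np.full((grid.ny, grid.nx), eps_b)
        for name, mask in masks.items():
            eps[mask] = cole_cole_eps(perturbed[name], float(f))
        healthy_scenes.append(PermittivityScene(grid, eps.copy(), eps_b))
        eps[stroke_mask] = cole_cole_eps(stroke_tissue, float(f))
        stroke_scenes.append(PermittivityScene(grid, eps, eps_b))

    labels = np.zeros((grid.ny, grid.nx), np.int64)
    labels[stroke_mask] = ISCHEMIC_CLASS if stroke_kind == "ischemic" else HEMORRHAGIC_CLASS
    return HeadPhantomSample(stroke_scenes, healthy_scenes, spec, labels)


def nominal_healthy_scenes(grid: ImagingGrid, frequencies) -> list[PermittivityScene]:
    """Unperturbed healthy head, used as the known background for the numerical
    Green's function tables of the differential-imaging pipeline."""
    sample = sample_head_phantom(0, grid, "ischemic", frequencies)
    # rebuild without perturbations or stroke
    spec = replace(
        sample.spec,
        skin_axes=(0.085, 0.100),
        perturbations={k: 1.0 for k in sample.spec.perturbations},
    )
    masks = _tissue_masks(grid, spec)
    tissues = {
        "skin-dry": SKIN_DRY,
        "bone-cortical": BONE_CORTICAL,
        "csf": CSF,
        "grey-matter": GREY_MATTER,
        "white-matter": WHITE_MATTER,
    }
    scenes = []
    for f in np.asarray(frequencies, float):
        eps_b = matching_medium_eps(float(f))
        eps = np.full((grid.ny, grid.nx), eps_b)
        for name, mask in masks.items():
            eps[mask] = cole_cole_eps(tissues[name], float(f))
        scenes.append(PermittivityScene(grid, eps, eps_b))
    return scenes
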