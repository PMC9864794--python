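"""Random two-cylinder dielectric scenes and contrast-class binning.

The free-space training family consists of two possibly overlapping lossless
homogeneous circular cylinders drawn uniformly in centre, radius (1.2–5 cm) and
relative permittivity (1.3–3.5), fully contained in the 25×25 cm imaging
domain.  Ground truth is the pixelwise contrast thresholded into Nc = 7
classes: class 0 is the zero-contrast background and classes 1..6 are the
half-open intervals (0,0.6], (0.6,1.0], (1.0,1.4], (1.4,1.8], (1.8,2.2],
(2.2,2.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry import ImagingGrid
from ..scene import PermittivityScene, disc_mask  # noqa: F401  (disc_mask re-exported)


@dataclass(frozen=True)
class ClassBinning:
    """Ordered contrast thresholds defining the segmentation classes.

    ``edges = (e0, e1, …, eK)`` with ``e0 = 0`` defines class 0 for τ = 0 and
    class i for τ ∈ (e_{i−1}, e_i]; every admissible τ maps to exactly one
    class.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if e.size < 2 or e[0] != 0.0 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must start at 0 and increase strictly")

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    def classify(self, tau: np.ndarray) -> np.ndarray:
        """Map real contrast values to class labels (upper edge inclusive)."""
        tau = np.asarray(tau, float)
        edges = np.asarray(self.edges)
        tol = 1e-9 * edges[-1]
        bad = (tau < -tol) | (tau > edges[-1] + tol)
        if np.any(bad):
            raise ValueError(
                f"contrast {tau[bad].flat[0]:.6g} outside the admissible "
                f"range [0, {edges[-1]:g}]"
            )
        return np.searchsorted(edges, np.clip(tau, 0.0, edges[-1]), side="left").astype(np.int64)

    def interval(self, class_id: int) -> str:
        if class_id == 0:
            return "0"
        return f"({self.edges[class_id - 1]:g},{self.edges[class_id]:g}]"


#: The 7-class binning of the contrast range [0, 2.5] used for the cylinder corpus.
SEVEN_CLASS_BINNING = ClassBinning((0.0, 0.6, 1.0, 1.4, 1.8, 2.2, 2.5))


@dataclass(frozen=True)
class CylinderSpec:
    """One lossless homogeneous circular cylinder."""

    center: tuple[float, float]
    radius: float
    eps: float


@dataclass(frozen=True)
class CylinderSceneSpec:
    """Provenance record for a sampled two-cylinder scene."""

    cylinders: tuple[CylinderSpec, ...]
    seed: int


RADIUS_RANGE = (0.012, 0.05)  # m
EPS_RANGE = (1.3, 3.5)


def sample_cylinder_scene(
    rng_seed: int,
    grid: ImagingGrid,
    radius_range: tuple[float, float] = RADIUS_RANGE,
    eps_range: tuple[float, float] = EPS_RANGE,
    eps_choices: tuple[float, ...] | None = None,
    min_separation: float | None = None,
    max_tries: int = 1000,
) -> tuple[PermittivityScene, CylinderSceneSpec]:
    """Draw two cylinders uniformly, fully contained in Ω; rasterize pixelwise.

    Overlap is allowed by default (the second-drawn cylinder overwrites the
    first, producing nested-target cases); ``min_separation`` forces a gap
    between the two boundaries instead.  ``eps_choices`` restricts the
    permittivities to a discrete set (used by the easy corpus).  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    half = grid.side_length / 2.0
    specs: list[CylinderSpec] = []
    for _ in range(max_tries):
        r = rng.uniform(*radius_range)
        c = rng.uniform(-(half - r), half - r, size=2)
        if eps_choices is not None:
            eps = float(rng.choice(np.asarray(eps_choices)))
        else:
            eps = float(rng.uniform(*eps_range))
        cand = CylinderSpec((float(c[0]), float(c[1])), float(r), eps)
        if min_separation is not None and specs:
            d = np.hypot(cand.center[0] - specs[0].center[0], cand.center[1] - specs[0].center[1])
            if d < specs[0].radius + cand.radius + min_separation:
                continue
        specs.append(cand)
        if len(specs) == 2:
            break
    else:
        raise RuntimeError(f"cylinder placement failed after {max_tries} tries")

    scene = PermittivityScene.homogeneous(grid)
    for s in specs:
        scene = scene.with_disc(s.center, s.radius, s.eps)
    return scene, CylinderSceneSpec(tuple(specs), rng_seed)


def segment_ground_truth(scene: PermittivityScene, binning: ClassBinning) -> np.ndarray:
    """Pixelwise class labels from the thresholded contrast, shape (ny, nx)."""
    tau = scene.contrast
    if np.any(np.abs(tau.imag) > 1e-9 * (1.0 + np.abs(tau.real))):
        raise ValueError("class binning is defined for real (lossless) contrast")
    return binning.classify(tau.real)
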