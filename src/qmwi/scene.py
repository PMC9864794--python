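"""Permittivity scenes and contrast maps.

A scene stores the equivalent complex relative permittivity
``εeq(r) = ε(r) − j σ(r)/(ω ε0)`` of every pixel at one frequency, together with
the host-medium permittivity ``εb``.  The unknown of the inverse problem is the
contrast ``τ(r) = εeq(r)/εb − 1``, which vanishes in the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import EPS0, ImagingGrid


def equivalent_permittivity(eps_r, sigma, frequency: float) -> np.ndarray:
    """εeq = ε − j σ/(ω ε0) under the exp(+jωt) convention."""
    omega = 2.0 * np.pi * frequency
    return np.asarray(eps_r, complex) - 1j * np.asarray(sigma, float) / (omega * EPS0)


@dataclass
class PermittivityScene:
    """Pixelwise complex permittivity map at a single frequency."""

    grid: ImagingGrid
    eps_eq: np.ndarray
    eps_background: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        self.eps_eq = np.asarray(self.eps_eq, complex)
        if self.eps_eq.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"eps_eq shape {self.eps_eq.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.eps_eq)):
            raise ValueError("eps_eq contains non-finite values")

    @property
    def contrast(self) -> np.ndarray:
        """τ(r) = εeq(r)/εb − 1, shape (ny, nx)."""
        return self.eps_eq / self.eps_background - 1.0

    @classmethod
    def homogeneous(cls, grid: ImagingGrid, eps_background: complex = 1.0 + 0.0j):
        """Target-free scene (τ ≡ 0)."""
        eps = np.full((grid.ny, grid.nx), complex(eps_background))
        return cls(grid, eps, eps_background)

    def with_disc(
        self, center, radius: float, eps_eq: complex, antialias: bool = False
    ) -> "PermittivityScene":
        """Return a copy with a homogeneous disc painted over the scene.

        ``antialias=True`` blends boundary pixels by their covered area fraction
        (supersampled), which sharpens agreement with continuous-geometry
        references; the default pixel-centre membership matches the pixelwise
        class maps used for training data.
        """
        eps = self.eps_eq.copy()
        if antialias:
            frac = disc_coverage(self.grid, center, radius)
            eps = eps * (1.0 - frac) + complex(eps_eq) * frac
        else:
            eps[disc_mask(self.grid, center, radius)] = complex(eps_eq)
        return PermittivityScene(self.grid, eps, self.eps_background)


@dataclass
class FieldOnGrid:
    """Complex field samples at all pixel centres for one transmitter/frequency."""

    grid: ImagingGrid
    values: np.ndarray
    role: str = "total"  # incident | total | contrast-source

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, complex)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("field shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


def disc_mask(grid: ImagingGrid, center, radius: float) -> np.ndarray:
    """Pixel-centre-membership rasterization of a disc, shape (ny, nx)."""
    pts = grid.centers().reshape(grid.ny, grid.nx, 2)
    return (pts[..., 0] - center[0]) ** 2 + (pts[..., 1] - center[1]) ** 2 <= radius**2


def disc_coverage(grid: ImagingGrid, center, radius: float, subsamples: int = 8) -> np.ndarray:
    """Fraction of each pixel covered by the disc, via subpixel supersampling."""
    off = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    x, y = grid.axes()
    xs = x[None, :, None, None] + off[None, None, :, None] * grid.dx
    ys = y[:, None, None, None] + off[None, None, None, :] * grid.dy
    inside = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2
    return inside.mean(axis=(2, 3))
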