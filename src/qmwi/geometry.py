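"""Imaging grid and multi-static measurement geometry.

Conventions used throughout the package:

* SI units (metres, Hz); the imaging domain is a square centred at the origin.
* Pixel ``(0, 0)`` sits at the bottom-left corner; 2-D arrays are indexed
  ``[iy, ix]`` and flattened row-major, so flat pixel ``p = iy * nx + ix``.
* Angles are measured counter-clockwise from the +x axis.
* Time convention ``exp(+j ω t)``: outgoing waves carry ``H0^(2)``, lossy media
  have a negative imaginary equivalent permittivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

C0 = 299_792_458.0
EPS0 = 8.854_187_8128e-12
MU0 = 1.256_637_062_12e-6


@dataclass(frozen=True)
class ImagingGrid:
    """Uniform square pixel grid covering the imaging domain Ω."""

    nx: int
    ny: int
    side_length: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 pixels per axis")
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def dx(self) -> float:
        return self.side_length / self.nx

    @property
    def dy(self) -> float:
        return self.side_length / self.ny

    @property
    def pixel_area(self) -> float:
        return self.dx * self.dy

    @property
    def cell_radius(self) -> float:
        """Radius of the equal-area disc used for cell integrals."""
        return float(np.sqrt(self.pixel_area / np.pi))

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.dx - self.side_length / 2.0
        y = (np.arange(self.ny) + 0.5) * self.dy - self.side_length / 2.0
        return x, y

    def centers(self) -> np.ndarray:
        """Pixel-centre coordinates, shape ``(n_pixels, 2)``, row-major in (iy, ix)."""
        x, y = self.axes()
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, points: np.ndarray) -> np.ndarray:
        half = self.side_length / 2.0
        pts = np.atleast_2d(points)
        return (np.abs(pts[:, 0]) <= half) & (np.abs(pts[:, 1]) <= half)


def wavenumber(frequency: float, eps_rel: complex) -> complex:
    """Background wavenumber k = ω √(μ0 ε0 εr); Im(k) ≤ 0 for lossy media."""
    k = 2.0 * np.pi * frequency / C0 * np.sqrt(complex(eps_rel))
    return complex(k)


@dataclass(frozen=True)
class MeasurementConfig:
    """Transmitter/receiver positions on the measurement curve Γ and frequencies."""

    tx_positions: np.ndarray
    rx_positions: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tx_positions", np.asarray(self.tx_positions, float))
        object.__setattr__(self, "rx_positions", np.asarray(self.rx_positions, float))
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        if self.tx_positions.ndim != 2 or self.tx_positions.shape[1] != 2:
            raise ValueError("tx_positions must have shape (Nv, 2)")
        if self.rx_positions.ndim != 2 or self.rx_positions.shape[1] != 2:
            raise ValueError("rx_positions must have shape (Nm, 2)")
        if self.n_tx < 1 or self.n_rx < 1:
            raise ValueError("need at least one transmitter and one receiver")
        f = self.frequencies
        if f.size < 1 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")

    @property
    def n_tx(self) -> int:
        return self.tx_positions.shape[0]

    @property
    def n_rx(self) -> int:
        return self.rx_positions.shape[0]

    @property
    def n_freq(self) -> int:
        return self.frequencies.size

    @property
    def tx_radius(self) -> float:
        return float(np.linalg.norm(self.tx_positions, axis=1).mean())

    @property
    def rx_radius(self) -> float:
        return float(np.linalg.norm(self.rx_positions, axis=1).mean())

    @property
    def rx_arc_weight(self) -> float:
        """Receiver arc-length quadrature weight on Γ (uniform angular sampling)."""
        return 2.0 * np.pi * self.rx_radius / self.n_rx

    @property
    def tx_arc_weight(self) -> float:
        return 2.0 * np.pi * self.tx_radius / self.n_tx

    def validate_outside(self, grid: ImagingGrid) -> None:
        pts = np.vstack([self.tx_positions, self.rx_positions])
        if np.any(grid.contains(pts)):
            raise ValueError("antenna positions must lie strictly outside Ω")


def ring_positions(
    n: int, radius: float, start_angle_deg: float = 0.0, span_deg: float = 360.0
) -> np.ndarray:
    """``n`` points on a circle; ``span_deg`` < 360 yields an open arc (endpoint included)."""
    if span_deg >= 360.0:
        ang = np.deg2rad(start_angle_deg) + 2.0 * np.pi * np.arange(n) / n
    else:
        ang = np.deg2rad(start_angle_deg + np.linspace(0.0, span_deg, n))
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def circular_config(
    n_tx: int,
    n_rx: int,
    radius: float,
    frequencies,
    tx_start_deg: float = 0.0,
    rx_start_deg: float = 0.0,
) -> MeasurementConfig:
    """Coincident Tx/Rx rings of the given radius, uniformly spaced."""
    return MeasurementConfig(
        tx_positions=ring_positions(n_tx, radius, tx_start_deg),
        rx_positions=ring_positions(n_rx, radius, rx_start_deg),
        frequencies=np.asarray(frequencies, float),
    )


def benchmark_config() -> MeasurementConfig:
    """The free-space multi-static setup used for the cylinder corpus.

    8 transmitters every 45°, 241 receivers every 1.5°, both on a 167 cm ring,
    8 frequencies from 2 to 9 GHz in 1 GHz steps.
    """
    tx = ring_positions(8, 1.67)
    ang = np.deg2rad(1.5 * np.arange(241))
    rx = 1.67 * np.column_stack([np.cos(ang), np.sin(ang)])
    return MeasurementConfig(tx, rx, np.arange(2e9, 9.5e9, 1e9))


def benchmark_grid() -> ImagingGrid:
    """64×64 pixels over the 25×25 cm imaging domain."""
    return ImagingGrid(64, 64, 0.25)
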