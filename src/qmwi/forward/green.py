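"""Outgoing 2-D Green's function and pulse-basis cell integrals.

Under the ``exp(+jωt)`` time convention the scalar outgoing Green's function of
a homogeneous background with wavenumber ``k`` is

    G(r, r') = −(j/4) · H0^(2)(k |r − r'|).

The method-of-moments discretization uses pulse (pixel) basis functions with
point matching.  Each square cell is replaced by the equal-area disc of radius
``a``; the Green's function integrated over that disc has the classical closed
forms (Richmond):

    ∫_cell G dS = −(jπa/2k) · J1(ka) · H0^(2)(k d)     observation outside the cell
    ∫_cell G dS = −(jπa/2k) · H1^(2)(ka) − 1/k²        observation at the cell centre

which keep the discretized domain operator a convolution plus a diagonal.
"""

from __future__ import annotations

import numpy as np
from scipy.special import hankel2, jv

from ..geometry import ImagingGrid


def background_green(k: complex, r, r_prime) -> complex:
    """Point-to-point Green's function −(j/4)·H0^(2)(k|r−r'|).

    Raises for coincident points; the cell self-term is handled separately by
    :func:`cell_self_integral`.
    """
    d = np.linalg.norm(np.asarray(r, float) - np.asarray(r_prime, float))
    if d == 0.0:
        raise ValueError("Green's function is singular at coincident points")
    return complex(-0.25j * hankel2(0, k * d))


def green_matrix(k: complex, points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Pairwise −(j/4)H0^(2)(k d) between two point sets, shape (Na, Nb)."""
    d = np.linalg.norm(points_a[:, None, :] - points_b[None, :, :], axis=-1)
    if np.any(d == 0.0):
        raise ValueError("coincident points in green_matrix")
    return -0.25j * hankel2(0, k * d)


def cell_coupling(k: complex, cell_radius: float, distance) -> np.ndarray:
    """Green's function integrated over an equal-area disc cell, observed outside."""
    a = cell_radius
    return -0.5j * np.pi * a / k * jv(1, k * a) * hankel2(0, k * np.asarray(distance))


def cell_self_integral(k: complex, cell_radius: float) -> complex:
    """Green's function integrated over the cell that contains the observation point."""
    a = cell_radius
    return complex(-0.5j * np.pi * a / k * hankel2(1, k * a) - 1.0 / k**2)


def domain_kernel(grid: ImagingGrid, k: complex) -> np.ndarray:
    """Cell-integrated Green's kernel over all pixel offsets, shape (ny, nx).

    Entry ``[dy, dx]`` is ∫_cell G for an observation point ``(dx·Δx, dy·Δy)``
    away from the source cell centre; the zero offset holds the self-term.
    """
    x = np.arange(grid.nx) * grid.dx
    y = np.arange(grid.ny) * grid.dy
    d = np.hypot(x[None, :], y[:, None])
    kern = np.empty((grid.ny, grid.nx), complex)
    kern[0, 0] = cell_self_integral(k, grid.cell_radius)
    mask = d > 0
    kern[mask] = cell_coupling(k, grid.cell_radius, d[mask])
    return kern


def radiation_matrix(k: complex, points: np.ndarray, grid: ImagingGrid) -> np.ndarray:
    """k²·∫_cell G from every pixel to every external point, shape (Npts, Np).

    Applied to a contrast source vector it evaluates the data equation at the
    given (receiver) points.
    """
    d = np.linalg.norm(points[:, None, :] - grid.centers()[None, :, :], axis=-1)
    return k**2 * cell_coupling(k, grid.cell_radius, d)
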