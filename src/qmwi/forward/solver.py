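"""Method-of-moments forward scattering solver with CG-FFT acceleration.

The total field obeys the discretized state (domain) equation

    E = Einc + k_b² · Gd[τ · E]

where ``Gd`` is the domain Green's operator.  On a uniform grid ``Gd`` is a
block-Toeplitz convolution applied with FFTs (plus the diagonal self-term baked
into the kernel), so one operator application costs two 2-D FFTs.  The linear
system ``(I − k_b² Gd τ)E = Einc`` is solved per transmitter and frequency with
BiCGSTAB.  Receivers are handled by the data equation

    Es(rm) = k_b² Σ_p ∫_cell G(rm, ·) τ_p E_p.

A dense assembly of the same discretization is provided for cross-checks on
small grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, bicgstab

from ..geometry import ImagingGrid, MeasurementConfig, wavenumber
from ..scene import FieldOnGrid, PermittivityScene
from .green import domain_kernel, green_matrix, radiation_matrix

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


class SolverError(RuntimeError):
    """Raised when the iterative solver fails to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class _FrequencyOperator:
    """Cached per-(grid, k) machinery: padded kernel spectrum and shapes."""

    grid: ImagingGrid
    k: complex

    def __post_init__(self) -> None:
        ny, nx = self.grid.ny, self.grid.nx
        kern = np.zeros((2 * ny, 2 * nx), complex)
        base = domain_kernel(self.grid, self.k)
        # circulant embedding of the symmetric Toeplitz kernel
        kern[:ny, :nx] = base
        kern[:ny, nx + 1 :] = base[:, :0:-1]
        kern[ny + 1 :, :nx] = base[:0:-1, :]
        kern[ny + 1 :, nx + 1 :] = base[:0:-1, :0:-1]
        self._spectrum = np.fft.fft2(kern)

    def apply_green(self, w: np.ndarray) -> np.ndarray:
        """Domain Green's operator Gd applied to a (ny, nx) source map."""
        ny, nx = self.grid.ny, self.grid.nx
        pad = np.zeros((2 * ny, 2 * nx), complex)
        pad[:ny, :nx] = w
        out = np.fft.ifft2(np.fft.fft2(pad) * self._spectrum)
        return out[:ny, :nx]

    def state_matvec(self, tau: np.ndarray):
        ny, nx = self.grid.ny, self.grid.nx
        k2 = self.k**2

        def mv(e_flat: np.ndarray) -> np.ndarray:
            e = e_flat.reshape(ny, nx)
            return (e - k2 * self.apply_green(tau * e)).ravel()

        return mv


def incident_field(
    config: MeasurementConfig,
    tx_index: int,
    f_index: int,
    grid: ImagingGrid,
    eps_background: complex = 1.0 + 0.0j,
) -> FieldOnGrid:
    """Unit-amplitude line source field −(j/4)H0^(2)(k_b|r−rt|) at all pixel centres."""
    k = wavenumber(config.frequencies[f_index], eps_background)
    src = config.tx_positions[tx_index][None, :]
    vals = green_matrix(k, src, grid.centers())[0].reshape(grid.ny, grid.nx)
    return FieldOnGrid(grid=grid, values=vals, role="incident")


def solve_total_field(
    scene: PermittivityScene,
    config: MeasurementConfig,
    tx_index: int,
    f_index: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FieldOnGrid:
    """Total field E on the grid for one transmitter and one frequency."""
    op = _FrequencyOperator(scene.grid, wavenumber(config.frequencies[f_index], scene.eps_background))
    einc = incident_field(config, tx_index, f_index, scene.grid, scene.eps_background)
    e = _solve_state(op, scene.contrast, einc.values, tol, max_iter)
    return FieldOnGrid(grid=scene.grid, values=e, role="total")


def _solve_state(
    op: _FrequencyOperator,
    tau: np.ndarray,
    einc: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    if not np.all(np.isfinite(tau)):
        raise ValueError("scene contrast contains non-finite values")
    if not np.any(tau):
        return einc.copy()
    ny, nx = einc.shape
    mv = op.state_matvec(tau)
    A = LinearOperator((ny * nx, ny * nx), matvec=mv, dtype=complex)
    b = einc.ravel()
    x, info = bicgstab(A, b, x0=b.copy(), rtol=tol, atol=0.0, maxiter=max_iter)
    res = np.linalg.norm(mv(x) - b) / np.linalg.norm(b)
    if info != 0 or not np.isfinite(res) or res > 10 * tol:
        # one retry with GMRES before giving up; some high-contrast scenes
        # stall BiCGSTAB without being genuinely hard
        from scipy.sparse.linalg import gmres

        x, info = gmres(A, b, x0=b.copy(), rtol=tol, atol=0.0, maxiter=max_iter, restart=50)
        res = np.linalg.norm(mv(x) - b) / np.linalg.norm(b)
        if info != 0 or not np.isfinite(res) or res > 10 * tol:
            raise SolverError(
                f"forward solver did not converge (relative residual {res:.3e})",
                residual=float(res),
            )
    return x.reshape(ny, nx)


def scattered_field(
    scene: PermittivityScene,
    config: MeasurementConfig,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    dispersive_scenes: list[PermittivityScene] | None = None,
) -> np.ndarray:
    """Scattered field at all receivers, shape (Nm, Nv, Nf).

    ``dispersive_scenes`` overrides ``scene`` per frequency (index-aligned with
    ``config.frequencies``) for media whose permittivity varies with frequency.
    """
    out = np.zeros((config.n_rx, config.n_tx, config.n_freq), complex)
    for fi, f in enumerate(config.frequencies):
        sc = dispersive_scenes[fi] if dispersive_scenes is not None else scene
        k = wavenumber(f, sc.eps_background)
        tau = sc.contrast
        if not np.any(tau):
            continue
        op = _FrequencyOperator(sc.grid, k)
        rad = radiation_matrix(k, config.rx_positions, sc.grid)
        for ti in range(config.n_tx):
            einc = incident_field(config, ti, fi, sc.grid, sc.eps_background)
            e = _solve_state(op, tau, einc.values, tol, max_iter)
            w = (tau * e).ravel()
            out[:, ti, fi] = rad @ w
    return out


def dense_state_matrix(scene: PermittivityScene, k: complex) -> np.ndarray:
    """Explicit (Np × Np) matrix of the state equation, for small-grid cross-checks."""
    grid = scene.grid
    kern = domain_kernel(grid, k)
    iy, ix = np.divmod(np.arange(grid.n_pixels), grid.nx)
    g = kern[np.abs(iy[:, None] - iy[None, :]), np.abs(ix[:, None] - ix[None, :])]
    tau = scene.contrast.ravel()
    return np.eye(grid.n_pixels, dtype=complex) - k**2 * g * tau[None, :]


def solve_total_field_dense(
    scene: PermittivityScene,
    config: MeasurementConfig,
    tx_index: int,
    f_index: int,
) -> FieldOnGrid:
    """Direct dense factorization of the same discretized system (small grids)."""
    k = wavenumber(config.frequencies[f_index], scene.eps_background)
    einc = incident_field(config, tx_index, f_index, scene.grid, scene.eps_background)
    e = np.linalg.solve(dense_state_matrix(scene, k), einc.values.ravel())
    return FieldOnGrid(grid=scene.grid, values=e.reshape(scene.grid.ny, scene.grid.nx), role="total")
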