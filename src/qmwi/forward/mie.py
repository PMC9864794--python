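"""Eigenfunction (Bessel/Hankel) series for a homogeneous circular cylinder.

Classical TM solution for a line source illuminating a homogeneous dielectric
cylinder in a homogeneous background, used as the independent oracle for the
method-of-moments solver.  With the ``exp(+jωt)`` convention the incident field
of a unit line source at ``rt`` expands about the cylinder centre as

    Einc(r) = −(j/4) Σ_n J_n(k_b ρ) H_n^(2)(k_b ρ_t) e^{jn(φ−φ_t)},   ρ < ρ_t,

and enforcing continuity of E and ∂E/∂ρ at the cylinder surface ρ = a gives the
exterior scattering coefficients

    a_n = [k_c J_n'(k_c a) J_n(k_b a) − k_b J_n'(k_b a) J_n(k_c a)]
          / [k_b H_n^(2)'(k_b a) J_n(k_c a) − k_c J_n'(k_c a) H_n^(2)(k_b a)]

and interior coefficients ``b_n`` from the continuity of E.  The series order is
grown adaptively until the relative tail contribution drops below 1e−10.
"""

from __future__ import annotations

import numpy as np
from scipy.special import h2vp, hankel2, jv, jvp

from ..geometry import ImagingGrid, MeasurementConfig, wavenumber


class SeriesError(RuntimeError):
    pass


def _coefficients(kb: complex, kc: complex, radius: float, orders: np.ndarray):
    beta = kb * radius
    gamma = kc * radius
    num = kc * jvp(orders, gamma) * jv(orders, beta) - kb * jvp(orders, beta) * jv(orders, gamma)
    den = kb * h2vp(orders, beta) * jv(orders, gamma) - kc * jvp(orders, gamma) * hankel2(orders, beta)
    a_n = num / den
    b_n = (jv(orders, beta) + a_n * hankel2(orders, beta)) / jv(orders, gamma)
    return a_n, b_n


def _adaptive_order(kb: complex, kc: complex, radius: float, rho_ref: float) -> int:
    """Grow the truncation until the last order's relative weight is < 1e-10."""
    n = max(8, int(np.ceil(abs(kb) * radius)) + 8)
    for _ in range(12):
        orders = np.arange(n + 1)
        a_n, _ = _coefficients(kb, kc, radius, orders)
        w = np.abs(a_n * hankel2(orders, kb * rho_ref) ** 2)
        total = w.sum()
        if total == 0.0:
            return n
        if w[-1] / total < 1e-10 and np.all(np.isfinite(w)):
            return n
        n = int(np.ceil(n * 1.6))
    raise SeriesError("cylinder series did not converge; check parameters")


def cylinder_scattered_field(
    radius: float,
    eps_cyl: complex,
    eps_background: complex,
    frequency: float,
    config: MeasurementConfig,
    center=(0.0, 0.0),
    truncation: int | None = None,
) -> np.ndarray:
    """Scattered field at all receivers for all transmitters, shape (Nm, Nv)."""
    kb = wavenumber(frequency, eps_background)
    kc = wavenumber(frequency, eps_cyl)
    if eps_cyl == eps_background:
        return np.zeros((config.n_rx, config.n_tx), complex)

    c = np.asarray(center, float)
    tx = config.tx_positions - c
    rx = config.rx_positions - c
    rho_t, phi_t = np.hypot(*tx.T), np.arctan2(tx[:, 1], tx[:, 0])
    rho_r, phi_r = np.hypot(*rx.T), np.arctan2(rx[:, 1], rx[:, 0])
    if np.any(rho_t <= radius) or np.any(rho_r <= radius):
        raise SeriesError("antennas must lie outside the cylinder")

    n_max = truncation if truncation is not None else _adaptive_order(kb, kc, radius, float(rho_t.min()))
    orders = np.arange(n_max + 1)
    a_n, _ = _coefficients(kb, kc, radius, orders)

    h_r = hankel2(orders[None, :], kb * rho_r[:, None])          # (Nm, N)
    h_t = hankel2(orders[None, :], kb * rho_t[:, None])          # (Nv, N)
    dphi = phi_r[:, None] - phi_t[None, :]                        # (Nm, Nv)
    # n and −n terms coincide (a_{-n} = a_n), so fold them into a cosine sum
    weight = np.where(orders == 0, 1.0, 2.0)
    angular = np.cos(orders[None, None, :] * dphi[:, :, None])    # (Nm, Nv, N)
    terms = (weight * a_n)[None, None, :] * h_r[:, None, :] * h_t[None, :, :] * angular
    return -0.25j * terms.sum(axis=2)


def cylinder_total_field(
    radius: float,
    eps_cyl: complex,
    eps_background: complex,
    frequency: float,
    config: MeasurementConfig,
    tx_index: int,
    grid: ImagingGrid,
    center=(0.0, 0.0),
    truncation: int | None = None,
) -> np.ndarray:
    """Total field on the imaging grid for one transmitter, shape (ny, nx)."""
    kb = wavenumber(frequency, eps_background)
    kc = wavenumber(frequency, eps_cyl)
    c = np.asarray(center, float)
    t = config.tx_positions[tx_index] - c
    rho_t, phi_t = float(np.hypot(*t)), float(np.arctan2(t[1], t[0]))

    pts = grid.centers() - c
    rho, phi = np.hypot(*pts.T), np.arctan2(pts[:, 1], pts[:, 0])

    n_max = truncation if truncation is not None else _adaptive_order(kb, kc, radius, rho_t)
    orders = np.arange(n_max + 1)
    a_n, b_n = _coefficients(kb, kc, radius, orders)
    weight = np.where(orders == 0, 1.0, 2.0)
    h_t = hankel2(orders, kb * rho_t)
    angular = np.cos(orders[None, :] * (phi[:, None] - phi_t))

    inside = rho <= radius
    field = np.empty(grid.n_pixels, complex)

    j_in = jv(orders[None, :], kc * rho[inside, None])
    field[inside] = -0.25j * (weight * b_n * h_t * j_in * angular[inside]).sum(axis=1)

    out = ~inside
    j_out = jv(orders[None, :], kb * rho[out, None])
    h_out = hankel2(orders[None, :], kb * rho[out, None])
    total = (j_out + a_n[None, :] * h_out) * (weight * h_t)[None, :] * angular[out]
    field[out] = -0.25j * total.sum(axis=1)
    return field.reshape(grid.ny, grid.nx)
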