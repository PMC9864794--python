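"""Orthogonality sampling method (OSM) imaging.

The OSM localizes scatterers without solving the inverse problem: for each
sampling point ``rp`` the measured scattered field is projected onto the
background Green's function anchored at that point (the *reduced field*)

    Ered(rp, rt) = ⟨Es(rm, rt), G(rm, rp)⟩_Γ = Σ_m Es(m, t) · conj(G(m, p)) · Δs,

and the indicator is its transmitter-summed energy

    I(rp) = ‖Ered(rp, ·)‖²_Γ = Σ_t |Ered(p, t)|² · Δt.

For a weak scatterer the reduced field is proportional to the Bessel-smoothed
contrast source, ``Ered(rp, rt) ≈ β ∫ J0(k|r'−rp|) W(r', rt) dr'``, which makes
the indicator a shape image whose spatial distribution also encodes contrast.

For inhomogeneous-but-known backgrounds (e.g. a healthy head in a matching
medium) the analytic Green's function is replaced by a numerically computed
table, and stroke imaging operates on differential data (stroke minus
baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward.green import green_matrix
from .forward.solver import _FrequencyOperator, _solve_state
from .geometry import ImagingGrid, MeasurementConfig, wavenumber
from .scene import PermittivityScene


@dataclass
class BackgroundGreenTable:
    """Green's function from every receiver to every pixel at one frequency."""

    values: np.ndarray  # (Nm, Np)
    grid: ImagingGrid
    frequency: float
    provenance: str = "analytic-homogeneous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, complex)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_pixels:
            raise ValueError("green table shape must be (Nm, Np)")


@dataclass
class ReducedFieldMap:
    """Reduced field Ered indexed (pixel, transmitter) for one frequency."""

    values: np.ndarray  # (Np, Nv)
    grid: ImagingGrid
    frequency: float


@dataclass
class IndicatorStack:
    """Per-frequency OSM indicator images, the network input.

    ``values`` has shape (Np, Nf); slices are non-negative and, once
    :func:`normalize_stack` has run, min-max mapped to [0, 1] per frequency.
    """

    values: np.ndarray
    grid: ImagingGrid
    frequencies: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.frequencies = np.asarray(self.frequencies, float)
        if self.values.shape != (self.grid.n_pixels, self.frequencies.size):
            raise ValueError("indicator stack must have shape (Np, Nf)")
        if np.any(self.values < 0):
            raise ValueError("indicator values must be non-negative")

    def images(self) -> np.ndarray:
        """Stack reshaped to (Nf, ny, nx) for image-style consumers."""
        return self.values.T.reshape(self.frequencies.size, self.grid.ny, self.grid.nx)


def analytic_green_table(
    config: MeasurementConfig,
    grid: ImagingGrid,
    f_index: int,
    eps_background: complex = 1.0 + 0.0j,
) -> BackgroundGreenTable:
    """Homogeneous-background table G(m, p) = −(j/4)H0^(2)(k_b |rm − rp|)."""
    f = float(config.frequencies[f_index])
    k = wavenumber(f, eps_background)
    vals = green_matrix(k, config.rx_positions, grid.centers())
    return BackgroundGreenTable(vals, grid, f, "analytic-homogeneous")


def numerical_green_table(
    background_scene: PermittivityScene,
    config: MeasurementConfig,
    f_index: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> BackgroundGreenTable:
    """Green's table of a known inhomogeneous background.

    Column ``G(m, ·)`` is the total field of a unit line source placed at
    receiver ``m`` propagating through the background scene (by reciprocity it
    equals the field at ``m`` due to a pixel source).  For a homogeneous
    background this reduces to the analytic table up to discretization error.
    Cost: one forward solve per receiver.
    """
    f = float(config.frequencies[f_index])
    k = wavenumber(f, background_scene.eps_background)
    grid = background_scene.grid
    tau = background_scene.contrast
    op = _FrequencyOperator(grid, k)
    src_green = green_matrix(k, config.rx_positions, grid.centers())  # incident fields
    vals = np.empty((config.n_rx, grid.n_pixels), complex)
    for m in range(config.n_rx):
        einc = src_green[m].reshape(grid.ny, grid.nx)
        vals[m] = _solve_state(op, tau, einc, tol, max_iter).ravel()
    return BackgroundGreenTable(vals, grid, f, "numerical-inhomogeneous")


def reduced_field(
    es: np.ndarray,
    green_table: BackgroundGreenTable,
    config: MeasurementConfig,
    f_index: int,
    green_norm: bool = False,
) -> ReducedFieldMap:
    """Project scattered data onto Green's functions: Ered(p, t), shape (Np, Nv).

    The scalar product on Γ is conjugate-linear in the Green's-function
    argument and carries the receiver arc-length weight Δs.

    ``green_norm=True`` divides each pixel's projection by ‖G(·, p)‖²_Γ,
    i.e. projects onto unit-energy test functions.  In a homogeneous lossless
    background ‖G(·, p)‖ is nearly constant over Ω and the option is a global
    rescale; in a lossy background (head in matching medium) it is essential —
    without it the exponential depth decay of |G| makes the indicator peak at
    the pixels nearest the receivers instead of at the target.
    """
    es = np.asarray(es)
    if es.shape[0] != green_table.values.shape[0]:
        raise ValueError(
            f"receiver count mismatch: data has {es.shape[0]}, "
            f"table has {green_table.values.shape[0]}"
        )
    data = es[:, :, f_index] if es.ndim == 3 else es
    vals = green_table.values.conj().T @ data * config.rx_arc_weight
    if green_norm:
        energy = (np.abs(green_table.values) ** 2).sum(axis=0) * config.rx_arc_weight
        vals = vals / energy[:, None]
    return ReducedFieldMap(vals, green_table.grid, green_table.frequency)


def indicator(ered: ReducedFieldMap, config: MeasurementConfig) -> np.ndarray:
    """OSM indicator I(p) = Σ_t |Ered(p, t)|² Δt for one frequency, shape (Np,)."""
    return (np.abs(ered.values) ** 2).sum(axis=1) * config.tx_arc_weight


def normalize_stack(stack: IndicatorStack) -> IndicatorStack:
    """Independent [0, 1] min-max normalization of each frequency slice.

    Constant slices (no spread) map to all-zeros rather than dividing by zero;
    a constant indicator carries no spatial information.  Idempotent.
    """
    vals = stack.values.copy()
    lo = vals.min(axis=0, keepdims=True)
    hi = vals.max(axis=0, keepdims=True)
    span = hi - lo
    flat = span[0] == 0
    span[:, flat] = 1.0
    vals = (vals - lo) / span
    vals[:, flat] = 0.0
    return IndicatorStack(vals, stack.grid, stack.frequencies, normalized=True)


def differential_data(es_total: np.ndarray, es_baseline: np.ndarray) -> np.ndarray:
    """Elementwise difference isolating a perturbation from a known baseline."""
    es_total = np.asarray(es_total)
    es_baseline = np.asarray(es_baseline)
    if es_total.shape != es_baseline.shape:
        raise ValueError("differential data requires identically shaped arrays")
    return es_total - es_baseline


def compute_indicator_stack(
    es: np.ndarray,
    green_tables: list[BackgroundGreenTable],
    config: MeasurementConfig,
    normalize: bool = True,
    green_norm: bool = False,
) -> IndicatorStack:
    """Full OSM pre-processing: reduced field → indicator per frequency → stack.

    ``es`` has shape (Nm, Nv, Nf) and ``green_tables`` one table per frequency.
    The result is the canonical (Np, Nf) network input, normalized by default.
    ``green_norm`` selects unit-energy Green's test functions (used by the
    lossy-background stroke pipeline; see :func:`reduced_field`).
    """
    if len(green_tables) != config.n_freq:
        raise ValueError("need one Green table per frequency")
    grid = green_tables[0].grid
    vals = np.empty((grid.n_pixels, config.n_freq))
    for fi in range(config.n_freq):
        ered = reduced_field(es, green_tables[fi], config, fi, green_norm=green_norm)
        vals[:, fi] = indicator(ered, config)
    stack = IndicatorStack(vals, grid, config.frequencies)
    return normalize_stack(stack) if normalize else stack
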