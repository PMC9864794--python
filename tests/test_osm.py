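"""OSM properties: linearity, localization, Bessel-kernel proportionality."""

import numpy as np
import pytest
from scipy.special import j0

from qmwi import ImagingGrid, PermittivityScene, circular_config, wavenumber
from qmwi.forward import background_green, scattered_field, solve_total_field
from qmwi.osm import (
    IndicatorStack,
    analytic_green_table,
    compute_indicator_stack,
    differential_data,
    indicator,
    normalize_stack,
    numerical_green_table,
    reduced_field,
)


@pytest.fixture(scope="module")
def geometry():
    grid = ImagingGrid(32, 32, 0.25)
    config = circular_config(4, 32, 1.67, [3e9])
    return grid, config


def test_zero_data_gives_zero_indicator(geometry):
    grid, config = geometry
    table = analytic_green_table(config, grid, 0)
    es = np.zeros((config.n_rx, config.n_tx, 1), complex)
    ered = reduced_field(es, table, config, 0)
    np.testing.assert_array_equal(ered.values, 0.0)
    np.testing.assert_array_equal(indicator(ered, config), 0.0)


def test_linearity_and_scale_equivariance(geometry):
    grid, config = geometry
    table = analytic_green_table(config, grid, 0)
    rng = np.random.default_rng(0)
    es = rng.normal(size=(config.n_rx, config.n_tx, 1)) + 1j * rng.normal(
        size=(config.n_rx, config.n_tx, 1)
    )
    c = 1.7 - 0.4j
    e1 = reduced_field(es, table, config, 0)
    e2 = reduced_field(c * es, table, config, 0)
    np.testing.assert_allclose(e2.values, c * e1.values, rtol=1e-12)
    np.testing.assert_allclose(
        indicator(e2, config), abs(c) ** 2 * indicator(e1, config), rtol=1e-12
    )


def test_receiver_count_mismatch_raises(geometry):
    grid, config = geometry
    table = analytic_green_table(config, grid, 0)
    with pytest.raises(ValueError):
        reduced_field(np.zeros((5, config.n_tx, 1), complex), table, config, 0)


def test_point_scatterer_localization():
    """Argmax of the indicator lands within one pixel of a small scatterer."""
    grid = ImagingGrid(64, 64, 0.25)
    config = circular_config(8, 64, 1.67, [4e9, 6e9, 8e9])
    center = (0.047, -0.031)
    scene = PermittivityScene.homogeneous(grid).with_disc(center, 0.006, 3.0)
    es = scattered_field(scene, config, tol=1e-8)
    tables = [analytic_green_table(config, grid, fi) for fi in range(3)]
    stack = compute_indicator_stack(es, tables, config)
    x, y = grid.axes()
    for fi in range(3):
        img = stack.images()[fi]
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(x[ix] - center[0]) <= grid.dx and abs(y[iy] - center[1]) <= grid.dy


def test_cylinder_top_decile_centroid_inside_target():
    """Centroid of the brightest decile falls inside the true cylinder (≥4 GHz)."""
    grid = ImagingGrid(64, 64, 0.25)
    config = circular_config(8, 64, 1.67, [4e9, 5e9, 6e9, 7e9, 8e9, 9e9])
    center, radius = (-0.04, 0.025), 0.02
    scene = PermittivityScene.homogeneous(grid).with_disc(center, radius, 2.0)
    es = scattered_field(scene, config, tol=1e-6)
    tables = [analytic_green_table(config, grid, fi) for fi in range(config.n_freq)]
    stack = compute_indicator_stack(es, tables, config)
    pts = grid.centers()
    for fi in range(config.n_freq):
        vals = stack.values[:, fi]
        top = vals >= np.quantile(vals, 0.9)
        centroid = (pts[top] * vals[top, None]).sum(axis=0) / vals[top].sum()
        assert np.hypot(centroid[0] - center[0], centroid[1] - center[1]) < radius


def test_reduced_field_proportional_to_bessel_smoothed_source(geometry):
    """Weak scatterer: Ered ≈ β ∫ J0(k|r'−rp|) W dr' after a single-β fit."""
    grid, config = geometry
    scene = PermittivityScene.homogeneous(grid).with_disc((0.02, 0.01), 0.025, 1.05)
    tau = scene.contrast
    k = wavenumber(3e9, 1.0)
    es = scattered_field(scene, config, tol=1e-10)
    table = analytic_green_table(config, grid, 0)
    ered = reduced_field(es, table, config, 0).values  # (Np, Nv)

    pts = grid.centers()
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    kernel = j0(k.real * d) * grid.pixel_area  # (Np, Np)
    w = np.stack(
        [
            (tau * solve_total_field(scene, config, v, 0, tol=1e-10).values).ravel()
            for v in range(config.n_tx)
        ],
        axis=1,
    )  # (Np, Nv)
    quad = kernel @ w
    beta = np.vdot(quad, ered) / np.vdot(quad, quad)
    residual = np.linalg.norm(ered - beta * quad) / np.linalg.norm(ered)
    assert residual < 0.10


def test_normalization_affine_idempotent_and_degenerate(geometry):
    grid, config = geometry
    vals = np.column_stack(
        [np.linspace(2.0, 6.0, grid.n_pixels), np.full(grid.n_pixels, 3.3)]
    )
    stack = IndicatorStack(vals, grid, [2e9, 3e9])
    normed = normalize_stack(stack)
    assert normed.normalized
    np.testing.assert_allclose(normed.values[:, 0], (vals[:, 0] - 2.0) / 4.0)
    np.testing.assert_array_equal(normed.values[:, 1], 0.0)  # constant slice
    again = normalize_stack(normed)
    np.testing.assert_allclose(again.values, normed.values)


def test_differential_data_rules():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(8, 4, 2)) + 1j * rng.normal(size=(8, 4, 2))
    np.testing.assert_array_equal(differential_data(a, a), 0.0)
    np.testing.assert_array_equal(differential_data(a, np.zeros_like(a)), a)
    with pytest.raises(ValueError):
        differential_data(a, a[:, :2])


def test_numerical_green_table_matches_analytic_for_homogeneous():
    grid = ImagingGrid(24, 24, 0.25)
    config = circular_config(4, 8, 1.0, [2e9])
    background = PermittivityScene.homogeneous(grid)
    num = numerical_green_table(background, config, 0)
    ana = analytic_green_table(config, grid, 0)
    rel = np.linalg.norm(num.values - ana.values) / np.linalg.norm(ana.values)
    assert rel < 0.02
    assert num.provenance == "numerical-inhomogeneous"


def test_numerical_green_table_reciprocity():
    """Field at B from a source at A equals field at A from a source at B,
    both evaluated through the inhomogeneous background machinery."""
    from qmwi.forward.green import radiation_matrix
    from qmwi.forward.solver import _FrequencyOperator, _solve_state, incident_field

    grid = ImagingGrid(24, 24, 0.25)
    config = circular_config(2, 2, 1.0, [2e9])  # two external points, 180° apart
    scene = PermittivityScene.homogeneous(grid).with_disc((0.02, 0.03), 0.05, 2.0)
    k = wavenumber(2e9, 1.0)
    op = _FrequencyOperator(grid, k)
    tau = scene.contrast
    rad = radiation_matrix(k, config.rx_positions, grid)

    def field_at(src_idx, obs_idx):
        einc = incident_field(config, src_idx, 0, grid).values
        e = _solve_state(op, tau, einc, 1e-11, 2000)
        scat = rad[obs_idx] @ (tau * e).ravel()
        direct = background_green(k, config.rx_positions[obs_idx], config.tx_positions[src_idx])
        return scat + direct

    assert field_at(0, 1) == pytest.approx(field_at(1, 0), rel=1e-8)


def test_lossy_background_green_decays_faster():
    from qmwi.scene import equivalent_permittivity

    f = 1e9
    k_lossless = wavenumber(f, 23.0)
    k_lossy = wavenumber(f, equivalent_permittivity(23.0, 0.19, f))
    d1, d2 = 0.05, 0.20
    ratio_ll = abs(background_green(k_lossless, [0, 0], [d2, 0])) / abs(
        background_green(k_lossless, [0, 0], [d1, 0])
    )
    ratio_lo = abs(background_green(k_lossy, [0, 0], [d2, 0])) / abs(
        background_green(k_lossy, [0, 0], [d1, 0])
    )
    assert ratio_lo < ratio_ll


def test_stack_shapes_zero_data_and_receiver_permutation(geometry):
    grid, _ = geometry
    config = circular_config(4, 16, 1.67, [2e9, 3e9, 4e9, 5e9, 6e9, 7e9, 8e9, 9e9])
    tables = [analytic_green_table(config, grid, fi) for fi in range(8)]
    es = np.zeros((16, 4, 8), complex)
    stack = compute_indicator_stack(es, tables, config)
    assert stack.values.shape == (grid.n_pixels, 8)
    np.testing.assert_array_equal(stack.values, 0.0)

    rng = np.random.default_rng(2)
    es = rng.normal(size=(16, 4, 8)) + 1j * rng.normal(size=(16, 4, 8))
    stack1 = compute_indicator_stack(es, tables, config)
    perm = rng.permutation(16)
    tables_p = [
        type(t)(t.values[perm], t.grid, t.frequency, t.provenance) for t in tables
    ]
    stack2 = compute_indicator_stack(es[perm], tables_p, config)
    np.testing.assert_allclose(stack2.values, stack1.values, atol=1e-12)
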