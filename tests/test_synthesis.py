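"""Scene generators: containment, binning, tissue dispersion, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmwi import ImagingGrid
from qmwi.geometry import EPS0
from qmwi.synth import (
    SEVEN_CLASS_BINNING,
    TISSUES,
    ClassBinning,
    build_brain_dataset,
    build_cylinder_dataset,
    cole_cole_eps,
    dataset_content_hash,
    easy_corpus_setup,
    sample_cylinder_scene,
    sample_head_phantom,
    segment_ground_truth,
    tissue_contrast,
)
from qmwi.synth.cylinders import EPS_RANGE, RADIUS_RANGE
from qmwi.synth.head import STROKE_RADIUS_RANGE, _brain_axes, _tissue_masks, brain_config
from qmwi.synth.tissues import ColeColeTissue, matching_medium_eps


@pytest.fixture(scope="module")
def grid64():
    return ImagingGrid(64, 64, 0.25)


# ---------------------------------------------------------------- cylinders


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_cylinder_scene_respects_invariants(seed):
    grid = ImagingGrid(64, 64, 0.25)
    scene, spec = sample_cylinder_scene(seed, grid)
    assert len(spec.cylinders) == 2
    half = grid.side_length / 2
    for c in spec.cylinders:
        assert RADIUS_RANGE[0] <= c.radius <= RADIUS_RANGE[1]
        assert EPS_RANGE[0] <= c.eps <= EPS_RANGE[1]
        # full containment in Ω
        assert abs(c.center[0]) + c.radius <= half
        assert abs(c.center[1]) + c.radius <= half
    # every target pixel classifiable, lossless scene
    labels = segment_ground_truth(scene, SEVEN_CLASS_BINNING)
    assert labels.min() >= 0 and labels.max() < SEVEN_CLASS_BINNING.n_classes


def test_cylinder_scene_deterministic(grid64):
    s1, sp1 = sample_cylinder_scene(123, grid64)
    s2, sp2 = sample_cylinder_scene(123, grid64)
    np.testing.assert_array_equal(s1.eps_eq, s2.eps_eq)
    assert sp1 == sp2


def test_min_separation_enforced(grid64):
    for seed in range(10):
        _, spec = sample_cylinder_scene(seed, grid64, min_separation=0.02)
        (a, b) = spec.cylinders
        d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
        assert d >= a.radius + b.radius + 0.02


def test_all_seven_classes_appear_across_corpus(grid64):
    seen = set()
    for seed in range(60):
        scene, _ = sample_cylinder_scene(seed, grid64)
        seen |= set(np.unique(segment_ground_truth(scene, SEVEN_CLASS_BINNING)))
        if len(seen) == 7:
            break
    assert seen == set(range(7))


# ---------------------------------------------------------------- binning


def test_binning_boundary_mapping_is_exact():
    b = SEVEN_CLASS_BINNING
    assert b.n_classes == 7
    assert b.classify(np.array([0.0]))[0] == 0
    assert b.classify(np.array([0.6]))[0] == 1  # upper edge inclusive
    assert b.classify(np.array([2.4]))[0] == 6
    assert b.classify(np.array([2.5]))[0] == 6
    assert b.classify(np.array([0.61]))[0] == 2
    with pytest.raises(ValueError, match="outside the admissible"):
        b.classify(np.array([2.6]))
    with pytest.raises(ValueError):
        b.classify(np.array([-0.1]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(tau=st.floats(min_value=0.0, max_value=2.5, allow_nan=False))
def test_every_admissible_contrast_maps_to_exactly_one_class(tau):
    b = SEVEN_CLASS_BINNING
    label = int(b.classify(np.array([tau]))[0])
    # reference: explicit interval walk
    if tau == 0.0:
        expected = 0
    else:
        expected = next(
            i for i in range(1, b.n_classes) if b.edges[i - 1] < tau <= b.edges[i]
        )
    assert label == expected


def test_binning_validation():
    with pytest.raises(ValueError):
        ClassBinning((0.1, 0.5))  # must start at zero
    with pytest.raises(ValueError):
        ClassBinning((0.0, 0.5, 0.5))  # strictly increasing


# ---------------------------------------------------------------- tissues


def test_dispersion_free_limit_is_real_constant():
    t = ColeColeTissue("toy", 5.0, (0, 0, 0, 0), (1e-12,) * 4, (0.0,) * 4, 0.0)
    assert cole_cole_eps(t, 1e9) == pytest.approx(5.0)


def test_static_conductivity_dominates_low_frequency():
    t = ColeColeTissue("toy", 5.0, (0, 0, 0, 0), (1e-12,) * 4, (0.0,) * 4, 1.0)
    im1 = -cole_cole_eps(t, 1e6).imag
    im2 = -cole_cole_eps(t, 1e7).imag
    assert im1 / im2 == pytest.approx(10.0, rel=1e-6)


@pytest.mark.parametrize("name", sorted(TISSUES))
@pytest.mark.parametrize("f", [0.5e9, 0.75e9, 1.0e9, 1.25e9])
def test_tissues_physical_in_band(name, f):
    eps = cole_cole_eps(TISSUES[name], f)
    assert eps.real >= 1.0
    assert eps.imag <= 0.0


def test_cole_cole_against_direct_formula():
    """Independent evaluation of the dispersion law for blood at 1 GHz."""
    t = TISSUES["blood"]
    w = 2 * np.pi * 1e9
    expected = t.eps_inf + sum(
        d / (1 + (1j * w * tau) ** (1 - a))
        for d, tau, a in zip(t.delta_eps, t.tau, t.alpha)
    ) + t.sigma_s / (1j * w * EPS0)
    assert cole_cole_eps(t, 1e9) == pytest.approx(expected)
    # sanity on magnitudes: high-water-content tissue
    assert 55 < expected.real < 70


def test_stroke_contrast_amplitudes_at_1ghz():
    """Mean contrast amplitudes of the two stroke tissues vs matching medium.

    The ischemic surrogate is constructed to land at ≈0.96; hemorrhagic tissue
    (blood, literature constants) evaluates to ≈1.96 under τ = εeq/εb − 1.
    """
    assert abs(tissue_contrast(TISSUES["ischemic-surrogate"], 1e9)) == pytest.approx(
        0.956, abs=0.01
    )
    assert abs(tissue_contrast(TISSUES["blood"], 1e9)) == pytest.approx(1.959, abs=0.01)
    assert matching_medium_eps(1e9) == pytest.approx(23.0 - 3.416j, abs=0.01)


def test_nonphysical_tissue_rejected():
    with pytest.raises(ValueError):
        ColeColeTissue("bad", 0.5, (0, 0, 0, 0), (1e-12,) * 4, (0.0,) * 4, 0.0)
    with pytest.raises(ValueError):
        ColeColeTissue("bad", 4.0, (1, 0, 0, 0), (1e-12,) * 4, (1.2, 0, 0, 0), 0.0)
    with pytest.raises(ValueError):
        cole_cole_eps(TISSUES["blood"], 0.0)


# ---------------------------------------------------------------- head phantom


@pytest.mark.parametrize("seed,kind", [(0, "ischemic"), (5, "hemorrhagic"), (11, "ischemic")])
def test_head_phantom_invariants(seed, kind):
    grid = ImagingGrid(32, 32, 0.24)
    freqs = brain_config().frequencies
    sample = sample_head_phantom(seed, grid, kind, freqs)
    spec = sample.spec
    assert STROKE_RADIUS_RANGE[0] <= spec.stroke.radius <= STROKE_RADIUS_RANGE[1]
    for v in spec.perturbations.values():
        assert 0.9 <= v <= 1.1
    # stroke pixels lie inside the brain region
    masks = _tissue_masks(grid, spec)
    brain = masks["grey-matter"] | masks["white-matter"]
    stroke_px = sample.labels > 0
    assert stroke_px.any()
    assert not (stroke_px & ~brain).any()
    # exactly two classes: background + requested kind
    expected = {0, 1} if kind == "ischemic" else {0, 2}
    assert set(np.unique(sample.labels)) == expected
    # geometric containment of the disc in the brain ellipse
    ba, bb = _brain_axes(spec)
    cx, cy = spec.stroke.center
    r = spec.stroke.radius
    assert (cx / (ba - r)) ** 2 + (cy / (bb - r)) ** 2 <= 1.0
    assert len(sample.stroke_scenes) == len(freqs)
    # healthy and stroke scenes differ only within the stroke disc
    for hs, ss in zip(sample.healthy_scenes, sample.stroke_scenes):
        diff = hs.eps_eq != ss.eps_eq
        assert diff.any() and not (diff & ~stroke_px).any()


def test_head_phantom_deterministic():
    grid = ImagingGrid(32, 32, 0.24)
    freqs = brain_config().frequencies
    a = sample_head_phantom(3, grid, "hemorrhagic", freqs)
    b = sample_head_phantom(3, grid, "hemorrhagic", freqs)
    assert a.spec == b.spec
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.stroke_scenes[0].eps_eq, b.stroke_scenes[0].eps_eq)


def test_unknown_stroke_kind_rejected():
    with pytest.raises(ValueError):
        sample_head_phantom(0, ImagingGrid(16, 16, 0.24), "embolic", [1e9])


# ---------------------------------------------------------------- datasets


def test_cylinder_dataset_shapes_and_determinism():
    grid, cfg, setup = easy_corpus_setup()
    ds = build_cylinder_dataset(4, 99, grid, cfg, setup)
    assert len(ds) == 4
    assert ds.inputs().shape == (4, 4, 32, 32)
    assert ds.targets().shape == (4, 32, 32)
    assert ds.targets().max() < setup.binning.n_classes
    for p in ds.pairs:
        assert p.indicators.normalized
        assert p.indicators.values.min() >= 0.0 and p.indicators.values.max() <= 1.0
    ds2 = build_cylinder_dataset(4, 99, grid, cfg, setup)
    assert dataset_content_hash(ds) == dataset_content_hash(ds2)


def test_brain_dataset_differential_and_classes():
    from qmwi.geometry import circular_config

    grid = ImagingGrid(24, 24, 0.24)
    cfg = circular_config(8, 8, 0.25, [0.75e9, 1.0e9])
    ds = build_brain_dataset(2, 13, grid=grid, config=cfg)
    assert len(ds) == 2
    kinds = [p.provenance["stroke"]["kind"] for p in ds.pairs]
    assert kinds == ["ischemic", "hemorrhagic"]
    for p, expected in zip(ds.pairs, [{0, 1}, {0, 2}]):
        assert set(np.unique(p.labels)) == expected
        assert p.indicators.values.shape == (grid.n_pixels, 2)
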