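"""Segmentation network: backprop exactness, determinism, training oracle."""

import numpy as np
import pytest

from qmwi.nn import (
    NetworkSpec,
    TrainingConfig,
    build_network,
    cross_entropy_with_softmax,
    make_folds,
    predict,
    run_cross_validation,
    train,
)


@pytest.fixture()
def tiny_spec():
    return NetworkSpec(input_channels=2, output_classes=3, image_side=8,
                       depth=2, base_channels=3)


def test_indivisible_image_side_rejected():
    with pytest.raises(ValueError):
        NetworkSpec(2, 3, 30, depth=2)


def test_presets():
    p = NetworkSpec.paper(8, 7)
    assert (p.depth, p.base_channels, p.image_side) == (4, 64, 64)
    r = NetworkSpec.reduced(4, 4)
    assert (r.depth, r.base_channels) == (2, 8)


def test_same_seed_identical_parameters(tiny_spec):
    a = build_network(tiny_spec, seed=42)
    b = build_network(tiny_spec, seed=42)
    for pa, pb in zip(a.parameters, b.parameters):
        np.testing.assert_array_equal(pa, pb)
    c = build_network(tiny_spec, seed=43)
    assert any((pa != pc).any() for pa, pc in zip(a.parameters, c.parameters))


def test_forward_zeros_finite_softmax_normalized(tiny_spec):
    net = build_network(tiny_spec, seed=0)
    probs = net.predict_proba(np.zeros((1, 2, 8, 8), np.float32))
    assert probs.shape == (1, 3, 8, 8)
    assert np.all(np.isfinite(probs))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_channel_mismatch_rejected(tiny_spec):
    net = build_network(tiny_spec, seed=0)
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 5, 8, 8), np.float32))


def test_backprop_matches_directional_derivative(tiny_spec):
    """Finite-difference oracle: ∇L·v equals (L(θ+εv) − L(θ−εv)) / 2ε."""
    net = build_network(tiny_spec, seed=1)
    for layer in net._layers():
        layer.params[:] = [p.astype(np.float64) for p in layer.params]
        layer.grads[:] = [np.zeros_like(p) for p in layer.params]
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 2, 8, 8))
    t = rng.integers(0, 3, size=(2, 8, 8))

    net.zero_grad()
    loss, dl = cross_entropy_with_softmax(net.forward(x), t)
    net.backward(dl)
    grads = [g.copy() for g in net.gradients]
    params = net.parameters

    vs = [rng.normal(size=p.shape) for p in params]
    eps = 1e-5
    saved = [p.copy() for p in params]
    for p, v in zip(params, vs):
        p += eps * v
    lp, _ = cross_entropy_with_softmax(net.forward(x), t)
    for p, s, v in zip(params, saved, vs):
        p[...] = s - eps * v
    lm, _ = cross_entropy_with_softmax(net.forward(x), t)
    numeric = (lp - lm) / (2 * eps)
    analytic = sum(float((g * v).sum()) for g, v in zip(grads, vs))
    assert numeric == pytest.approx(analytic, rel=1e-6)


def test_training_history_bookkeeping(tiny_spec):
    net = build_network(tiny_spec, seed=0)
    rng = np.random.default_rng(1)
    x = rng.random((6, 2, 8, 8)).astype(np.float32)
    t = rng.integers(0, 3, size=(6, 8, 8))
    cfg = TrainingConfig(learning_rate=1e-3, batch_size=4, epochs=3,
                         validation_fraction=0.34, seed=0)
    hist = train(net, x, t, cfg)
    assert len(hist.train_loss) == 3
    assert len(hist.val_loss) == 3
    assert all(np.isfinite(hist.train_loss))


def test_default_training_config_echoes_published_recipe():
    cfg = TrainingConfig()
    assert cfg.learning_rate == pytest.approx(1e-4)
    assert cfg.batch_size == 16
    assert cfg.epochs == 200
    assert cfg.optimizer == "adam"
    assert cfg.loss == "categorical-cross-entropy"


def test_overfit_singleton_drives_loss_to_zero():
    """Training-loop correctness oracle: one sample is memorized."""
    net = build_network(NetworkSpec(2, 3, 8, depth=2, base_channels=8), seed=0)
    rng = np.random.default_rng(2)
    x = rng.random((1, 2, 8, 8)).astype(np.float32)
    t = np.zeros((1, 8, 8), np.int64)
    t[0, 2:6, 2:6] = 1
    hist = train(net, x, t, TrainingConfig(learning_rate=3e-3, batch_size=1,
                                           epochs=150, validation_fraction=0.0, seed=0))
    assert hist.train_loss[-1] < 0.01
    seg = predict(net, x[0])
    np.testing.assert_array_equal(seg.labels, t[0])


def test_predict_argmax_and_probability_consistency(tiny_spec):
    net = build_network(tiny_spec, seed=3)
    x = np.random.default_rng(4).random((2, 8, 8)).astype(np.float32)
    seg = predict(net, x)
    assert seg.labels.shape == (8, 8)
    np.testing.assert_allclose(seg.probabilities.sum(axis=0), 1.0, atol=1e-5)
    np.testing.assert_array_equal(seg.labels, seg.probabilities.argmax(axis=0))


def test_train_input_validation(tiny_spec):
    net = build_network(tiny_spec, seed=0)
    with pytest.raises(ValueError):
        train(net, np.zeros((0, 2, 8, 8)), np.zeros((0, 8, 8), int))
    with pytest.raises(ValueError):
        train(net, np.zeros((2, 2, 8, 8)), np.zeros((3, 8, 8), int))
    with pytest.raises(ValueError):  # label beyond class count
        train(net, np.zeros((1, 2, 8, 8)), np.full((1, 8, 8), 9))


def test_make_folds_partition_properties():
    plan = make_folds(7000, 10, seed=0)
    sizes = [len(te) for _, te in plan.folds]
    assert sizes == [700] * 10
    allte = sorted(i for _, te in plan.folds for i in te)
    assert allte == list(range(7000))
    for tr, te in plan.folds:
        assert not set(tr) & set(te)
        assert sorted(set(tr) | set(te)) == list(range(7000))
    assert make_folds(7000, 10, seed=0) == plan
    assert make_folds(7000, 10, seed=1) != plan
    with pytest.raises(ValueError):
        make_folds(5, 10, seed=0)
    with pytest.raises(ValueError):
        make_folds(10, 1, seed=0)


def test_cross_validation_covers_every_sample_once(tiny_spec):
    rng = np.random.default_rng(5)
    x = rng.random((10, 2, 8, 8)).astype(np.float32)
    t = rng.integers(0, 3, size=(10, 8, 8))
    cfg = TrainingConfig(learning_rate=1e-3, batch_size=4, epochs=1,
                         validation_fraction=0.0, seed=0)
    res = run_cross_validation(x, t, tiny_spec, cfg, n_folds=2, seed=0)
    assert len(res.models) == 2
    assert sorted(res.predictions) == list(range(10))
    res2 = run_cross_validation(x, t, tiny_spec, cfg, n_folds=2, seed=0)
    assert res2.plan == res.plan
    for i in res.predictions:
        np.testing.assert_array_equal(res2.predictions[i].labels, res.predictions[i].labels)


def test_checkpoint_roundtrip(tmp_path, tiny_spec):
    from qmwi.nn import UNet

    net = build_network(tiny_spec, seed=6)
    x = np.random.default_rng(7).random((1, 2, 8, 8)).astype(np.float32)
    ref = net.forward(x)
    path = tmp_path / "model.npz"
    net.save(path)
    loaded = UNet.load(path)
    np.testing.assert_array_equal(loaded.forward(x), ref)
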