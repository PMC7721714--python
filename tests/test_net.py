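import numpy as np
import pytest

from morphoseg.net.autodiff import Tape
from morphoseg.net.model import (DMapNet, NetworkConfig, TrainSettings,
                                 _loss_node, build_network, interclass_weight,
                                 predict_distance_map, softmax, tiny_config,
                                 train, weighted_cross_entropy)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_default_config_shape_arithmetic():
    cfg = NetworkConfig()
    assert cfg.input_depth == 24
    assert cfg.boundary_exclude == 4          # 4 per side = 8 slices excluded
    assert cfg.output_depth == 16
    assert cfg.n_classes == 17


def test_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(input_depth=8, boundary_exclude=4)
    with pytest.raises(ValueError):
        NetworkConfig(tile_hw=100, levels=3)
    with pytest.raises(ValueError):
        NetworkConfig(K=1)
    assert NetworkConfig(binary=True).n_classes == 2


def test_tiny_forward_shape_and_normalization():
    cfg = tiny_config()
    net = build_network(cfg)
    x = np.random.default_rng(0).normal(size=(1, 1, 16, 64, 64))
    probs = net.predict_probabilities(x)
    assert probs.shape == (1, 12, 64, 64, 17)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0)
    assert (probs >= 0).all()


def test_forward_rejects_bad_input():
    net = build_network(tiny_config())
    with pytest.raises(ValueError):
        net.forward(Tape(), np.zeros((16, 64, 64)))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_interclass_weight_examples():
    assert interclass_weight(5, 5, 16) == 1.0
    np.testing.assert_allclose(interclass_weight(15, 1, 16), np.exp(14 / 16))
    assert interclass_weight(15, 1, 16) > interclass_weight(2, 1, 16)
    # symmetric in |k - truth|
    assert interclass_weight(3, 7, 16) == interclass_weight(7, 3, 16)
    with pytest.raises(ValueError):
        interclass_weight(17, 0, 16)


def test_weighted_cross_entropy_uniform_closed_form():
    n = 17
    P = np.full((1, n), 1.0 / n)
    target = np.array([3])
    got = weighted_cross_entropy(P, target)
    # hand-expanded sum over classes at the single voxel
    expected = 0.0
    for k in range(n):
        omega = np.exp(abs(k - 3) / (n - 1))
        if k == 3:
            expected -= omega * np.log(1.0 / n)
        else:
            expected -= omega * np.log(1.0 - 1.0 / n)
    np.testing.assert_allclose(got, expected)


def test_weighted_cross_entropy_far_miss_costs_more():
    # equal max-class probability mass, error at |dk|=14 vs |dk|=1
    n = 17

    def pred(wrong_class):
        P = np.full((1, n), 1e-4)
        P[0, wrong_class] = 1.0 - 1e-4 * (n - 1)
        return P

    target = np.array([1])
    far = weighted_cross_entropy(pred(15), target)
    near = weighted_cross_entropy(pred(2), target)
    assert far > near


def test_weighted_cross_entropy_onehot_is_minimum():
    n = 5
    target = np.array([2])
    eps = 1e-6
    P0 = np.full((1, n), eps)
    P0[0, 2] = 1 - eps * (n - 1)
    base = weighted_cross_entropy(P0, target)
    rng = np.random.default_rng(0)
    for _ in range(10):
        d = rng.normal(size=n) * 1e-3
        d -= d.mean()
        P = np.clip(P0 + d, 1e-9, 1 - 1e-9)
        P /= P.sum()
        assert weighted_cross_entropy(P, target) >= base


def test_loss_strictly_decreasing_in_true_class_probability():
    n = 9
    target = np.array([4])
    losses = []
    for p_true in np.linspace(0.1, 0.9, 9):
        P = np.full((1, n), (1 - p_true) / (n - 1))
        P[0, 4] = p_true
        losses.append(weighted_cross_entropy(P, target))
    assert (np.diff(losses) < 0).all()


def test_weighted_cross_entropy_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        weighted_cross_entropy(np.array([[1.5, -0.5]]), np.array([0]))


def test_loss_node_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    logits = rng.normal(size=(1, 5, 2, 3, 3))
    target = rng.integers(0, 5, size=(1, 2, 3, 3))
    xi = np.linspace(0.5, 1.5, 5)
    tape = Tape()
    node = tape.node(logits.copy())
    loss = _loss_node(tape, node, target, xi)
    tape.backward(loss)
    grad = node.grad

    def f(z):
        t2 = Tape()
        return float(_loss_node(t2, t2.node(z), target, xi).value)

    eps = 1e-6
    for idx in [(0, 0, 0, 0, 0), (0, 3, 1, 2, 2), (0, 4, 0, 1, 1)]:
        zp = logits.copy()
        zp[idx] += eps
        zm = logits.copy()
        zm[idx] -= eps
        fd = (f(zp) - f(zm)) / (2 * eps)
        np.testing.assert_allclose(grad[idx], fd, rtol=1e-5, atol=1e-8)


def test_softmax_normalizes():
    z = np.random.default_rng(0).normal(size=(2, 7, 3))
    p = softmax(z, axis=1)
    np.testing.assert_allclose(p.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _toy_data(cfg, n_volumes=2, seed=0):
    rng = np.random.default_rng(seed)
    shape = (cfg.input_depth, cfg.tile_hw, cfg.tile_hw)
    data = []
    for _ in range(n_volumes):
        img = rng.normal(size=shape)
        tgt = rng.integers(0, cfg.K + 1, size=shape)
        data.append((img, tgt))
    return data


def test_train_zero_epochs_is_identity():
    cfg = tiny_config()
    net = build_network(cfg)
    before = [p.value.copy() for p in net.params()]
    net2, trace = train(net, _toy_data(cfg), TrainSettings(epochs=0))
    assert trace == []
    for b, p in zip(before, net2.params()):
        np.testing.assert_array_equal(b, p.value)


def test_train_rejects_small_volume():
    cfg = tiny_config()
    net = build_network(cfg)
    bad = [(np.zeros((4, 8, 8)), np.zeros((4, 8, 8), dtype=int))]
    with pytest.raises(ValueError):
        train(net, bad)
    with pytest.raises(ValueError):
        train(net, [])


def test_train_is_deterministic():
    cfg = tiny_config()
    data = _toy_data(cfg)
    _, trace1 = train(build_network(cfg), data, TrainSettings(epochs=2, seed=3))
    _, trace2 = train(build_network(cfg), data, TrainSettings(epochs=2, seed=3))
    assert trace1 == trace2


def test_predict_single_tile_matches_forward():
    cfg = tiny_config()
    net = build_network(cfg)
    rng = np.random.default_rng(0)
    stack = rng.normal(size=(cfg.output_depth, cfg.tile_hw, cfg.tile_hw))
    psi = predict_distance_map(net, stack)
    assert psi.shape == stack.shape
    assert psi.min() >= 0 and psi.max() <= cfg.K


def test_predict_rejects_small_stack():
    net = build_network(tiny_config())
    with pytest.raises(ValueError):
        predict_distance_map(net, np.zeros((4, 8, 8)))


def test_save_load_roundtrip(tmp_path):
    cfg = tiny_config(seed=7)
    net = build_network(cfg)
    path = tmp_path / "model.npz"
    net.save(path)
    loaded = DMapNet.load(path)
    assert loaded.config == cfg
    for a, b in zip(net.params(), loaded.params()):
        np.testing.assert_array_equal(a.value, b.value)
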