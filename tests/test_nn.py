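"""The NumPy learning backend: gradients, determinism, training behavior."""

import numpy as np
import pytest

from larvadet.exceptions import ConfigurationError
from larvadet.nn import Conv2D, Dense, Dropout, Flatten, MaxPool2D, Sequential


def _bce_from_logits(model, X, y):
    model.forward(X)
    z = model.layers[-1].z.ravel().astype(np.float64)
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def _analytic_grads(model, X, y):
    p = model.forward(X).ravel()
    delta = ((p - y) / len(y)).astype(np.float64).reshape(-1, 1)
    g = delta
    for li in range(len(model.layers) - 1, -1, -1):
        g = model.layers[li].backward(g, pre=(li == len(model.layers) - 1))


@pytest.mark.parametrize(
    "layers,input_shape",
    [
        (
            [
                Conv2D(4, activation="relu", pool=2),
                Conv2D(6, activation="relu", pool=2),
                Flatten(),
                Dense(8, activation="relu"),
                Dense(1, activation="sigmoid"),
            ],
            (14, 14, 2),
        ),
        (
            [
                Conv2D(3, activation="relu"),
                MaxPool2D(2),
                Flatten(),
                Dense(5, activation="relu"),
                Dense(1, activation="sigmoid"),
            ],
            (9, 9, 1),
        ),
        ([Flatten(), Dense(7), Dense(1, activation="sigmoid")], (3, 3, 1)),
    ],
    ids=["fused-conv-pool", "standalone-pool", "dense-only"],
)
def test_backprop_matches_finite_differences(layers, input_shape):
    """Analytic gradients agree with float64 central differences."""
    rng = np.random.default_rng(0)
    model = Sequential(layers).build(input_shape, seed=1, dtype=np.float64)
    X = rng.standard_normal((5,) + input_shape)
    y = rng.integers(0, 2, 5).astype(np.float64)
    _analytic_grads(model, X, y)
    eps = 1e-6
    for lyr in model.layers:
        for P, G in lyr.params_and_grads():
            flat, gflat = P.ravel(), G.ravel()
            for i in rng.choice(flat.size, size=min(20, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = _bce_from_logits(model, X, y)
                flat[i] = orig - eps
                lm = _bce_from_logits(model, X, y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                err = abs(num - gflat[i]) / max(1e-6, abs(num), abs(gflat[i]))
                assert err < 1e-4


def test_separable_toy_reaches_perfect_training_accuracy():
    """Two constant-image classes are learned to accuracy 1.0."""
    X = np.full((20, 6, 6, 1), -1.0, np.float32)
    y = np.arange(20) % 2
    X[y == 1] = 1.0
    model = Sequential(
        [Conv2D(2, activation="relu", pool=2), Flatten(), Dense(1, activation="sigmoid")]
    ).build((6, 6, 1), seed=0)
    h = model.fit(X, y, epochs=20, batch_size=4, lr=1e-2, seed=0)
    assert h["train_acc"][-1] == 1.0
    assert not h["diverged"]


def test_fit_is_deterministic_for_fixed_seed():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((16, 6, 6, 1)).astype(np.float32)
    y = rng.integers(0, 2, 16)
    results = []
    for _ in range(2):
        m = Sequential(
            [Conv2D(2, activation="relu", pool=2), Flatten(), Dropout(0.3),
             Dense(1, activation="sigmoid")]
        ).build((6, 6, 1), seed=3)
        h = m.fit(X, y, epochs=5, batch_size=4, lr=1e-3, seed=9)
        results.append((h["train_loss"], m.layers[-1].W.copy()))
    assert results[0][0] == results[1][0]
    np.testing.assert_array_equal(results[0][1], results[1][1])


def test_high_learning_rate_flagged_unstable():
    """An aggressive Adam step oscillates without settling where a small
    one descends smoothly, and only the former is flagged."""
    import pandas as pd

    from larvadet.classifier import training_unstable

    X = np.tile(np.array([[100.0]], np.float32), (16, 1))
    y = np.arange(16) % 2  # conflicting labels: optimum is p = 0.5
    hist = {}
    for lr in (0.1, 1e-4):
        m = Sequential([Dense(1, activation="sigmoid")]).build((1,), seed=1)
        h = m.fit(X, y, epochs=15, batch_size=4, lr=lr, seed=0)
        hist[lr] = pd.DataFrame({"train_loss": h["train_loss"]})
    assert training_unstable(hist[0.1])
    assert not training_unstable(hist[1e-4])


def test_stable_run_not_flagged():
    import pandas as pd

    from larvadet.classifier import training_unstable

    h = pd.DataFrame({"train_loss": [0.9, 0.5, 0.3, 0.2, 0.15]})
    assert not training_unstable(h)
    assert training_unstable(pd.DataFrame({"train_loss": [0.5, 0.4, 5.0, 0.3]}))
    assert training_unstable(pd.DataFrame({"train_loss": [0.5, float("nan")]}))


def test_optimizers_available_and_unknown_rejected():
    from larvadet.nn import get_optimizer

    for name in ("adam", "sgd", "rmsprop", "Adam"):
        assert get_optimizer(name, 1e-3).lr == 1e-3
    with pytest.raises(ConfigurationError):
        get_optimizer("adagrad", 1e-3)


def test_adam_fused_and_fallback_agree():
    """The numba path and the numpy path compute the same update."""
    from larvadet.nn.optim import _HAVE_NUMBA, Adam

    rng = np.random.default_rng(0)
    p1 = rng.standard_normal(8000).astype(np.float32)  # above the fused cutoff
    p2 = p1.copy()
    g = rng.standard_normal(8000).astype(np.float32)
    a1, a2 = Adam(1e-3), Adam(1e-3)
    a1.step([(p1, g)])
    # force the numpy fallback by making the second array non-contiguous
    buf = np.empty((8000, 2), np.float32)
    pv = buf[:, 0]
    pv[:] = p2
    a2.step([(pv, g)])
    if _HAVE_NUMBA:
        np.testing.assert_allclose(p1, pv, rtol=1e-5, atol=1e-7)


def test_dropout_identity_at_eval(rng):
    d = Dropout(0.5)
    d.build((10,), rng=np.random.default_rng(0))
    x = rng.standard_normal((4, 10)).astype(np.float32)
    np.testing.assert_array_equal(d.forward(x, training=False), x)
    out = d.forward(x, training=True)
    assert (out == 0).any()


def test_divergence_recorded_not_raised():
    X = np.full((8, 4), 1e3, np.float32)
    y = np.arange(8) % 2
    m = Sequential([Dense(4, activation="relu"),
                    Dense(1, activation="sigmoid")]).build((4,), seed=0)
    h = m.fit(X, y, epochs=10, batch_size=4, lr=1e6, seed=0)
    assert h["diverged"] or np.isfinite(h["train_loss"]).all()
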