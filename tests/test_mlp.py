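"""MLP forward pass, LM training and hidden-size selection."""

import numpy as np
import pytest

from fertopt.mlp import (
    MLP,
    _residual_jacobian,
    mean_squared_error,
    select_hidden_size,
    train_lm,
)
from fertopt.preprocessing import kfold_split


def brute_force_forward(model, x):
    """Loop evaluation of yhat = b2 + sum_j w2_j * tanh(sum_i W1_ji x_i + b1_j)."""
    total = model.b2
    for j in range(model.hidden_size):
        a = model.b1[j]
        for i in range(model.W1.shape[1]):
            a += model.W1[j, i] * x[i]
        total += model.w2[j] * np.tanh(a)
    return total


def test_zero_network_outputs_bias():
    m = MLP(W1=np.zeros((2, 3)), b1=np.zeros(2), w2=np.zeros(2), b2=0.0)
    assert m.predict(np.array([1.0, 2.0, 3.0])) == 0.0
    m.b2 = 4.5
    assert m.predict(np.array([1.0, 2.0, 3.0])) == 4.5


def test_forward_hand_value():
    # one hidden unit wired to the first input only: yhat = tanh(0.5)
    m = MLP(
        W1=np.array([[1.0, 0.0, 0.0]]), b1=np.zeros(1), w2=np.array([1.0]), b2=0.0
    )
    assert m.predict(np.array([0.5, 0.0, 0.0])) == pytest.approx(
        np.tanh(0.5), abs=1e-12
    )


def test_forward_matches_brute_force():
    rng = np.random.default_rng(2)
    m = MLP(
        W1=rng.normal(size=(4, 3)),
        b1=rng.normal(size=4),
        w2=rng.normal(size=4),
        b2=float(rng.normal()),
    )
    for x in rng.normal(size=(20, 3)):
        assert m.predict(x) == pytest.approx(brute_force_forward(m, x), abs=1e-12)


def test_hidden_contribution_bounded():
    rng = np.random.default_rng(3)
    m = MLP(
        W1=rng.normal(size=(3, 3)) * 10,
        b1=rng.normal(size=3),
        w2=np.array([2.0, -3.0, 0.5]),
        b2=0.0,
    )
    preds = m.predict(rng.normal(size=(50, 3)))
    assert np.all(np.abs(preds) <= np.abs(m.w2).sum() + 1e-12)


def test_mean_squared_error_values():
    assert mean_squared_error([1, 2], [1, 2]) == 0.0
    assert mean_squared_error([1, 2], [1, 0]) == pytest.approx(2.0)
    # scaling residuals by c scales the error by c^2
    y = np.array([1.0, 2.0, 3.0])
    p = np.array([0.5, 2.5, 2.0])
    assert mean_squared_error(y, y + 3 * (p - y)) == pytest.approx(
        9 * mean_squared_error(y, p)
    )
    with pytest.raises(ValueError):
        mean_squared_error([], [])


def test_analytic_jacobian_matches_finite_differences():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(15, 3))
    y = rng.normal(size=15)
    p = 3
    theta = rng.uniform(-0.5, 0.5, size=p * 3 + 2 * p + 1)
    r, J = _residual_jacobian(theta, X, y, p)
    h = 1e-6
    for k in range(theta.size):
        e = np.zeros_like(theta)
        e[k] = h
        rp, _ = _residual_jacobian(theta + e, X, y, p)
        rm, _ = _residual_jacobian(theta - e, X, y, p)
        fd = (rp - rm) / (2 * h)
        denom = max(np.abs(fd).max(), 1e-8)
        assert np.abs(J[:, k] - fd).max() / denom < 1e-4


def test_accepted_sse_sequence_non_increasing():
    rng = np.random.default_rng(5)
    X = rng.random((40, 3))
    y = np.sin(X @ [3.0, 1.0, 2.0])
    m = train_lm(X, y, p=3, seed=1, max_iter=200)
    path = np.array(m.training_log["sse_path"])
    assert np.all(np.diff(path) <= 1e-12)


def test_self_recovery_of_generating_network():
    rng = np.random.default_rng(6)
    X = rng.uniform(-1, 1, size=(60, 3))
    teacher = MLP(
        W1=rng.normal(size=(2, 3)),
        b1=rng.normal(size=2),
        w2=rng.normal(size=2),
        b2=0.3,
    )
    y = teacher.predict(X)
    best = min(
        (train_lm(X, y, p=2, seed=s, max_iter=500) for s in (0, 1, 2)),
        key=lambda m: m.training_log["final_sse"],
    )
    rmse = np.sqrt(mean_squared_error(y, best.predict(X)))
    assert rmse < 1e-3 * y.std()


def test_training_reproducible():
    rng = np.random.default_rng(7)
    X, y = rng.random((30, 3)), rng.random(30)
    a = train_lm(X, y, p=2, seed=9, max_iter=100)
    b = train_lm(X, y, p=2, seed=9, max_iter=100)
    np.testing.assert_array_equal(a.W1, b.W1)
    np.testing.assert_array_equal(a.w2, b.w2)
    assert a.b2 == b.b2


def test_small_network_fits_linear_map():
    # first-order tanh expansion: 1 hidden unit approximates y = 2x + 1
    x = np.linspace(0, 0.1, 30)[:, None]
    y = 2 * x.ravel() + 1
    m = train_lm(x, y, p=1, seed=0, max_iter=500)
    pred = m.predict(x)
    ss_res = ((y - pred) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert 1 - ss_res / ss_tot > 0.999


def test_warns_when_data_too_small_for_width():
    rng = np.random.default_rng(8)
    with pytest.warns(UserWarning, match="rows"):
        train_lm(rng.random((10, 3)), rng.random(10), p=4, seed=0, max_iter=5)


def test_select_hidden_size_singleton_and_determinism():
    rng = np.random.default_rng(9)
    X = rng.random((40, 3))
    y = X @ [1.0, -2.0, 0.5] + rng.normal(scale=0.05, size=40)
    folds = kfold_split(40, 5, seed=3)
    p, profile = select_hidden_size(X, y, candidates=[4], folds=folds, restarts=2,
                                    max_iter=60)
    assert p == 4 and len(profile) == 1
    p1, prof1 = select_hidden_size(X, y, candidates=[1, 3], folds=folds,
                                   restarts=2, max_iter=60)
    p2, prof2 = select_hidden_size(X, y, candidates=[1, 3], folds=folds,
                                   restarts=2, max_iter=60)
    assert p1 == p2
    assert prof1.equals(prof2)


def test_select_hidden_size_prefers_small_on_linear_truth():
    rng = np.random.default_rng(10)
    X = rng.random((50, 3))
    y = X @ [2.0, 1.0, -1.0] + rng.normal(scale=0.3, size=50)
    folds = kfold_split(50, 5, seed=4)
    p, profile = select_hidden_size(
        X, y, candidates=[1, 2, 10], folds=folds, restarts=3, max_iter=100
    )
    prof = dict(zip(profile.p, profile.median_cv_rmse))
    assert prof[p] <= prof[10]
    assert p <= 2
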