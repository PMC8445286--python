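import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpclasso.datasets import generate_regression
from mpclasso.lasso import (
    DivergenceError,
    GDConfig,
    UndefinedRSquaredError,
    calc_gradient,
    evaluate,
    initial_step_size,
    objective,
    proxy,
    proxy_via_bits,
    r_squared,
    train_plaintext,
    update_difference,
)


def _well_conditioned_instance(n=100, m=5, seed=0):
    """Orthonormal-column design, sparse truth, noiseless target."""
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(n, m)))
    w = rng.normal(size=m)
    w[rng.choice(m, m // 2, replace=False)] = 0.0
    return Q, Q @ w, w


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def test_objective_at_zero_weights():
    rng = np.random.default_rng(1)
    X, y = rng.random((7, 3)), rng.random(7)
    assert objective(X, y, np.zeros(3), 0.5) == pytest.approx(float(y @ y) / 7)


def test_objective_reduces_to_ols_loss_at_zero_lambda():
    rng = np.random.default_rng(2)
    X, y, w = rng.random((6, 2)), rng.random(6), rng.normal(size=2)
    r = X @ w - y
    assert objective(X, y, w, 0.0) == pytest.approx(float(r @ r) / 6)


def test_objective_matches_direct_recomputation():
    rng = np.random.default_rng(3)
    X, y, w = rng.random((9, 4)), rng.random(9), rng.normal(size=4)
    lam = 0.03
    direct = sum((X[i] @ w - y[i]) ** 2 for i in range(9)) / 9 + lam * sum(abs(v) for v in w)
    assert objective(X, y, w, lam) == pytest.approx(direct)


def test_gradient_zero_at_interpolating_weights():
    rng = np.random.default_rng(4)
    X = rng.random((5, 5)) + np.eye(5)
    w = rng.normal(size=5)
    y = X @ w
    assert np.allclose(calc_gradient(X, y, w), 0.0, atol=1e-12)


def test_gradient_at_zero_weights():
    rng = np.random.default_rng(5)
    X, y = rng.random((8, 3)), rng.random(8)
    assert np.allclose(calc_gradient(X, y, np.zeros(3)), -2.0 / 8 * X.T @ y)


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(6)
    X, y, w = rng.random((10, 4)), rng.random(10), rng.normal(size=4)
    g = calc_gradient(X, y, w)
    eps = 1e-7
    for i in range(4):
        e = np.zeros(4)
        e[i] = eps
        fd = (objective(X, y, w + e, 0.0) - objective(X, y, w - e, 0.0)) / (2 * eps)
        assert abs(g[i] - fd) < 1e-6


def test_proxy_worked_example():
    assert proxy(np.array([0.5, 0.05, -0.5]), 0.1) == pytest.approx([0.4, 0.0, -0.4])


def test_proxy_identity_at_zero_lambda():
    w = np.array([0.3, -0.7, 0.0])
    assert proxy(w, 0.0) == pytest.approx(list(w))


def test_proxy_rejects_negative_lambda():
    with pytest.raises(ValueError):
        proxy(np.array([1.0]), -0.1)
    with pytest.raises(ValueError):
        proxy_via_bits(np.array([1.0]), -0.1)


def test_proxy_bit_form_boundaries():
    lam = 0.2
    assert proxy_via_bits(np.array([lam]), lam) == pytest.approx([0.0])
    assert proxy_via_bits(np.array([2 * lam]), lam) == pytest.approx([lam])
    assert proxy_via_bits(np.array([-lam]), lam) == pytest.approx([0.0])


def test_proxy_equals_bit_form_on_dense_grid():
    grid = np.linspace(-1.0, 1.0, 2001)
    for lam in (0.0, 0.01, 0.1):
        assert np.array_equal(proxy(grid, lam), proxy_via_bits(grid, lam))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=8),
    st.floats(0, 1, allow_nan=False),
)
def test_property_proxy_equivalence(ws, lam):
    w = np.asarray(ws)
    assert np.array_equal(proxy(w, lam), proxy_via_bits(w, lam))


def test_update_difference_cases():
    w = np.array([1.0, 2.0])
    assert update_difference(w, w) == 0.0
    assert update_difference(w, np.zeros(2)) == math.inf
    w2 = np.array([1.5, 1.0])
    direct = float((w2 - w) @ (w2 - w)) / float(w @ w)
    assert update_difference(w2, w) == pytest.approx(direct)
    with pytest.raises(ValueError):
        update_difference(np.zeros(2), np.zeros(3))


def test_initial_step_size_worked_examples():
    assert initial_step_size(np.eye(4)) == pytest.approx(0.1)
    assert initial_step_size(2 * np.eye(4)) == pytest.approx(0.025)
    rng = np.random.default_rng(7)
    X = rng.random((6, 3))
    brute = max((X.T @ X)[i, j] for i in range(3) for j in range(3))
    assert initial_step_size(X) == pytest.approx(0.1 / brute)
    with pytest.raises(ValueError):
        initial_step_size(np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_parameter_recovery_noiseless_sparse():
    """With lam -> 0 and ISTA scaling the sparse truth is recovered."""
    X, y, w_star = _well_conditioned_instance(seed=3)
    L = 2.0 / X.shape[0] * np.linalg.eigvalsh(X.T @ X).max()
    cfg = GDConfig(lam=1e-6, tolerance=1e-14, max_iter=500, ista_scaling=True,
                   step_rule="constant", eta0=1.0 / L)
    model = train_plaintext(X, y, cfg)
    assert np.abs(model.weights - w_star).max() < 1e-3


def test_lambda_to_zero_limit_is_least_squares():
    X, y, _ = _well_conditioned_instance(seed=4)
    ls = np.linalg.lstsq(X, y, rcond=None)[0]
    L = 2.0 / X.shape[0] * np.linalg.eigvalsh(X.T @ X).max()
    cfg = GDConfig(lam=1e-9, tolerance=1e-15, max_iter=800, ista_scaling=True,
                   step_rule="constant", eta0=1.0 / L)
    model = train_plaintext(X, y, cfg)
    assert np.abs(model.weights - ls).max() < 1e-4


def test_huge_lambda_kills_all_weights():
    full, _ = generate_regression(40, 4, 0.01, 0.0, seed=8)
    X, y = full.features[:, :-1], full.column("target")
    lam = 10.0 * float(np.abs(2.0 / len(y) * X.T @ y).max())
    model = train_plaintext(X, y, GDConfig(lam=lam, tolerance=1e-10, max_iter=100, ista_scaling=True))
    assert np.all(model.weights == 0.0)


def test_objective_monotone_with_ista_and_safe_step():
    X, y, _ = _well_conditioned_instance(seed=5)
    L = 2.0 / X.shape[0] * np.linalg.eigvalsh(X.T @ X).max()
    cfg = GDConfig(lam=0.001, tolerance=1e-15, max_iter=60, ista_scaling=True,
                   step_rule="constant", eta0=1.0 / L)
    w = np.zeros(X.shape[1])
    prev = objective(X, y, w, cfg.lam)
    for t in range(cfg.max_iter):
        u = w - cfg.eta0 * calc_gradient(X, y, w)
        w = proxy(u, cfg.eta0 * cfg.lam)
        cur = objective(X, y, w, cfg.lam)
        assert cur <= prev + 1e-12
        prev = cur


def test_max_iter_zero_invalid():
    with pytest.raises(ValueError):
        GDConfig(max_iter=0)


def test_divergence_guard_triggers():
    X, y, _ = _well_conditioned_instance(seed=6)
    cfg = GDConfig(lam=0.0001, tolerance=1e-15, max_iter=500, step_rule="constant", eta0=1e5)
    with pytest.raises(DivergenceError):
        train_plaintext(X, y, cfg)


def test_intercept_column_unpenalized():
    rng = np.random.default_rng(9)
    X = rng.random((60, 3))
    y = X @ np.array([0.5, 0.0, -0.3]) + 2.0
    L = 2.0 / X.shape[0] * np.linalg.eigvalsh(
        np.column_stack([X, np.ones(60)]).T @ np.column_stack([X, np.ones(60)])
    ).max()
    cfg = GDConfig(lam=1e-6, tolerance=1e-14, max_iter=2000, ista_scaling=True,
                   step_rule="constant", eta0=1.0 / L, fit_intercept=True)
    model = train_plaintext(X, y, cfg)
    assert model.intercept == pytest.approx(2.0, abs=1e-2)


def test_stop_reason_and_iteration_count():
    full, _ = generate_regression(50, 5, 0.01, 0.0, seed=10)
    X, y = full.features[:, :-1], full.column("target")
    model = train_plaintext(X, y, GDConfig(lam=0.01, tolerance=1e-4, max_iter=200, ista_scaling=True))
    assert model.stop_reason == "tolerance"
    assert model.iterations_used <= 200


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def test_r_squared_perfect_and_mean_predictor():
    rng = np.random.default_rng(11)
    y = rng.random(20)
    assert r_squared(y, y) == pytest.approx(1.0)
    assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0)


def test_r_squared_matches_sklearn():
    from sklearn.metrics import r2_score

    rng = np.random.default_rng(12)
    y, yp = rng.random(30), rng.random(30)
    assert r_squared(y, yp) == pytest.approx(r2_score(y, yp))


def test_r_squared_constant_target_undefined():
    with pytest.raises(UndefinedRSquaredError):
        r_squared(np.ones(5), np.zeros(5))


def test_evaluate_report_matches_sklearn_metrics():
    from sklearn.metrics import mean_absolute_error, mean_squared_error

    full, _ = generate_regression(40, 3, 0.05, 0.0, seed=13)
    X, y = full.features[:, :-1], full.column("target")
    model = train_plaintext(X, y, GDConfig(lam=0.001, tolerance=1e-8, max_iter=300, ista_scaling=True))
    rep = evaluate(model, X, y)
    yp = X @ model.weights
    assert rep.mse == pytest.approx(mean_squared_error(y, yp))
    assert rep.mae == pytest.approx(mean_absolute_error(y, yp))
    assert rep.y_mean == pytest.approx(float(y.mean()))


def test_plaintext_trainer_reaches_sklearn_objective():
    """Our solver minimizes (1/n)||.||^2 + lam||w||_1, i.e. sklearn alpha=lam/2."""
    from sklearn.linear_model import Lasso

    full, _ = generate_regression(100, 5, 0.05, 0.2, seed=14)
    X, y = full.features[:, :-1], full.column("target")
    lam = 0.01
    L = 2.0 / X.shape[0] * np.linalg.eigvalsh(X.T @ X).max()
    cfg = GDConfig(lam=lam, tolerance=1e-14, max_iter=20000, ista_scaling=True,
                   step_rule="constant", eta0=1.0 / L)
    ours = train_plaintext(X, y, cfg)
    sk = Lasso(alpha=lam / 2, fit_intercept=False, max_iter=100000, tol=1e-12).fit(X, y)
    assert objective(X, y, ours.weights, lam) == pytest.approx(
        objective(X, y, sk.coef_, lam), abs=1e-6
    )
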