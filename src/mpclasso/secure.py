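"""Secure Lasso training on (1,3)-Shamir-shared data.

Runs the exact iteration of :func:`mpclasso.lasso.train_plaintext` on shares:
the gradient is linear algebra on shared fixed-point values, the soft
threshold is evaluated through two secret-shared comparison bits per
coefficient (``a = (w_i > tau)``, ``b = (w_i < -tau)``, output
``a*(w_i - tau) + b*(w_i + tau)``), and the data-driven initial step size
``0.1 / max(X^T X)`` uses shared inner products and a secure maximum, after
which the single aggregate maximum is revealed so the division can happen in
plaintext.  Per iteration only the numerator and denominator of the relative
update difference are revealed (so the public stopping rule can be applied),
and at the end the weight vector itself -- the model both data parties are
entitled to.  Every revealed value is recorded in the reveal ledger.
"""

from __future__ import annotations

import math

import numpy as np

from .lasso import GDConfig, LassoModel, UndefinedRSquaredError
from .runtime import PARTIES
from .shamir import ShamirEngine, SharedArray

__all__ = ["train_secure", "secure_initial_step_size", "secure_r_squared"]


def _append_ones_column(engine: ShamirEngine, X: SharedArray) -> SharedArray:
    n, m = X.shape
    one = engine.field.encode(1.0, X.frac)
    shares = {}
    for q in X.shares:
        src = X.shares[q]
        out = []
        for r in range(n):
            out.extend(src[r * m : (r + 1) * m])
            out.append(one)
        shares[q] = out
    return SharedArray(shares, (n, m + 1), X.frac, engine.field)


def secure_initial_step_size(engine: ShamirEngine, X: SharedArray) -> float:
    """eta0 = 0.1 / max(X^T X), the maximum taken over all entries.

    The Gram matrix stays shared; only its maximum entry is revealed
    (ledger label ``eta0_max``) so the division is public.
    """
    n, m = X.shape
    p = engine.field.p
    # local degree-2 Gram contributions, one resharing for all m*m entries
    local = {}
    for q in PARTIES:
        src = X.shares[q]
        out = []
        for i in range(m):
            for j in range(m):
                out.append(sum(src[r * m + i] * src[r * m + j] for r in range(n)) % p)
        local[q] = out
    gram = engine._reshare(local, (m * m,), 2 * X.frac)
    mx = engine.secure_max(gram)
    mx_val = engine.reveal(mx, "eta0_max")
    if mx_val <= 0:
        raise ValueError("X^T X has no positive entry; cannot set a step size")
    return 0.1 / mx_val


def train_secure(
    Xs: SharedArray,
    ys: SharedArray,
    cfg: GDConfig,
    engine: ShamirEngine,
) -> LassoModel:
    """Proximal gradient descent over shares; same semantics as the plaintext trainer.

    The returned model's ``objective`` is ``None``: computing it would require
    an extra reveal, which :func:`secure_r_squared` provides (its revealed
    residual sum equals ``||Xw - y||^2``).
    """
    fld = engine.field
    f, p = fld.f, fld.p
    Xe = _append_ones_column(engine, Xs) if cfg.fit_intercept else Xs
    n, m = Xe.shape
    eta0 = cfg.eta0 if cfg.eta0 is not None else secure_initial_step_size(engine, Xe)

    w = engine.constant([0] * m, (m,), f)
    y2f = engine.mul_public(ys, 1 << f, frac=2 * f)
    stop_reason = "max_iter"
    t_used = cfg.max_iter
    for t in range(cfg.max_iter):
        eta = cfg.step_size(eta0, t)
        tau = eta * cfg.lam if cfg.ista_scaling else cfg.lam
        tau_enc = fld.encode(tau, f)

        # u = w - eta * (2/n) X^T (Xw - y)
        Xw = engine.matvec(Xe, w)  # frac 2f
        res = engine.sub_shared(Xw, y2f)
        g3 = engine.matvec_transpose(Xe, res)  # frac 3f
        g = engine.truncate(g3, 2 * f)  # frac f
        c_t = fld.encode(eta * 2.0 / n, f)
        u2 = engine.sub_shared(
            engine.mul_public(w, 1 << f, frac=2 * f),
            engine.mul_public(g, c_t, frac=2 * f),
        )
        u = engine.truncate(u2, f)  # frac f

        # soft threshold via comparison bits: a=(u>tau), b=(u<-tau)
        d_a = engine.add_public(engine.mul_public(u, p - 1), [tau_enc] * m)  # tau - u
        d_b = engine.add_public(u, [tau_enc] * m)  # u + tau
        bits = engine.ltz(engine._concat(d_a, d_b))
        a = engine._slice(bits, 0, m)
        b = engine._slice(bits, m, 2 * m)
        u_minus = engine.add_public(u, [(-tau_enc) % p] * m)
        u_plus = engine.add_public(u, [tau_enc] * m)
        prods = engine.mul_shared(engine._concat(a, b), engine._concat(u_minus, u_plus))
        prods.frac = f
        w_new = engine.add_shared(engine._slice(prods, 0, m), engine._slice(prods, m, 2 * m))
        w_new.frac = f
        if cfg.fit_intercept:
            for q in PARTIES:
                w_new.shares[q][m - 1] = u.shares[q][m - 1]

        delta = engine.sub_shared(w_new, w)
        num = engine.reveal(engine.inner_product(delta, delta), "ud_num", iteration=t)
        den = engine.reveal(engine.inner_product(w, w), "ud_den", iteration=t)
        ud = math.inf if den == 0.0 else num / den
        w = w_new
        if ud < cfg.tolerance:
            stop_reason = "tolerance"
            t_used = t + 1
            break

    final = engine.reveal(w, "final_w")
    if cfg.fit_intercept:
        weights, intercept = final[:-1], final[-1]
    else:
        weights, intercept = final, 0.0
    return LassoModel(
        weights=np.asarray(weights, dtype=float),
        intercept=float(intercept),
        iterations_used=t_used,
        objective=None,
        stop_reason=stop_reason,
    )


def _matvec_public_weights(engine: ShamirEngine, X: SharedArray, w_enc: list[int]) -> SharedArray:
    """X @ w for public fixed-point weights: purely local linear combination."""
    n, m = X.shape
    p = engine.field.p
    shares = {}
    for q in X.shares:
        src = X.shares[q]
        shares[q] = [
            sum(src[r * m + c] * w_enc[c] for c in range(m)) % p for r in range(n)
        ]
    return SharedArray(shares, (n,), 2 * X.frac, engine.field)


def secure_r_squared(
    Xs: SharedArray,
    ys: SharedArray,
    model: LassoModel,
    engine: ShamirEngine,
) -> tuple[float, dict]:
    """R^2 of public weights on shared data, revealing only the two sums.

    Shares of ``y_pred = X w`` are a local linear combination because ``w``
    is already public; the (squared) residual sum and total sum are revealed
    (ledger labels ``r2_num``, ``r2_den``).  Returns ``(r_squared, details)``
    with the revealed sums in ``details`` -- ``r2_num`` equals
    ``||Xw - y||^2``, from which the Lasso objective follows publicly.
    """
    fld = engine.field
    f = fld.f
    n = ys.shape[0]
    if n == 0:
        raise UndefinedRSquaredError("empty target")
    w_enc = [fld.encode(v, f) for v in model.weights]
    y_pred = _matvec_public_weights(engine, Xs, w_enc)  # frac 2f
    if model.intercept:
        y_pred = engine.add_public(y_pred, [fld.encode(model.intercept, 2 * f)] * n)
    res2f = engine.sub_shared(engine.mul_public(ys, 1 << f, frac=2 * f), y_pred)
    res = engine.truncate(res2f, f)  # frac f
    num = engine.reveal(engine.inner_product(res, res), "r2_num")

    total = engine.sum(ys)
    ybar2f = engine.mul_public(total, fld.encode(1.0 / n, f), frac=2 * f)
    ybar = engine.truncate(ybar2f, f)
    ybar_rep = SharedArray(
        {q: ybar.shares[q] * n for q in ybar.shares}, (n,), f, fld
    )
    dev = engine.sub_shared(ys, ybar_rep)
    den = engine.reveal(engine.inner_product(dev, dev), "r2_den")
    if den == 0.0:
        raise UndefinedRSquaredError("target is constant; R^2 undefined")
    return 1.0 - num / den, {"r2_num": num, "r2_den": den}
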