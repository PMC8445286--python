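import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from mpclasso.fields import FieldParams
from mpclasso.innerjoin import AdditiveShareTable
from mpclasso.runtime import AC, EMC, PolicyViolationError
from mpclasso.shamir import (
    InconsistentSharesError,
    InsufficientSharesError,
    reconstruct_value,
    share_value,
)

from _utils import decode_all, open_all


# ---------------------------------------------------------------------------
# low-level sharing
# ---------------------------------------------------------------------------


def test_any_two_of_three_shares_reconstruct():
    p = FieldParams().p
    rng = random.Random(0)
    for _ in range(20):
        x = rng.randrange(p)
        sh = share_value(x, p, rng)
        for pair in ({1: sh[1], 2: sh[2]}, {1: sh[1], 3: sh[3]}, {2: sh[2], 3: sh[3]}):
            assert reconstruct_value(pair, p) == x
        assert reconstruct_value(sh, p) == x


def test_single_share_insufficient():
    p = FieldParams().p
    sh = share_value(5, p, random.Random(1))
    with pytest.raises(InsufficientSharesError):
        reconstruct_value({1: sh[1]}, p)


def test_inconsistent_triple_is_rejected():
    p = FieldParams().p
    sh = share_value(5, p, random.Random(1))
    sh[3] = (sh[3] + 1) % p
    with pytest.raises(InconsistentSharesError):
        reconstruct_value(sh, p)


def test_exhaustive_one_privacy_at_toy_prime():
    """Over p=31, each party's share marginal is uniform whatever the secret."""
    p = 31
    for secret in range(p):
        for party in (1, 2, 3):
            counts = Counter((secret + a * party) % p for a in range(p))
            assert all(c == 1 for c in counts.values())  # exactly uniform


# ---------------------------------------------------------------------------
# engine arithmetic vs plaintext oracle
# ---------------------------------------------------------------------------


def test_linear_ops_match_plaintext_oracle(make_engine, field):
    eng, _ = make_engine(seed=2)
    p = field.p
    rng = random.Random(5)
    for _ in range(100):
        a, b, c = rng.randrange(p), rng.randrange(p), rng.randrange(1 << 20)
        sa = eng.share_from(AC, [a], (1,), 0)
        sb = eng.share_from(EMC, [b], (1,), 0)
        assert open_all(eng, eng.add_shared(sa, sb)) == [(a + b) % p]
        assert open_all(eng, eng.sub_shared(sa, sb)) == [(a - b) % p]
        assert open_all(eng, eng.mul_public(sa, c)) == [a * c % p]
        assert open_all(eng, eng.add_public(sa, [c])) == [(a + c) % p]


def test_multiplication_matches_plaintext_oracle(make_engine, field):
    eng, _ = make_engine(seed=3)
    p = field.p
    rng = random.Random(6)
    xs = [rng.randrange(p) for _ in range(50)]
    ys = [rng.randrange(p) for _ in range(50)]
    sx = eng.share_from(AC, xs, (50,), 0)
    sy = eng.share_from(EMC, ys, (50,), 0)
    assert open_all(eng, eng.mul_shared(sx, sy)) == [x * y % p for x, y in zip(xs, ys)]


def test_multiply_small_worked_examples(make_engine):
    eng, _ = make_engine(seed=4)
    s6 = eng.share_from(AC, [6], (1,), 0)
    s7 = eng.share_from(EMC, [7], (1,), 0)
    assert open_all(eng, eng.mul_shared(s6, s7)) == [42]
    s0 = eng.share_from(AC, [0], (1,), 0)
    assert open_all(eng, eng.mul_shared(s0, s7)) == [0]


def test_fixed_point_product_with_truncation(make_engine, field):
    eng, _ = make_engine(seed=5)
    half = eng.share_from(AC, [field.encode(0.5)], (1,), field.f)
    prod = eng.truncate(eng.mul_shared(half, half), field.f)
    val = decode_all(eng, prod)[0]
    assert val == pytest.approx(0.25, abs=2**-field.f)


def test_inner_product_and_max_worked_examples(make_engine, field):
    eng, _ = make_engine(seed=6)
    v1 = eng.share_from(AC, [field.encode(x) for x in (1, 2, 3)], (3,), field.f)
    v2 = eng.share_from(EMC, [field.encode(x) for x in (4, 5, 6)], (3,), field.f)
    ip = eng.inner_product(v1, v2)
    assert field.decode(open_all(eng, ip)[0], 2 * field.f) == pytest.approx(32.0)
    mx = eng.secure_max(eng.share_from(AC, [field.encode(x) for x in (0.1, 0.9, 0.4)], (3,), field.f))
    assert decode_all(eng, mx)[0] == pytest.approx(0.9, abs=2**-30)
    const = eng.secure_max(eng.share_from(AC, [field.encode(0.3)] * 4, (4,), field.f))
    assert decode_all(eng, const)[0] == pytest.approx(0.3, abs=2**-30)


def test_secure_max_random_oracle(make_engine, field):
    eng, _ = make_engine(seed=7)
    rng = random.Random(8)
    vals = [rng.uniform(-5, 5) for _ in range(9)]
    sv = eng.share_from(AC, [field.encode(v) for v in vals], (9,), field.f)
    got = decode_all(eng, eng.secure_max(sv))[0]
    assert got == pytest.approx(max(vals), abs=2**-30)


def test_secure_max_empty_rejected(make_engine, field):
    eng, _ = make_engine(seed=8)
    empty = eng.constant([], (0,), field.f)
    with pytest.raises(ValueError):
        eng.secure_max(empty)


def test_matvec_matches_numpy(make_engine, field):
    import numpy as np

    eng, _ = make_engine(seed=9)
    rng = np.random.default_rng(1)
    A = rng.uniform(-1, 1, (4, 3))
    x = rng.uniform(-1, 1, 3)
    sA = eng.share_from(AC, [field.encode(v) for v in A.flatten()], (4, 3), field.f)
    sx = eng.share_from(EMC, [field.encode(v) for v in x], (3,), field.f)
    got = [field.decode(v, 2 * field.f) for v in open_all(eng, eng.matvec(sA, sx))]
    assert got == pytest.approx(list(A @ x), abs=1e-9)
    y = rng.uniform(-1, 1, 4)
    sy = eng.share_from(EMC, [field.encode(v) for v in y], (4,), field.f)
    gotT = [field.decode(v, 2 * field.f) for v in open_all(eng, eng.matvec_transpose(sA, sy))]
    assert gotT == pytest.approx(list(A.T @ y), abs=1e-9)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


def test_truncation_error_bounded_by_one_ulp(make_engine, field):
    eng, _ = make_engine(seed=10)
    rng = random.Random(11)
    vals = [rng.uniform(-100, 100) for _ in range(200)]
    enc = [field.encode(v, 2 * field.f) for v in vals]
    sv = eng.share_from(AC, enc, (200,), 2 * field.f)
    out = eng.truncate(sv, field.f)
    got = decode_all(eng, out)
    for g, v in zip(got, vals):
        assert abs(g - v) <= 2**-field.f + 2**-field.f  # encoding + trunc ulp


def test_truncation_exact_on_exact_multiples(make_engine, field):
    eng, _ = make_engine(seed=11)
    vals = [3.0, -7.0, 0.0, 123.0]
    enc = [field.encode(v, 2 * field.f) for v in vals]
    sv = eng.share_from(AC, enc, (4,), 2 * field.f)
    assert decode_all(eng, eng.truncate(sv, field.f)) == vals


def test_truncation_preserves_sign(make_engine, field):
    eng, _ = make_engine(seed=12)
    rng = random.Random(13)
    vals = [-rng.uniform(0.5, 50) for _ in range(50)]
    sv = eng.share_from(AC, [field.encode(v, 2 * field.f) for v in vals], (50,), 2 * field.f)
    got = decode_all(eng, eng.truncate(sv, field.f))
    assert all(g < 0 for g in got)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


def test_comparison_against_plaintext_oracle(make_engine, field):
    eng, _ = make_engine(seed=13)
    rng = random.Random(14)
    vals = [rng.uniform(-3, 3) for _ in range(100)]
    sv = eng.share_from(AC, [field.encode(a) for a in vals], (100,), field.f)
    c = 0.25
    bits = open_all(eng, eng.greater_than_public(sv, c))
    assert bits == [1 if a > c else 0 for a in vals]
    bits_lt = open_all(eng, eng.less_than_public(sv, -0.5))
    assert bits_lt == [1 if a < -0.5 else 0 for a in vals]


def test_comparison_boundary_is_strict(make_engine, field):
    eng, _ = make_engine(seed=14)
    sv = eng.share_from(AC, [field.encode(0.1)], (1,), field.f)
    assert open_all(eng, eng.greater_than_public(sv, 0.1)) == [0]
    assert open_all(eng, eng.greater_than_public(sv, 0.0999))[0] == 1
    assert open_all(eng, eng.less_than_public(sv, 0.1)) == [0]


def test_ltz_on_mixed_signs(make_engine, field):
    eng, _ = make_engine(seed=15)
    vals = [-0.5, -2**-field.f, 0.0, 2**-field.f, 1.5]
    sv = eng.share_from(AC, [field.encode(v) for v in vals], (5,), field.f)
    assert open_all(eng, eng.ltz(sv)) == [1, 1, 0, 0, 0]


# ---------------------------------------------------------------------------
# shared randomness
# ---------------------------------------------------------------------------


def test_random_bits_are_bits(make_engine):
    eng, _ = make_engine(seed=16)
    bits = open_all(eng, eng.random_bits(64))
    assert set(bits) <= {0, 1}
    assert 0 < sum(bits) < 64  # not degenerate


# ---------------------------------------------------------------------------
# casting from the join's additive sharing
# ---------------------------------------------------------------------------


def test_cast_2of2_worked_example(make_engine, field):
    eng, _ = make_engine(seed=17)
    p = field.p
    ta = AdditiveShareTable(AC, ["v"], [[3]], field)
    tb = AdditiveShareTable(EMC, ["v"], [[7]], field)
    shared = eng.cast_2of2_to_shamir(ta, tb)
    assert open_all(eng, shared) == [10]


def test_cast_2of2_random_cells(make_engine, field):
    eng, _ = make_engine(seed=18)
    p = field.p
    rng = random.Random(19)
    vals = [rng.randrange(p) for _ in range(12)]
    xa = [rng.randrange(p) for _ in range(12)]
    xb = [(v - a) % p for v, a in zip(vals, xa)]
    ta = AdditiveShareTable(AC, list("abcd"), [xa[i : i + 4] for i in range(0, 12, 4)], field)
    tb = AdditiveShareTable(EMC, list("abcd"), [xb[i : i + 4] for i in range(0, 12, 4)], field)
    assert open_all(eng, eng.cast_2of2_to_shamir(ta, tb)) == vals


def test_cast_2of2_zero_rows(make_engine, field):
    eng, _ = make_engine(seed=19)
    ta = AdditiveShareTable(AC, ["v"], [], field)
    tb = AdditiveShareTable(EMC, ["v"], [], field)
    assert eng.cast_2of2_to_shamir(ta, tb).size == 0


# ---------------------------------------------------------------------------
# reveal policy
# ---------------------------------------------------------------------------


def test_reveal_records_ledger_entry(make_engine, field):
    eng, ctx = make_engine(seed=20)
    sv = eng.share_from(AC, [field.encode(5.0)], (1,), field.f)
    val = eng.reveal(sv, "final_w")
    assert val == [5.0]
    assert len(ctx.ledger.entries) == 1
    assert ctx.ledger.entries[0].label == "final_w"


def test_reveal_without_label_refused(make_engine, field):
    eng, _ = make_engine(seed=21)
    sv = eng.share_from(AC, [field.encode(1.0)], (1,), field.f)
    with pytest.raises(PolicyViolationError):
        eng.reveal(sv, "")


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=FieldParams().p - 1), min_size=1, max_size=8),
       st.lists(st.integers(min_value=0, max_value=FieldParams().p - 1), min_size=1, max_size=8))
def test_property_mul_and_inner_match_oracle(xs, ys):
    n = min(len(xs), len(ys))
    xs, ys = xs[:n], ys[:n]
    field = FieldParams()
    from mpclasso.runtime import ProtocolContext
    from mpclasso.shamir import ShamirEngine

    ctx = ProtocolContext(seed=99)
    try:
        eng = ShamirEngine(ctx, field)
        sx = eng.share_from(AC, xs, (n,), 0)
        sy = eng.share_from(EMC, ys, (n,), 0)
        assert open_all(eng, eng.mul_shared(sx, sy)) == [x * y % field.p for x, y in zip(xs, ys)]
        ip = open_all(eng, eng.inner_product(sx, sy))[0]
        assert ip == sum(x * y for x, y in zip(xs, ys)) % field.p
    finally:
        ctx.close()
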