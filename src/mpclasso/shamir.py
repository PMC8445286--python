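"""(1,3)-Shamir secret sharing engine with fixed-point arithmetic.

The three parties hold evaluations of a random degree-1 polynomial at the
fixed points 1, 2, 3; the secret is the value at 0.  Any single share is
uniform and independent of the secret (1-privacy), any two reconstruct it.
Linear operations are local; multiplication locally multiplies shares (a
degree-2 sharing), then re-shares and Lagrange-recombines in one round of
interaction, so no degree-2 value ever survives past that round.

Fixed-point layer: reals carry ``frac`` fractional bits (see
:mod:`mpclasso.fields`).  Products double the fractional bits and are brought
back with a probabilistic truncation (one ulp error bound); comparisons are
realized by opening a statistically masked shifted difference to the data
parties and comparing its low bits against shared random bits.  The masked
openings are uniform-looking by construction and are excluded from the reveal
ledger, which records only deliberately published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fields import FieldParams
from .runtime import AC, EMC, PARTIES, SHAMIR_INDEX, ProtocolAbortError, ProtocolContext

__all__ = [
    "ShamirEngine",
    "SharedArray",
    "share_value",
    "reconstruct_value",
    "InsufficientSharesError",
    "InconsistentSharesError",
]


class InsufficientSharesError(ValueError):
    pass


class InconsistentSharesError(ValueError):
    """Reconstruction of three mutually inconsistent shares (the ⊥ outcome)."""


# Lagrange coefficients at 0 for evaluation points (1, 2, 3).
def _lagrange_at_zero(p: int) -> dict[int, int]:
    return {1: 3 % p, 2: (-3) % p, 3: 1 % p}


def share_value(x: int, p: int, rng) -> dict[int, int]:
    """Deal one degree-1 sharing of ``x``: party i gets f(i), f(0) = x."""
    a = rng.randrange(p)
    return {i: (x + a * i) % p for i in (1, 2, 3)}


def reconstruct_value(shares: dict[int, int], p: int) -> int:
    """Reconstruct from >= 2 degree-1 shares; inconsistent triples raise ⊥."""
    if len(shares) < 2:
        raise InsufficientSharesError("need at least two shares to reconstruct")
    (i, si), (j, sj) = sorted(shares.items())[:2]
    inv = pow(j - i, -1, p)
    secret = (si * j - sj * i) * inv % p
    slope = (sj - si) * inv % p
    for idx, s in shares.items():
        if (secret + slope * idx) % p != s:
            raise InconsistentSharesError("shares do not lie on a degree-1 polynomial")
    return secret


@dataclass
class SharedArray:
    """A (1,3)-shared tensor of field elements with fixed-point metadata."""

    shares: dict[str, list[int]]  # party name -> flat share list
    shape: tuple[int, ...]
    frac: int
    field: FieldParams

    @property
    def size(self) -> int:
        return math.prod(self.shape)

    def reshape(self, shape: tuple[int, ...]) -> "SharedArray":
        if math.prod(shape) != self.size:
            raise ValueError("incompatible reshape")
        return SharedArray(self.shares, shape, self.frac, self.field)

    def _check(self, other: "SharedArray") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if self.field.p != other.field.p:
            raise ValueError("field mismatch")


class ShamirEngine:
    """Orchestrates the share arithmetic of the three simulated parties.

    All interactive steps pass through the context's bus, so the transcript
    of a training run is complete and auditable.  Operations are vectorised:
    one interaction round covers a whole array.
    """

    def __init__(self, ctx: ProtocolContext, field: FieldParams):
        self.ctx = ctx
        self.field = field
        self._lam = _lagrange_at_zero(field.p)

    # ------------------------------------------------------------------
    # dealing and opening
    # ------------------------------------------------------------------

    def share_from(
        self, dealer: str, values: list[int], shape: tuple[int, ...], frac: int
    ) -> SharedArray:
        """``dealer`` secret-shares a list of field elements it knows."""
        p = self.field.p
        rng = self.ctx.rng(dealer)
        per_party: dict[str, list[int]] = {q: [] for q in PARTIES}
        for x in values:
            a = rng.randrange(p)
            for q in PARTIES:
                per_party[q].append((x + a * SHAMIR_INDEX[q]) % p)
        for q in PARTIES:
            if q != dealer:
                self.ctx.bus.send(dealer, q, "deal_shares", per_party[q], kind="share")
        shares = {q: (per_party[q] if q == dealer else self.ctx.bus.recv(dealer, q)) for q in PARTIES}
        return SharedArray(shares, shape, frac, self.field)

    def constant(self, values: list[int], shape: tuple[int, ...], frac: int) -> SharedArray:
        """Sharing of universally public constants (degenerate polynomial)."""
        return SharedArray({q: list(values) for q in PARTIES}, shape, frac, self.field)

    def encode_constant(self, reals, shape: tuple[int, ...], frac: int | None = None) -> SharedArray:
        frac = self.field.f if frac is None else frac
        return self.constant([self.field.encode(v, frac) for v in reals], shape, frac)

    def _open_to(self, a: SharedArray, receivers: tuple[str, ...], label: str, kind: str) -> dict[str, list[int]]:
        """Open ``a`` to ``receivers`` only; others learn nothing."""
        p = self.field.p
        for sender in PARTIES:
            for recv in receivers:
                if sender != recv:
                    self.ctx.bus.send(sender, recv, label, a.shares[sender], kind=kind)
        opened: dict[str, list[int]] = {}
        for recv in receivers:
            got = {
                SHAMIR_INDEX[s]: (a.shares[s] if s == recv else self.ctx.bus.recv(s, recv))
                for s in PARTIES
            }
            vals = []
            for t in range(a.size):
                vals.append(reconstruct_value({i: col[t] for i, col in got.items()}, p))
            opened[recv] = vals
        return opened

    def reveal(self, a: SharedArray, label: str, iteration: int | None = None):
        """Deliberately publish ``a`` to all parties and record it in the ledger."""
        opened = self._open_to(a, PARTIES, f"reveal:{label}", kind="share")
        vals = opened[AC]
        decoded = [self.field.decode(v, a.frac) for v in vals]
        entry = decoded[0] if a.shape == () else decoded
        self.ctx.ledger.record(label, entry, iteration)
        return entry

    # ------------------------------------------------------------------
    # local linear algebra
    # ------------------------------------------------------------------

    def add_shared(self, a: SharedArray, b: SharedArray) -> SharedArray:
        a._check(b)
        if a.frac != b.frac:
            raise ValueError("fixed-point scales differ")
        return self._add_raw(a, b)

    def sub_shared(self, a: SharedArray, b: SharedArray) -> SharedArray:
        a._check(b)
        if a.frac != b.frac:
            raise ValueError("fixed-point scales differ")
        return self._sub_raw(a, b)

    def _add_raw(self, a: SharedArray, b: SharedArray) -> SharedArray:
        p = self.field.p
        return SharedArray(
            {q: [(x + y) % p for x, y in zip(a.shares[q], b.shares[q])] for q in PARTIES},
            a.shape,
            a.frac,
            self.field,
        )

    def _sub_raw(self, a: SharedArray, b: SharedArray) -> SharedArray:
        p = self.field.p
        return SharedArray(
            {q: [(x - y) % p for x, y in zip(a.shares[q], b.shares[q])] for q in PARTIES},
            a.shape,
            a.frac,
            self.field,
        )

    def add_public(self, a: SharedArray, consts: list[int]) -> SharedArray:
        """Add universally public field elements (shifts the polynomial)."""
        p = self.field.p
        return SharedArray(
            {q: [(x + c) % p for x, c in zip(a.shares[q], consts)] for q in PARTIES},
            a.shape,
            a.frac,
            self.field,
        )

    def mul_public(self, a: SharedArray, consts: list[int] | int, frac: int | None = None) -> SharedArray:
        """Multiply by universally public field elements (local)."""
        p = self.field.p
        if isinstance(consts, int):
            consts = [consts] * a.size
        return SharedArray(
            {q: [x * c % p for x, c in zip(a.shares[q], consts)] for q in PARTIES},
            a.shape,
            a.frac if frac is None else frac,
            self.field,
        )

    def sum(self, a: SharedArray) -> SharedArray:
        p = self.field.p
        return SharedArray(
            {q: [sum(a.shares[q]) % p] for q in PARTIES}, (), a.frac, self.field
        )

    # ------------------------------------------------------------------
    # interactive arithmetic
    # ------------------------------------------------------------------

    def _reshare(self, local: dict[str, list[int]], shape, frac) -> SharedArray:
        """Turn per-party degree-2 contributions into a fresh degree-1 sharing.

        Each party deals a degree-1 sharing of each of its local values; every
        party then Lagrange-combines what it received.  One communication
        round, six messages.
        """
        p = self.field.p
        dealt: dict[str, dict[str, list[int]]] = {}
        own: dict[str, list[int]] = {}
        for dealer in PARTIES:
            rng = self.ctx.rng(dealer)
            per_party = {q: [] for q in PARTIES}
            for x in local[dealer]:
                a = rng.randrange(p)
                for q in PARTIES:
                    per_party[q].append((x + a * SHAMIR_INDEX[q]) % p)
            own[dealer] = per_party[dealer]
            dealt[dealer] = {q: per_party[q] for q in PARTIES if q != dealer}
        received = self.ctx.bus.exchange("reshare", dealt, kind="share")
        shares: dict[str, list[int]] = {}
        n = len(local[AC])
        for q in PARTIES:
            acc = [0] * n
            for dealer in PARTIES:
                lam = self._lam[SHAMIR_INDEX[dealer]]
                src = own[dealer] if dealer == q else received[q][dealer]
                for t in range(n):
                    acc[t] = (acc[t] + lam * src[t]) % p
            shares[q] = acc
        return SharedArray(shares, shape, frac, self.field)

    def mul_shared(self, a: SharedArray, b: SharedArray) -> SharedArray:
        """Element-wise product; one interaction round; fractional bits add."""
        a._check(b)
        p = self.field.p
        local = {
            q: [x * y % p for x, y in zip(a.shares[q], b.shares[q])] for q in PARTIES
        }
        return self._reshare(local, a.shape, a.frac + b.frac)

    def inner_product(self, a: SharedArray, b: SharedArray) -> SharedArray:
        """Dot product with a single resharing regardless of length."""
        a._check(b)
        p = self.field.p
        local = {
            q: [sum(x * y % p for x, y in zip(a.shares[q], b.shares[q])) % p]
            for q in PARTIES
        }
        return self._reshare(local, (), a.frac + b.frac)

    def matvec(self, m: SharedArray, v: SharedArray) -> SharedArray:
        """``m @ v`` for a 2-D shared matrix and shared vector; one round."""
        if len(m.shape) != 2 or m.shape[1] != v.shape[0]:
            raise ValueError("incompatible shapes for matvec")
        p = self.field.p
        rows, cols = m.shape
        local: dict[str, list[int]] = {}
        for q in PARTIES:
            ms, vs = m.shares[q], v.shares[q]
            out = []
            for r in range(rows):
                base = r * cols
                out.append(sum(ms[base + c] * vs[c] for c in range(cols)) % p)
            local[q] = out
        return self._reshare(local, (rows,), m.frac + v.frac)

    def matvec_transpose(self, m: SharedArray, v: SharedArray) -> SharedArray:
        """``m.T @ v``; one round."""
        if len(m.shape) != 2 or m.shape[0] != v.shape[0]:
            raise ValueError("incompatible shapes for matvec_transpose")
        p = self.field.p
        rows, cols = m.shape
        local: dict[str, list[int]] = {}
        for q in PARTIES:
            ms, vs = m.shares[q], v.shares[q]
            out = [0] * cols
            for r in range(rows):
                base = r * cols
                w = vs[r]
                for c in range(cols):
                    out[c] += ms[base + c] * w
            local[q] = [x % p for x in out]
        return self._reshare(local, (cols,), m.frac + v.frac)

    # ------------------------------------------------------------------
    # shared randomness
    # ------------------------------------------------------------------

    def random_bits(self, count: int) -> SharedArray:
        """``count`` uniform shared bits, unknown to every individual party.

        Each party deals a sharing of its own random bit; the three are
        XOR-combined arithmetically (two multiplication rounds, batched).
        """
        contribs = []
        for party in PARTIES:
            rng = self.ctx.rng(party)
            bits = [rng.randrange(2) for _ in range(count)]
            contribs.append(self.share_from(party, bits, (count,), 0))
        x, y, z = contribs
        t = self._xor(x, y)
        return self._xor(t, z)

    def _xor(self, x: SharedArray, y: SharedArray) -> SharedArray:
        prod = self.mul_shared(x, y)
        prod.frac = 0
        p = self.field.p
        two = 2 % p
        s = self.add_shared(x, y)
        return SharedArray(
            {q: [(a - two * b) % p for a, b in zip(s.shares[q], prod.shares[q])] for q in PARTIES},
            x.shape,
            0,
            self.field,
        )

    def random_int(self, bits: int, count: int) -> SharedArray:
        """Sum of three per-party uniform draws from [0, 2^bits).

        Not perfectly uniform (range is [0, 3*2^bits)), but unknown to any
        single party and entropy-rich enough for statistical masking.
        """
        p = self.field.p
        total = None
        for party in PARTIES:
            rng = self.ctx.rng(party)
            vals = [rng.getrandbits(bits) for _ in range(count)]
            dealt = self.share_from(party, vals, (count,), 0)
            total = dealt if total is None else self.add_shared(total, dealt)
        return total

    # ------------------------------------------------------------------
    # fixed-point plumbing: truncation and comparison
    # ------------------------------------------------------------------

    def truncate(self, a: SharedArray, d: int, mag_bits: int | None = None) -> SharedArray:
        """Divide by 2^d, dropping ``d`` fractional bits; error <= 1 ulp.

        ``mag_bits`` bounds ``log2 |value|`` of the encoded integers (range
        contract; violating it silently corrupts the result).  The masked sum
        opened to the data parties is statistically close to uniform, so the
        opening leaks nothing beyond negligible probability.
        """
        fld = self.field
        p = fld.p
        count = a.size
        if count == 0:
            return SharedArray({q: [] for q in PARTIES}, a.shape, a.frac - d, fld)
        if mag_bits is None:
            mag_bits = fld.k_int + a.frac + 8
        k = mag_bits + 1
        if k + fld.sigma + 3 > p.bit_length():
            raise ValueError("magnitude bound too large for this field")
        flat = a.reshape((count,))
        bits = self.random_bits(d * count)
        r_low = self._bits_to_ints(bits, d, count)
        r_high = self.random_int(k + fld.sigma - d, count)
        shift = [1 << (k - 1)] * count
        c_shared = self.add_public(
            self._add_raw(self._add_raw(flat, r_low), self.mul_public(r_high, 1 << d)),
            shift,
        )
        opened = self._open_to(c_shared, (AC, EMC), "trunc_mask", kind="masked")
        c_low = [v % (1 << d) for v in opened[AC]]
        c_low_sh = self.share_from(AC, c_low, (count,), 0)
        inv = pow(1 << d, -1, p)
        res = self.mul_public(self._add_raw(flat, self._sub_raw(r_low, c_low_sh)), inv)
        res = res.reshape(a.shape)
        res.frac = a.frac - d
        return res

    def _bits_to_ints(self, bits: SharedArray, width: int, count: int) -> SharedArray:
        """Recombine consecutive shared bits (LSB first) into shared integers."""
        p = self.field.p
        shares = {}
        for q in PARTIES:
            src = bits.shares[q]
            out = []
            for t in range(count):
                acc = 0
                for j in range(width):
                    acc += src[t * width + j] << j
                out.append(acc % p)
            shares[q] = out
        return SharedArray(shares, (count,), 0, self.field)

    def ltz(self, a: SharedArray, mag_bits: int | None = None) -> SharedArray:
        """Shared bit per element: 1 iff the signed value is negative.

        Opens ``value + 2^m + mask`` to the data parties (statistically
        hidden), then resolves the borrow of the low ``m`` bits with a
        bitwise less-than circuit against shared random bits.
        """
        fld = self.field
        p = fld.p
        count = a.size
        if count == 0:
            return SharedArray({q: [] for q in PARTIES}, a.shape, 0, fld)
        m = fld.k_int + a.frac + 1 if mag_bits is None else mag_bits
        if m + fld.sigma + 4 > p.bit_length():
            raise ValueError("magnitude bound too large for this field")
        r_bits = self.random_bits(m * count)
        r_low = self._bits_to_ints(r_bits, m, count)
        r_high = self.random_int(fld.sigma + 2, count)
        flat = a.reshape((count,))
        c_shared = self.add_public(
            self._add_raw(self._add_raw(flat, r_low), self.mul_public(r_high, 1 << m)),
            [1 << m] * count,
        )
        opened = self._open_to(c_shared, (AC, EMC), "ltz_mask", kind="masked")
        c = opened[AC]
        c_low = [v % (1 << m) for v in c]
        c_high = [v >> m for v in c]
        # the data parties share the public-to-them pieces the circuit needs
        c_high_sh = self.share_from(AC, [v % p for v in c_high], (count,), 0)
        c_bits = self.share_from(
            AC,
            [(c_low[t] >> j) & 1 for t in range(count) for j in range(m)],
            (m * count,),
            0,
        )
        carry = self._bit_lt(c_bits, r_bits, m, count)
        # b_high = c_high - r_high - carry in {0,1}; ltz = 1 - b_high
        b_high = self.sub_shared(self.sub_shared(c_high_sh, r_high), carry)
        one = [1] * count
        neg = self.mul_public(b_high, p - 1)
        out = self.add_public(neg, one)
        out = out.reshape(a.shape)
        out.frac = 0
        return out

    def _bit_lt(self, c_bits: SharedArray, r_bits: SharedArray, m: int, count: int) -> SharedArray:
        """Shared bit (c < r) from two shared bit-vectors, MSB-first scan."""
        p = self.field.p

        def pick(arr: SharedArray, j: int) -> SharedArray:
            shares = {q: [arr.shares[q][t * m + j] for t in range(count)] for q in PARTIES}
            return SharedArray(shares, (count,), 0, self.field)

        res = self.constant([0] * count, (count,), 0)
        eq = self.constant([1] * count, (count,), 0)
        for j in range(m - 1, -1, -1):
            cj, rj = pick(c_bits, j), pick(r_bits, j)
            prod = self.mul_shared(cj, rj)
            prod.frac = 0
            # gt_j = r_j(1 - c_j); eq_j = 1 - c_j - r_j + 2 c_j r_j
            gt = self.sub_shared(rj, prod)
            eq_j = self.add_public(
                SharedArray(
                    {
                        q: [
                            (2 * pr - cc - rr) % p
                            for pr, cc, rr in zip(prod.shares[q], cj.shares[q], rj.shares[q])
                        ]
                        for q in PARTIES
                    },
                    (count,),
                    0,
                    self.field,
                ),
                [1] * count,
            )
            # batch the two multiplications of this level into one round
            left = self._concat(eq, eq)
            right = self._concat(gt, eq_j)
            both = self.mul_shared(left, right)
            both.frac = 0
            res = self.add_shared(res, self._slice(both, 0, count))
            eq = self._slice(both, count, 2 * count)
        return res

    def _concat(self, a: SharedArray, b: SharedArray) -> SharedArray:
        return SharedArray(
            {q: a.shares[q] + b.shares[q] for q in PARTIES},
            (a.size + b.size,),
            a.frac,
            self.field,
        )

    def _slice(self, a: SharedArray, lo: int, hi: int) -> SharedArray:
        return SharedArray(
            {q: a.shares[q][lo:hi] for q in PARTIES}, (hi - lo,), a.frac, self.field
        )

    # ------------------------------------------------------------------
    # derived comparisons
    # ------------------------------------------------------------------

    def greater_than_public(self, a: SharedArray, c: float) -> SharedArray:
        """Shared bit per element: 1 iff value > c (strict), c public."""
        enc = self.field.encode(c, a.frac)
        p = self.field.p
        diff = self.add_public(self.mul_public(a, p - 1), [enc] * a.size)  # c - a
        diff.frac = a.frac
        return self.ltz(diff)  # c - a < 0  <=>  a > c

    def less_than_public(self, a: SharedArray, c: float) -> SharedArray:
        """Shared bit per element: 1 iff value < c (strict), c public."""
        enc = self.field.encode(c, a.frac)
        diff = self.add_public(a, [(-enc) % self.field.p] * a.size)  # a - c
        diff.frac = a.frac
        return self.ltz(diff)

    def secure_max(self, v: SharedArray) -> SharedArray:
        """Maximum of a shared vector via a comparison tournament."""
        if v.size == 0:
            raise ValueError("secure_max of an empty vector")
        cur = v.reshape((v.size,))
        while cur.size > 1:
            half = cur.size // 2
            a = self._slice(cur, 0, half)
            b = self._slice(cur, half, 2 * half)
            a.frac = b.frac = cur.frac
            diff = self.sub_shared(b, a)
            gt = self.ltz(diff)  # 1 iff a > b
            picked = self.mul_shared(gt, diff)  # gt * (b - a)
            picked.frac = cur.frac
            # max(a,b) = b - gt*(b-a)
            mx = self.sub_shared(b, picked)
            if cur.size % 2:
                tail = self._slice(cur, 2 * half, cur.size)
                tail.frac = cur.frac
                mx = self._concat(mx, tail)
            mx.frac = cur.frac
            cur = mx
        return cur.reshape(())

    # ------------------------------------------------------------------
    # casting from the inner join's 2-out-of-2 sharing
    # ------------------------------------------------------------------

    def cast_2of2_to_shamir(self, table_ac, table_emc) -> SharedArray:
        """Lift aligned additive share tables into one (1,3)-shared matrix.

        Each data party Shamir-shares its additive share of every cell; all
        parties locally add the two dealt sharings, yielding shares of
        ``x + y mod p`` -- the fixed-point encoding of the joined table.
        """
        if table_ac.shape != table_emc.shape:
            raise ValueError("additive share tables are not aligned")
        if table_ac.field.p != self.field.p or table_emc.field.p != self.field.p:
            raise ProtocolAbortError("additive share tables use a different field")
        shape = table_ac.shape
        flat_ac = [v for row in table_ac.rows for v in row]
        flat_emc = [v for row in table_emc.rows for v in row]
        sh_ac = self.share_from(AC, flat_ac, shape, self.field.f)
        sh_emc = self.share_from(EMC, flat_emc, shape, self.field.f)
        return self.add_shared(sh_ac, sh_emc)
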