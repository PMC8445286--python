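"""Paillier additively homomorphic encryption.

Textbook construction: ``n = p*q`` with ``p, q`` primes of equal size,
``g = n + 1``, encryption ``Enc(m, r) = (1 + m*n) * r^n mod n^2`` and
decryption through the Carmichael function ``lam = lcm(p-1, q-1)``.
Only the additive homomorphism is needed here: the helper party combines
ciphertexts it cannot decrypt, so that feature values can be blinded with
uniform masks without ever being exposed in the clear.

Key generation draws primes from ``secrets`` by default.  A seeded
deterministic mode exists purely so protocol transcripts can be regression
tested; it is NOT secure and is flagged as such.
"""

from __future__ import annotations

import math
import random
import secrets
from dataclasses import dataclass

import sympy

MIN_KEY_BITS = 512  # fast test mode; production default below
DEFAULT_KEY_BITS = 2048


class KeyMismatchError(ValueError):
    """Ciphertexts under different public keys were combined."""


@dataclass(frozen=True)
class PublicKey:
    n: int

    @property
    def n_sq(self) -> int:
        return self.n * self.n

    @property
    def key_id(self) -> str:
        return f"{self.n % (1 << 64):016x}"

    def to_json(self) -> dict:
        return {"n": hex(self.n)}

    @staticmethod
    def from_json(d: dict) -> "PublicKey":
        return PublicKey(int(d["n"], 16))


@dataclass(frozen=True)
class SecretKey:
    public: PublicKey
    lam: int  # lcm(p-1, q-1)
    mu: int  # (L(g^lam mod n^2))^-1 mod n

    def to_json(self) -> dict:
        return {"n": hex(self.public.n), "lam": hex(self.lam), "mu": hex(self.mu)}

    @staticmethod
    def from_json(d: dict) -> "SecretKey":
        return SecretKey(PublicKey(int(d["n"], 16)), int(d["lam"], 16), int(d["mu"], 16))


@dataclass(frozen=True)
class HEKeypair:
    public_key: PublicKey
    secret_key: SecretKey


@dataclass(frozen=True)
class HECiphertext:
    value: int
    key_id: str


def _random_prime(bits: int, rng) -> int:
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        p = sympy.nextprime(cand - 1)
        if p.bit_length() == bits:
            return int(p)


def keygen(bits: int = DEFAULT_KEY_BITS, seed: int | None = None) -> HEKeypair:
    """Generate a fresh Paillier keypair with an ``n`` of roughly ``bits`` bits.

    ``seed`` switches to an insecure deterministic mode (transcript tests only).
    """
    if bits < MIN_KEY_BITS:
        raise ValueError(f"key size {bits} below minimum {MIN_KEY_BITS}")
    rng = random.Random(seed) if seed is not None else secrets.SystemRandom()
    half = bits // 2
    while True:
        p = _random_prime(half, rng)
        q = _random_prime(bits - half, rng)
        if p != q:
            break
    n = p * q
    lam = math.lcm(p - 1, q - 1)
    # g = n + 1, so L(g^lam mod n^2) = lam mod n and mu = lam^-1 mod n.
    mu = pow(lam, -1, n)
    pk = PublicKey(n)
    return HEKeypair(pk, SecretKey(pk, lam, mu))


def encrypt(pk: PublicKey, m: int, rng=None) -> HECiphertext:
    """Encrypt an integer ``m`` in ``[0, n)`` (callers pre-encode signed values)."""
    m %= pk.n
    rng = rng if rng is not None else secrets.SystemRandom()
    while True:
        r = rng.randrange(1, pk.n)
        if math.gcd(r, pk.n) == 1:
            break
    c = (1 + m * pk.n) % pk.n_sq * pow(r, pk.n, pk.n_sq) % pk.n_sq
    return HECiphertext(c, pk.key_id)


def decrypt(sk: SecretKey, c: HECiphertext) -> int:
    if c.key_id != sk.public.key_id:
        raise KeyMismatchError("ciphertext was produced under a different key")
    n, n_sq = sk.public.n, sk.public.n_sq
    u = pow(c.value, sk.lam, n_sq)
    return (u - 1) // n * sk.mu % n


def add_cipher(pk: PublicKey, c1: HECiphertext, c2: HECiphertext) -> HECiphertext:
    """Homomorphic addition: Dec(c1 (+) c2) = m1 + m2 (mod n)."""
    if c1.key_id != c2.key_id or c1.key_id != pk.key_id:
        raise KeyMismatchError("cannot combine ciphertexts under different keys")
    return HECiphertext(c1.value * c2.value % pk.n_sq, c1.key_id)


def sub_cipher(pk: PublicKey, c1: HECiphertext, c2: HECiphertext) -> HECiphertext:
    """Homomorphic subtraction: Dec(c1 (-) c2) = m1 - m2 (mod n)."""
    if c1.key_id != c2.key_id or c1.key_id != pk.key_id:
        raise KeyMismatchError("cannot combine ciphertexts under different keys")
    inv = pow(c2.value, -1, pk.n_sq)
    return HECiphertext(c1.value * inv % pk.n_sq, c1.key_id)
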