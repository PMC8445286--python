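"""Prime field and fixed-point encoding parameters shared by all protocol layers.

Every secret value handled by the MPC layers -- additive shares coming out of
the inner join as well as (1,3)-Shamir shares used during training -- lives in
the same prime field ``Z_p``.  Real-valued features are embedded into the field
with a two's-complement style signed fixed-point encoding: a real ``v`` is
represented by the field element ``round(v * 2^f) mod p``, and field elements
in ``(p/2, p)`` are interpreted as negative numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy

# 192-bit prime, the largest below 2**192.
_DEFAULT_PRIME = 6277101735386680763835789423207666416102355444464034512659


class EncodingOverflowError(ValueError):
    """A real value does not fit the configured fixed-point range."""


@dataclass(frozen=True)
class FieldParams:
    """Prime field plus fixed-point layout.

    Parameters
    ----------
    p:
        Prime modulus of the share arithmetic.
    f:
        Fractional bits of the fixed-point encoding (resolution ``2**-f``).
    k_int:
        Integer bits; encoded magnitudes must stay below ``2**k_int``.
    sigma:
        Statistical security parameter, in bits, used to size the random
        masks opened during truncation and comparison sub-protocols.
    """

    p: int = _DEFAULT_PRIME
    f: int = 40
    k_int: int = 16
    sigma: int = 40

    def __post_init__(self) -> None:
        if not sympy.isprime(self.p):
            raise ValueError("field modulus must be prime")
        if self.f < 1 or self.k_int < 1 or self.sigma < 1:
            raise ValueError("f, k_int and sigma must be positive")
        # Degree-2 products of encoded values plus statistical masks must not
        # wrap around the field.
        if self.p <= 2 ** (2 * (self.k_int + self.f) + self.sigma + 2):
            raise ValueError(
                "field modulus too small for the fixed-point layout: need "
                f"p > 2^{2 * (self.k_int + self.f) + self.sigma + 2}"
            )

    # -- signed embedding -------------------------------------------------

    @property
    def half(self) -> int:
        return self.p // 2

    def to_signed(self, x: int) -> int:
        """Map a field element to its signed representative in (-p/2, p/2]."""
        x %= self.p
        return x - self.p if x > self.half else x

    # -- fixed point -------------------------------------------------------

    def encode(self, v: float, frac: int | None = None) -> int:
        """Encode a real number as a field element with ``frac`` fractional bits."""
        frac = self.f if frac is None else frac
        q = round(v * (1 << frac))
        if abs(q) >> frac >= (1 << self.k_int):
            raise EncodingOverflowError(
                f"value {v!r} outside fixed-point range (k_int={self.k_int})"
            )
        return q % self.p

    def decode(self, x: int, frac: int | None = None) -> float:
        """Decode a field element back to a float."""
        frac = self.f if frac is None else frac
        return self.to_signed(x) / (1 << frac)


def toy_field(p: int = 31, **kw) -> FieldParams:
    """A deliberately tiny field for exhaustive privacy tests.

    Bypasses the size invariant; never use for actual data.
    """
    fp = object.__new__(FieldParams)
    object.__setattr__(fp, "p", p)
    object.__setattr__(fp, "f", kw.get("f", 0))
    object.__setattr__(fp, "k_int", kw.get("k_int", 2))
    object.__setattr__(fp, "sigma", kw.get("sigma", 1))
    if not sympy.isprime(p):
        raise ValueError("toy modulus must still be prime")
    return fp
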