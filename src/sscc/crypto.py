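"""Additively homomorphic encryption in the lifted-ElGamal style.

A plaintext integer ``m`` is encrypted as the pair ``(r*G, r*Q + m*G)``
over a prime-order elliptic-curve group with generator ``G`` and public
key ``Q = sk*G``.  Because the message rides in the exponent, ciphertexts
add componentwise to add their plaintexts (the protocol's ``⊕``) and a
known integer multiplies a plaintext by scalar-multiplying both components
(``⊗``).  Decryption recovers ``m*G`` and then solves the discrete log over
a small signed interval — a precomputed table for protocol-sized ranges,
baby-step/giant-step beyond that.

Negative plaintexts are encoded directly as group inverses (``-3`` becomes
``-3*G``), so scores are split into negative, zero and positive exactly as
the counting step of the search protocol requires.
"""

from __future__ import annotations

import math
import random
import secrets
from dataclasses import dataclass
from typing import Optional, Union

from . import _ec
from ._ec import AffinePoint

_POINT_BYTES = 25  # 1 prefix byte + 24-byte x-coordinate (192-bit field)
_SCALAR_BYTES = 24
_TABLE_MAX_WIDTH = 1 << 20  # widest range decoded by table lookup


class CryptoError(Exception):
    """Base class for crypto-layer failures."""


class UnknownGroupError(CryptoError):
    pass


class DecodeFailureError(CryptoError):
    """Decrypted point maps to no plaintext in the configured range.

    On an honest run this never happens; it signals protocol misuse or a
    malformed/malicious ciphertext.
    """


class GroupSpec:
    """A standardized prime-order group (default: the secp192k1 curve)."""

    def __init__(self, name: str = "secp192k1"):
        if name not in _ec.CURVES:
            raise UnknownGroupError(f"unknown group {name!r}; known: {sorted(_ec.CURVES)}")
        self.name = name
        self.curve = _ec.CURVES[name]
        self._decode_tables: dict[tuple[int, int], dict[AffinePoint, int]] = {}

    @property
    def order(self) -> int:
        return self.curve.n

    @property
    def generator(self) -> AffinePoint:
        return self.curve.generator

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GroupSpec) and other.name == self.name

    def __hash__(self) -> int:
        return hash(self.name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GroupSpec({self.name!r})"

    # -- point serialization: SEC-style compressed, fixed 25 bytes ----------

    def point_to_bytes(self, P: AffinePoint) -> bytes:
        if P is None:
            return b"\x00" * _POINT_BYTES
        x, y = P
        prefix = b"\x03" if y & 1 else b"\x02"
        return prefix + x.to_bytes(_POINT_BYTES - 1, "big")

    def point_from_bytes(self, data: bytes) -> AffinePoint:
        if len(data) != _POINT_BYTES:
            raise CryptoError(f"point encoding must be {_POINT_BYTES} bytes")
        prefix, xb = data[0], data[1:]
        if prefix == 0:
            if any(xb):
                raise CryptoError("malformed identity-point encoding")
            return None
        if prefix not in (2, 3):
            raise CryptoError(f"bad point prefix {prefix:#x}")
        p = self.curve.p
        x = int.from_bytes(xb, "big")
        if x >= p:
            raise CryptoError("point x-coordinate out of field range")
        rhs = (x * x * x + self.curve.a * x + self.curve.b) % p
        y = pow(rhs, (p + 1) // 4, p)  # p ≡ 3 (mod 4) for secp192k1
        if y * y % p != rhs:
            raise CryptoError("point is not on the curve")
        if (y & 1) != (prefix & 1):
            y = p - y
        return (x, y)

    # -- small-discrete-log table -------------------------------------------

    def decode_table(self, lo: int, hi: int) -> dict[AffinePoint, int]:
        """Map m*G -> m for every integer m in [lo, hi] (cached)."""
        key = (lo, hi)
        table = self._decode_tables.get(key)
        if table is None:
            table = {}
            P = _ec.scalar_mult(self.curve, lo, self.generator)
            for m in range(lo, hi + 1):
                table[P] = m
                P = _ec.affine_add(self.curve, P, self.generator)
            self._decode_tables[key] = table
        return table


@dataclass(frozen=True)
class PlaintextRange:
    """Signed integer interval [lo, hi] of decodable plaintexts."""

    lo: int
    hi: int

    def __post_init__(self):
        if not self.lo <= 0 <= self.hi:
            raise ValueError("plaintext range must contain 0")

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def __contains__(self, m: int) -> bool:
        return self.lo <= m <= self.hi


class PublicKey:
    """Group spec plus public element, with cached fixed-base tables."""

    __slots__ = ("spec", "point", "_comb")

    def __init__(self, spec: GroupSpec, point: AffinePoint):
        if point is None or not spec.curve.on_curve(point):
            raise CryptoError("public key point is not on the curve")
        self.spec = spec
        self.point = point
        self._comb: _ec.FixedBaseTable | None = None

    def _mult_pk(self, k: int) -> AffinePoint:
        if self._comb is None:
            self._comb = _ec.FixedBaseTable(self.spec.curve, self.point)
        return self._comb.mult(k)

    def _mult_g(self, k: int) -> AffinePoint:
        return self.spec.curve.generator_table().mult(k)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PublicKey)
            and other.spec == self.spec
            and other.point == self.point
        )

    def __hash__(self) -> int:
        return hash((self.spec, self.point))


@dataclass(frozen=True)
class KeyPair:
    pk: PublicKey
    sk: int


@dataclass(frozen=True)
class Ciphertext:
    """ElGamal pair (c1, c2); the all-identity pair encrypts 0 trivially."""

    spec: GroupSpec
    c1: AffinePoint
    c2: AffinePoint

    def to_hex(self) -> str:
        return (self.spec.point_to_bytes(self.c1) + self.spec.point_to_bytes(self.c2)).hex()

    @classmethod
    def from_hex(cls, spec: GroupSpec, data: str) -> "Ciphertext":
        raw = bytes.fromhex(data)
        if len(raw) != 2 * _POINT_BYTES:
            raise CryptoError("ciphertext encoding has wrong length")
        return cls(spec, spec.point_from_bytes(raw[:_POINT_BYTES]),
                   spec.point_from_bytes(raw[_POINT_BYTES:]))


RngLike = Union[random.Random, random.SystemRandom]


def _rng_or_secure(rng: Optional[RngLike]) -> RngLike:
    return rng if rng is not None else random.SystemRandom()


def random_scalar(spec: GroupSpec, rng: Optional[RngLike] = None) -> int:
    if rng is None:
        return 1 + secrets.randbelow(spec.order - 1)
    return rng.randrange(1, spec.order)


def key_gen(spec: GroupSpec, seed: Optional[int] = None) -> KeyPair:
    """Generate a key pair; ``seed`` is for test reproducibility only."""
    rng = random.Random(seed) if seed is not None else None
    sk = random_scalar(spec, rng)
    pk_point = spec.curve.generator_table().mult(sk)
    return KeyPair(pk=PublicKey(spec, pk_point), sk=sk)


def encrypt(pk: PublicKey, m: int, randomness: Optional[int] = None,
            rng: Optional[RngLike] = None) -> Ciphertext:
    """Lifted encryption (r*G, r*Q + m*G) with fresh randomness by default."""
    r = randomness if randomness is not None else random_scalar(pk.spec, rng)
    c1 = pk._mult_g(r)
    c2 = _ec.affine_add(pk.spec.curve, pk._mult_pk(r), pk._mult_g(m))
    return Ciphertext(pk.spec, c1, c2)


def add(ct_a: Ciphertext, ct_b: Ciphertext) -> Ciphertext:
    """Homomorphic plaintext addition (the protocol's ⊕)."""
    if ct_a.spec != ct_b.spec:
        raise CryptoError("ciphertexts from different groups")
    curve = ct_a.spec.curve
    return Ciphertext(ct_a.spec,
                      _ec.affine_add(curve, ct_a.c1, ct_b.c1),
                      _ec.affine_add(curve, ct_a.c2, ct_b.c2))


def scalar_mul(e: int, ct: Ciphertext) -> Ciphertext:
    """Homomorphic multiplication of the plaintext by integer e (⊗)."""
    curve = ct.spec.curve
    return Ciphertext(ct.spec,
                      _ec.scalar_mult(curve, e, ct.c1),
                      _ec.scalar_mult(curve, e, ct.c2))


def rerandomize(pk: PublicKey, ct: Ciphertext, rng: Optional[RngLike] = None) -> Ciphertext:
    """Fresh ciphertext of the same plaintext (⊕ a fresh encryption of 0)."""
    return add(ct, encrypt(pk, 0, rng=rng))


def zero_ciphertext(spec: GroupSpec) -> Ciphertext:
    """The trivial encryption of 0 — the ⊕-identity."""
    return Ciphertext(spec, None, None)


def decrypt(sk: Union[int, KeyPair], ct: Ciphertext, prange: PlaintextRange) -> int:
    """Recover the plaintext by solving the small DLP over ``prange``."""
    secret = sk.sk if isinstance(sk, KeyPair) else sk
    spec = ct.spec
    curve = spec.curve
    M = _ec.affine_add(curve, ct.c2, _ec.scalar_mult(curve, -secret, ct.c1))
    if prange.width <= _TABLE_MAX_WIDTH:
        table = spec.decode_table(prange.lo, prange.hi)
        m = table.get(M, None)
        if m is None:
            raise DecodeFailureError(
                f"plaintext outside decode range [{prange.lo}, {prange.hi}]")
        return m
    return _bsgs(spec, M, prange)


def _bsgs(spec: GroupSpec, M: AffinePoint, prange: PlaintextRange) -> int:
    """Baby-step/giant-step over [lo, hi] for wide configured ranges."""
    curve = spec.curve
    G = spec.generator
    width = prange.width
    mm = math.isqrt(width) + 1
    baby: dict[AffinePoint, int] = {}
    P: AffinePoint = None
    for j in range(mm):
        baby.setdefault(P, j)
        P = _ec.affine_add(curve, P, G)
    # T = M - lo*G = d*G with d in [0, width)
    T = _ec.affine_add(curve, M, _ec.scalar_mult(curve, -prange.lo, G))
    step = _ec.negate(curve, _ec.scalar_mult(curve, mm, G))
    cur = T
    for i in range(mm + 1):
        j = baby.get(cur, None)
        if j is not None:
            d = i * mm + j
            if d < width:
                return prange.lo + d
        cur = _ec.affine_add(curve, cur, step)
    raise DecodeFailureError(
        f"plaintext outside decode range [{prange.lo}, {prange.hi}]")


# -- key file serialization -------------------------------------------------

def keypair_to_text(keys: KeyPair, include_secret: bool = True) -> str:
    import json

    doc = {
        "format": "sscc-key/1",
        "group": keys.pk.spec.name,
        "pk": keys.pk.spec.point_to_bytes(keys.pk.point).hex(),
    }
    if include_secret:
        doc["sk"] = format(keys.sk, "x")
    return json.dumps(doc, indent=1)


def keypair_from_text(text: str) -> KeyPair:
    import json

    doc = json.loads(text)
    if doc.get("format") != "sscc-key/1":
        raise CryptoError("not an sscc key file")
    spec = GroupSpec(doc["group"])
    pk = PublicKey(spec, spec.point_from_bytes(bytes.fromhex(doc["pk"])))
    sk = int(doc["sk"], 16) if "sk" in doc else 0
    return KeyPair(pk=pk, sk=sk)
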