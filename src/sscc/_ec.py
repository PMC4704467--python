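"""Elliptic-curve group arithmetic over prime fields.

Short-Weierstrass curves ``y^2 = x^3 + a*x + b (mod p)`` with prime group
order, in Jacobian coordinates.  Scalar multiplication uses width-4 wNAF for
arbitrary bases and a precomputed comb table for fixed bases (the generator
and a public key), which is where the protocol spends nearly all of its
point multiplications.

Affine points are ``(x, y)`` tuples; the point at infinity is ``None``.
This module is deliberately self-contained and allocation-light: it is the
hot path of every encryption, proof and decryption.
"""

from __future__ import annotations

from typing import Optional

AffinePoint = Optional[tuple[int, int]]
_JacPoint = Optional[tuple[int, int, int]]

_WNAF_WINDOW = 4
_COMB_WINDOW = 4


class Curve:
    """A named short-Weierstrass curve with a prime-order base point."""

    __slots__ = ("name", "p", "a", "b", "n", "gx", "gy", "_g_comb")

    def __init__(self, name: str, p: int, a: int, b: int, n: int, gx: int, gy: int):
        self.name = name
        self.p = p
        self.a = a
        self.b = b
        self.n = n  # order of the base point (prime, cofactor 1)
        self.gx = gx
        self.gy = gy
        self._g_comb: "FixedBaseTable | None" = None

    @property
    def generator(self) -> AffinePoint:
        return (self.gx, self.gy)

    def generator_table(self) -> "FixedBaseTable":
        if self._g_comb is None:
            self._g_comb = FixedBaseTable(self, self.generator)
        return self._g_comb

    def on_curve(self, P: AffinePoint) -> bool:
        if P is None:
            return True
        x, y = P
        return (y * y - (x * x * x + self.a * x + self.b)) % self.p == 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Curve({self.name!r})"


# SEC 2 parameter set secp192k1 (a = 0, cofactor 1).
SECP192K1 = Curve(
    name="secp192k1",
    p=0xFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFFEFFFFEE37,
    a=0,
    b=3,
    n=0xFFFFFFFFFFFFFFFFFFFFFFFE26F2FC170F69466A74DEFD8D,
    gx=0xDB4FF10EC057E9AE26B07D0280B7F4341DA5D1B1EAE06C7D,
    gy=0x9B2F2F6D9C5628A7844163D015BE86344082AA88D95E2F9D,
)

CURVES: dict[str, Curve] = {SECP192K1.name: SECP192K1}


# ---------------------------------------------------------------------------
# Jacobian primitives

def _jac_double(P: _JacPoint, p: int, a: int) -> _JacPoint:
    if P is None:
        return None
    X1, Y1, Z1 = P
    if Y1 == 0:
        return None
    YY = Y1 * Y1 % p
    S = 4 * X1 * YY % p
    M = 3 * X1 * X1
    if a:
        ZZ = Z1 * Z1 % p
        M += a * ZZ * ZZ
    M %= p
    X3 = (M * M - 2 * S) % p
    Y3 = (M * (S - X3) - 8 * YY * YY) % p
    Z3 = 2 * Y1 * Z1 % p
    return (X3, Y3, Z3)


def _jac_add_mixed(P: _JacPoint, Q: tuple[int, int], p: int, a: int) -> _JacPoint:
    """Add an affine point Q to a Jacobian point P."""
    if P is None:
        return (Q[0], Q[1], 1)
    X1, Y1, Z1 = P
    x2, y2 = Q
    ZZ = Z1 * Z1 % p
    U2 = x2 * ZZ % p
    S2 = y2 * Z1 * ZZ % p
    H = (U2 - X1) % p
    r = (S2 - Y1) % p
    if H == 0:
        if r == 0:
            return _jac_double(P, p, a)
        return None
    HH = H * H % p
    HHH = H * HH % p
    V = X1 * HH % p
    X3 = (r * r - HHH - 2 * V) % p
    Y3 = (r * (V - X3) - Y1 * HHH) % p
    Z3 = Z1 * H % p
    return (X3, Y3, Z3)


def _jac_to_affine(P: _JacPoint, p: int) -> AffinePoint:
    if P is None:
        return None
    X, Y, Z = P
    zinv = pow(Z, -1, p)
    zinv2 = zinv * zinv % p
    return (X * zinv2 % p, Y * zinv2 * zinv % p)


def _batch_to_affine(points: list[_JacPoint], p: int) -> list[AffinePoint]:
    """Normalize many Jacobian points with a single field inversion."""
    idx = [i for i, pt in enumerate(points) if pt is not None]
    if not idx:
        return [None] * len(points)
    zs = [points[i][2] for i in idx]
    prefix = [1] * (len(zs) + 1)
    for i, z in enumerate(zs):
        prefix[i + 1] = prefix[i] * z % p
    inv = pow(prefix[-1], -1, p)
    out: list[AffinePoint] = [None] * len(points)
    for i in range(len(zs) - 1, -1, -1):
        zinv = prefix[i] * inv % p
        inv = inv * zs[i] % p
        X, Y, _ = points[idx[i]]
        zinv2 = zinv * zinv % p
        out[idx[i]] = (X * zinv2 % p, Y * zinv2 * zinv % p)
    return out


# ---------------------------------------------------------------------------
# Affine API

def negate(curve: Curve, P: AffinePoint) -> AffinePoint:
    if P is None:
        return None
    return (P[0], (-P[1]) % curve.p)


def affine_add(curve: Curve, P: AffinePoint, Q: AffinePoint) -> AffinePoint:
    if P is None:
        return Q
    if Q is None:
        return P
    p = curve.p
    x1, y1 = P
    x2, y2 = Q
    if x1 == x2:
        if (y1 + y2) % p == 0:
            return None
        m = (3 * x1 * x1 + curve.a) * pow(2 * y1, -1, p) % p
    else:
        m = (y2 - y1) * pow(x2 - x1, -1, p) % p
    x3 = (m * m - x1 - x2) % p
    y3 = (m * (x1 - x3) - y1) % p
    return (x3, y3)


def _wnaf(k: int, w: int) -> list[int]:
    digits = []
    mask = (1 << w) - 1
    half = 1 << (w - 1)
    while k:
        if k & 1:
            d = k & mask
            if d >= half:
                d -= 1 << w
            k -= d
        else:
            d = 0
        digits.append(d)
        k >>= 1
    return digits


def scalar_mult(curve: Curve, k: int, P: AffinePoint) -> AffinePoint:
    """Compute k*P for any integer k (negative allowed)."""
    if P is None:
        return None
    if k < 0:
        k, P = -k, negate(curve, P)
    k %= curve.n
    if k == 0:
        return None
    p, a = curve.p, curve.a
    if k.bit_length() <= _WNAF_WINDOW + 1:
        # tiny scalars (the protocol's λ multipliers): plain double-and-add
        R: _JacPoint = None
        for bit in bin(k)[2:]:
            R = _jac_double(R, p, a)
            if bit == "1":
                R = _jac_add_mixed(R, P, p, a)
        return _jac_to_affine(R, p)
    # precompute odd multiples P, 3P, ..., 15P (affine, one batched inversion)
    P2 = _jac_double((P[0], P[1], 1), p, a)
    odd_jac: list[_JacPoint] = [(P[0], P[1], 1)]
    P2_aff = _jac_to_affine(P2, p)
    for _ in range((1 << (_WNAF_WINDOW - 1)) - 1):
        odd_jac.append(_jac_add_mixed(odd_jac[-1], P2_aff, p, a))
    odds = _batch_to_affine(odd_jac, p)
    R = None
    for d in reversed(_wnaf(k, _WNAF_WINDOW)):
        R = _jac_double(R, p, a)
        if d > 0:
            R = _jac_add_mixed(R, odds[(d - 1) >> 1], p, a)
        elif d < 0:
            x, y = odds[(-d - 1) >> 1]
            R = _jac_add_mixed(R, (x, (-y) % p), p, a)
    return _jac_to_affine(R, p)


class FixedBaseTable:
    """Comb table for fast repeated multiplication of a fixed base point.

    Stores ``d * 2^(w*j) * base`` for every window position j and digit
    d in 1..2^w-1, so a full multiplication is at most ceil(bits/w) mixed
    additions and no doublings.
    """

    __slots__ = ("curve", "base", "_rows")

    def __init__(self, curve: Curve, base: tuple[int, int], window: int = _COMB_WINDOW):
        self.curve = curve
        self.base = base
        p, a = curve.p, curve.a
        nwin = (curve.n.bit_length() + window - 1) // window
        rows_jac: list[list[_JacPoint]] = []
        cur = base
        for _ in range(nwin):
            row: list[_JacPoint] = [(cur[0], cur[1], 1)]
            for _ in range((1 << window) - 2):
                row.append(_jac_add_mixed(row[-1], cur, p, a))
            rows_jac.append(row)
            nxt = row[-1]  # (2^w - 1) * cur
            nxt = _jac_add_mixed(nxt, cur, p, a)  # 2^w * cur
            cur = _jac_to_affine(nxt, p)
            if cur is None:  # exhausted the group; remaining rows unreachable
                break
        flat = [pt for row in rows_jac for pt in row]
        flat_aff = _batch_to_affine(flat, p)
        stride = (1 << window) - 1
        self._rows = [flat_aff[i * stride:(i + 1) * stride] for i in range(len(rows_jac))]

    def mult(self, k: int) -> AffinePoint:
        if k < 0:
            return negate(self.curve, self.mult(-k))
        k %= self.curve.n
        if k == 0:
            return None
        p, a = self.curve.p, self.curve.a
        mask = (1 << _COMB_WINDOW) - 1
        R: _JacPoint = None
        j = 0
        while k:
            d = k & mask
            if d:
                R = _jac_add_mixed(R, self._rows[j][d - 1], p, a)
            k >>= _COMB_WINDOW
            j += 1
        return _jac_to_affine(R, p)
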