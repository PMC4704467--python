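"""Non-interactive zero-knowledge proof that a ciphertext encrypts 0 or 1.

The server must be able to reject "illegal" queries whose components are
not bits — otherwise a malicious client can plant one huge component and
read a database bit straight out of the reply — without learning which bit
each component is.  The proof here is the standard two-branch disjunctive
Chaum–Pedersen sigma protocol over the lifted-ElGamal ciphertext
``(A, B) = (r*G, r*Q + m*G)``:

* branch 0 proves knowledge of ``r`` with ``A = r*G`` and ``B = r*Q``;
* branch 1 proves the same for ``B - G`` in place of ``B``.

The real branch is run honestly, the other branch is simulated, and the
two challenges are forced to sum to a Fiat–Shamir hash of the full
transcript (domain-separated SHA-256 over the fixed serialization), which
makes the proof non-interactive and binds it to the exact ciphertext and
public key.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

from . import _ec
from .crypto import (
    Ciphertext,
    CryptoError,
    PublicKey,
    RngLike,
    random_scalar,
    _POINT_BYTES,
    _SCALAR_BYTES,
)
from ._ec import AffinePoint

_DOMAIN_TAG = b"sscc/bitproof/v1"


@dataclass(frozen=True)
class BitProof:
    """Transcript of the disjunctive proof: per-branch commitment pairs,
    challenges and responses.  Valid iff the challenges sum to the
    Fiat–Shamir hash and both branch verification equations hold."""

    e0: int
    e1: int
    s0: int
    s1: int
    a0: AffinePoint
    b0: AffinePoint
    a1: AffinePoint
    b1: AffinePoint

    def to_hex(self, pk: PublicKey) -> str:
        spec = pk.spec
        parts = [e.to_bytes(_SCALAR_BYTES, "big") for e in (self.e0, self.e1, self.s0, self.s1)]
        parts += [spec.point_to_bytes(P) for P in (self.a0, self.b0, self.a1, self.b1)]
        return b"".join(parts).hex()

    @classmethod
    def from_hex(cls, pk: PublicKey, data: str) -> "BitProof":
        raw = bytes.fromhex(data)
        if len(raw) != 4 * _SCALAR_BYTES + 4 * _POINT_BYTES:
            raise CryptoError("bit proof encoding has wrong length")
        scalars = [int.from_bytes(raw[i * _SCALAR_BYTES:(i + 1) * _SCALAR_BYTES], "big")
                   for i in range(4)]
        off = 4 * _SCALAR_BYTES
        points = [pk.spec.point_from_bytes(raw[off + i * _POINT_BYTES:off + (i + 1) * _POINT_BYTES])
                  for i in range(4)]
        return cls(*scalars, *points)


def fiat_shamir_challenge(pk: PublicKey, ct: Ciphertext,
                          a0: AffinePoint, b0: AffinePoint,
                          a1: AffinePoint, b1: AffinePoint) -> int:
    """Hash the transcript to a scalar (mod group order)."""
    spec = pk.spec
    h = hashlib.sha256()
    h.update(_DOMAIN_TAG)
    h.update(spec.name.encode())
    for P in (pk.point, ct.c1, ct.c2, a0, b0, a1, b1):
        h.update(spec.point_to_bytes(P))
    return int.from_bytes(h.digest(), "big") % spec.order


def _branch_statement(pk: PublicKey, ct: Ciphertext, branch: int) -> AffinePoint:
    """B - branch*G: the point that must equal r*Q on this branch."""
    curve = pk.spec.curve
    if branch == 0:
        return ct.c2
    return _ec.affine_add(curve, ct.c2, _ec.negate(curve, pk.spec.generator))


def _simulate_branch(pk: PublicKey, ct: Ciphertext, branch: int,
                     e: int, s: int) -> tuple[AffinePoint, AffinePoint]:
    """Commitments that make (e, s) verify on ``branch`` without a witness."""
    curve = pk.spec.curve
    a = _ec.affine_add(curve, pk._mult_g(s),
                       _ec.scalar_mult(curve, -e, ct.c1))
    b = _ec.affine_add(curve, pk._mult_pk(s),
                       _ec.scalar_mult(curve, -e, _branch_statement(pk, ct, branch)))
    return a, b


def prove_bit(pk: PublicKey, m: int, randomness: int, ct: Ciphertext,
              rng: Optional[RngLike] = None) -> BitProof:
    """Prove that ``ct = Enc(m; randomness)`` encrypts a bit.

    Running the prover with ``m`` outside {0, 1} still produces a
    transcript (the nearest branch is used), but one that cannot verify —
    the soundness contract the server relies on.
    """
    order = pk.spec.order
    real = 1 if m >= 1 else 0
    sim = 1 - real
    e_sim = random_scalar(pk.spec, rng)
    s_sim = random_scalar(pk.spec, rng)
    a_sim, b_sim = _simulate_branch(pk, ct, sim, e_sim, s_sim)
    w = random_scalar(pk.spec, rng)
    a_real = pk._mult_g(w)
    b_real = pk._mult_pk(w)
    if real == 0:
        a0, b0, a1, b1 = a_real, b_real, a_sim, b_sim
    else:
        a0, b0, a1, b1 = a_sim, b_sim, a_real, b_real
    e = fiat_shamir_challenge(pk, ct, a0, b0, a1, b1)
    e_real = (e - e_sim) % order
    s_real = (w + e_real * randomness) % order
    if real == 0:
        return BitProof(e_real, e_sim, s_real, s_sim, a0, b0, a1, b1)
    return BitProof(e_sim, e_real, s_sim, s_real, a0, b0, a1, b1)


def _check_equations(pk: PublicKey, ct: Ciphertext, proof: BitProof) -> bool:
    """Both branches' verification equations (challenge split not checked)."""
    curve = pk.spec.curve
    for branch, e, s, a, b in ((0, proof.e0, proof.s0, proof.a0, proof.b0),
                               (1, proof.e1, proof.s1, proof.a1, proof.b1)):
        lhs = pk._mult_g(s)
        rhs = _ec.affine_add(curve, a, _ec.scalar_mult(curve, e, ct.c1))
        if lhs != rhs:
            return False
        lhs = pk._mult_pk(s)
        rhs = _ec.affine_add(curve, b,
                             _ec.scalar_mult(curve, e, _branch_statement(pk, ct, branch)))
        if lhs != rhs:
            return False
    return True


def verify_with_challenge(pk: PublicKey, ct: Ciphertext, proof: BitProof,
                          challenge: int) -> bool:
    """Interactive-protocol check against an externally supplied challenge
    (used by the special-honest-verifier simulator tests)."""
    try:
        if (proof.e0 + proof.e1) % pk.spec.order != challenge % pk.spec.order:
            return False
        return _check_equations(pk, ct, proof)
    except Exception:
        return False


def verify_bit(pk: PublicKey, ct: Ciphertext, proof: BitProof) -> bool:
    """True iff ``proof`` is a valid bit proof for exactly this ciphertext
    under this public key.  Malformed inputs are rejected, never raised."""
    try:
        e = fiat_shamir_challenge(pk, ct, proof.a0, proof.b0, proof.a1, proof.b1)
        return verify_with_challenge(pk, ct, proof, e)
    except Exception:
        return False


def simulate_transcript(pk: PublicKey, ct: Ciphertext, challenge: int,
                        rng: Optional[RngLike] = None) -> BitProof:
    """Special-honest-verifier simulator: a transcript for an arbitrary
    challenge, produced without the encryption randomness.  Its existence
    (and acceptance by :func:`verify_with_challenge`) is what makes the
    proof zero-knowledge."""
    order = pk.spec.order
    e0 = random_scalar(pk.spec, rng)
    e1 = (challenge - e0) % order
    s0 = random_scalar(pk.spec, rng)
    s1 = random_scalar(pk.spec, rng)
    a0, b0 = _simulate_branch(pk, ct, 0, e0, s0)
    a1, b1 = _simulate_branch(pk, ct, 1, e1, s1)
    return BitProof(e0, e1, s0, s1, a0, b0, a1, b1)
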