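"""The secure similar compounds counter: client and server sides.

One search is two messages.  The client encrypts its query fingerprint
bit-by-bit under its own key and attaches a zero-knowledge bit proof per
ciphertext; the server verifies the proofs (rejecting illegal queries),
homomorphically evaluates the integer threshold Tversky score of the query
against every database entry, pads the encrypted scores with ``n`` dummy
ciphertexts drawn from the score domain, shuffles everything, and returns
the multiset together with the number ``s_d`` of non-negative dummies.
The client decrypts, counts the non-negative plaintexts ``s_c``, and
``s_c − s_d`` is the number of similar compounds — the only thing either
party learns.

Notably the server computes Enc(−|q|) from the query ciphertexts itself
rather than asking the client for it: a client-supplied |q| would need its
own validity proof to be trusted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import crypto
from .bitproof import BitProof, prove_bit, verify_bit
from .crypto import (
    Ciphertext,
    KeyPair,
    PlaintextRange,
    PublicKey,
    RngLike,
    random_scalar,
)
from .fingerprints import Fingerprint, popcount
from .tversky import LambdaParams, TverskyParams, derive_lambdas, score_range


class ProtocolError(Exception):
    pass


class InvalidQueryError(ProtocolError):
    """Query failed bit-proof verification; the server refuses to score it."""


@dataclass
class QueryMessage:
    """Client → server: ℓ ciphertexts of the query bits plus ℓ bit proofs."""

    pk: PublicKey
    enc_bits: list[Ciphertext]
    proofs: list[BitProof]
    params: Optional[TverskyParams] = None

    @property
    def length(self) -> int:
        return len(self.enc_bits)


@dataclass(frozen=True)
class DummyConfig:
    """How the server pads its reply.

    ``domain`` defaults to the full integer score range for the session's
    fingerprint length and λ parameters — the "possible values" the uniform
    dummy analysis assumes.  ``distribution`` optionally gives categorical
    weights over that domain (e.g. a perturbed near-uniform distribution for
    the security experiments).
    """

    n: int = 10_000
    domain: Optional[tuple[int, int]] = None
    distribution: Optional[tuple[float, ...]] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 0:
            raise ProtocolError("dummy count must be non-negative")
        if self.distribution is not None:
            if self.domain is None:
                raise ProtocolError("explicit distribution requires an explicit domain")
            width = self.domain[1] - self.domain[0] + 1
            if len(self.distribution) != width:
                raise ProtocolError("distribution length must match domain width")
            if any(w < 0 for w in self.distribution):
                raise ProtocolError("distribution weights must be non-negative")
            total = sum(self.distribution)
            if abs(total - 1.0) > 1e-9:
                raise ProtocolError("distribution weights must sum to 1")


@dataclass
class ReplyMessage:
    """Server → client: shuffled M+n ciphertexts and the dummy count s_d."""

    items: list[Ciphertext]
    s_d: int


@dataclass(frozen=True)
class SearchResult:
    """Client-side outcome: s_c non-negative decryptions, count = s_c − s_d."""

    s_c: int
    s_d: int

    @property
    def count(self) -> int:
        return self.s_c - self.s_d


# ---------------------------------------------------------------------------
# Client side

def build_query(keys: KeyPair, q: Fingerprint,
                rng: Optional[RngLike] = None) -> QueryMessage:
    """Encrypt each query bit under the client's key, with a bit proof."""
    pk = keys.pk
    enc_bits: list[Ciphertext] = []
    proofs: list[BitProof] = []
    for bit in q.bits:
        r = random_scalar(pk.spec, rng)
        ct = crypto.encrypt(pk, bit, randomness=r)
        enc_bits.append(ct)
        proofs.append(prove_bit(pk, bit, r, ct, rng=rng))
    return QueryMessage(pk=pk, enc_bits=enc_bits, proofs=proofs)


def evaluate_reply(keys: KeyPair, reply: ReplyMessage,
                   prange: PlaintextRange) -> SearchResult:
    """Decrypt the reply, count non-negative values, subtract s_d."""
    s_c = 0
    for ct in reply.items:
        if crypto.decrypt(keys, ct, prange) >= 0:
            s_c += 1
    return SearchResult(s_c=s_c, s_d=reply.s_d)


# ---------------------------------------------------------------------------
# Server side

def verify_query(msg: QueryMessage) -> bool:
    """True iff every bit proof verifies against its own ciphertext."""
    if len(msg.proofs) != len(msg.enc_bits):
        return False
    return all(verify_bit(msg.pk, ct, proof)
               for ct, proof in zip(msg.enc_bits, msg.proofs))


def encrypted_scores(msg: QueryMessage, db: Sequence[Fingerprint],
                     lam: LambdaParams, *, verified: bool = False,
                     rng: Optional[RngLike] = None) -> list[Ciphertext]:
    """Homomorphic threshold scores t_j of the query against each entry.

    Each t_j decrypts to λ1|p⁽ʲ⁾∩q| − λ2|p⁽ʲ⁾| − λ3|q| and is rerandomized
    before release.  Unless ``verified`` asserts that :func:`verify_query`
    already passed, the proofs are (re)checked and an invalid query is
    refused before any scoring.
    """
    if not verified and not verify_query(msg):
        raise InvalidQueryError("query failed bit-proof verification; refusing to score")
    pk = msg.pk
    ell = msg.length
    spec = pk.spec
    # Enc(-|q|) derived from the query itself: -1 ⊗ (⊕_i Enc(q_i))
    acc = crypto.zero_ciphertext(spec)
    for ct in msg.enc_bits:
        acc = crypto.add(acc, ct)
    enc_neg_q = crypto.scalar_mul(-1, acc)
    lam3_neg_q = crypto.scalar_mul(lam.lambda3, enc_neg_q)
    out: list[Ciphertext] = []
    for p in db:
        if p.length != ell:
            raise ProtocolError(
                f"database entry length {p.length} does not match query length {ell}")
        c = crypto.zero_ciphertext(spec)
        for k, bit in enumerate(p.bits):
            if bit:
                c = crypto.add(c, msg.enc_bits[k])
        enc_neg_p = crypto.encrypt(pk, -popcount(p), rng=rng)
        t = crypto.add(crypto.scalar_mul(lam.lambda1, c),
                       crypto.scalar_mul(lam.lambda2, enc_neg_p))
        t = crypto.add(t, lam3_neg_q)
        out.append(crypto.rerandomize(pk, t, rng=rng))
    return out


def make_dummies(pk: PublicKey, cfg: DummyConfig,
                 rng: Optional[RngLike] = None) -> tuple[list[Ciphertext], int]:
    """Draw and encrypt n dummy scores; also return s_d = #{φ_i ≥ 0}."""
    if cfg.domain is None:
        raise ProtocolError("dummy domain not set; pass score_range(ℓ, λ)")
    if rng is None:
        rng = random.Random(cfg.seed) if cfg.seed is not None else random.SystemRandom()
    lo, hi = cfg.domain
    if cfg.distribution is None:
        values = [rng.randrange(lo, hi + 1) for _ in range(cfg.n)]
    else:
        values = rng.choices(range(lo, hi + 1), weights=cfg.distribution, k=cfg.n)
    s_d = sum(1 for v in values if v >= 0)
    cts = [crypto.encrypt(pk, v, rng=rng) for v in values]
    return cts, s_d


def assemble_reply(scores: Sequence[Ciphertext], dummies: Sequence[Ciphertext],
                   s_d: int, seed: Optional[int] = None,
                   rng: Optional[RngLike] = None) -> ReplyMessage:
    """Uniformly shuffle true scores and dummies into one reply."""
    if rng is None:
        rng = random.Random(seed) if seed is not None else random.SystemRandom()
    items = list(scores) + list(dummies)
    rng.shuffle(items)
    return ReplyMessage(items=items, s_d=s_d)


# ---------------------------------------------------------------------------
# End to end

def decode_range_for(length: int, lam: LambdaParams,
                     cfg: Optional[DummyConfig] = None) -> PlaintextRange:
    """Decode interval covering both true scores and the dummy domain, so
    honest decryption can never fail."""
    lo, hi = score_range(length, lam)
    if cfg is not None and cfg.domain is not None:
        lo = min(lo, cfg.domain[0])
        hi = max(hi, cfg.domain[1])
    return PlaintextRange(lo, hi)


def run_protocol(q: Fingerprint, db: Sequence[Fingerprint],
                 params: TverskyParams, cfg: Optional[DummyConfig] = None,
                 seed: Optional[int] = None,
                 spec: Optional[crypto.GroupSpec] = None) -> SearchResult:
    """Execute one full search: keygen, query, verify, score, pad, count.

    ``seed`` makes the whole run reproducible (test mode); without it every
    random choice uses the system CSPRNG.
    """
    spec = spec or crypto.GroupSpec()
    lam = derive_lambdas(params)
    if cfg is None:
        cfg = DummyConfig()
    if cfg.domain is None:
        cfg = DummyConfig(n=cfg.n, domain=score_range(q.length, lam),
                          distribution=None, seed=cfg.seed)
    rng: Optional[RngLike] = random.Random(seed) if seed is not None else None
    keys = crypto.key_gen(spec, seed=rng.randrange(2 ** 31) if rng else None)
    msg = build_query(keys, q, rng=rng)
    msg.params = params
    if not verify_query(msg):
        raise InvalidQueryError("honest query unexpectedly failed verification")
    scores = encrypted_scores(msg, db, lam, verified=True, rng=rng)
    dummies, s_d = make_dummies(keys.pk, cfg, rng=rng)
    reply = assemble_reply(scores, dummies, s_d, rng=rng)
    return evaluate_reply(keys, reply, decode_range_for(q.length, lam, cfg))


# ---------------------------------------------------------------------------
# Message serialization (single-document text, hex payloads)

_PROTOCOL_VERSION = "sscc/1"


def query_to_text(msg: QueryMessage) -> str:
    if msg.params is None:
        raise ProtocolError("query message lacks similarity parameters")
    p = msg.params
    doc = {
        "format": "sscc-query/1",
        "protocol": _PROTOCOL_VERSION,
        "group": msg.pk.spec.name,
        "length": msg.length,
        "params": {"mu_a": p.mu_a, "mu_b": p.mu_b, "gamma": p.gamma,
                   "theta_n": p.theta_n, "theta_d": p.theta_d},
        "pk": msg.pk.spec.point_to_bytes(msg.pk.point).hex(),
        "bits": [{"ct": ct.to_hex(), "proof": proof.to_hex(msg.pk)}
                 for ct, proof in zip(msg.enc_bits, msg.proofs)],
    }
    return json.dumps(doc)


def query_from_text(text: str) -> QueryMessage:
    doc = json.loads(text)
    if doc.get("format") != "sscc-query/1":
        raise ProtocolError("not an sscc query document")
    spec = crypto.GroupSpec(doc["group"])
    pk = PublicKey(spec, spec.point_from_bytes(bytes.fromhex(doc["pk"])))
    pp = doc["params"]
    params = TverskyParams(mu_a=pp["mu_a"], mu_b=pp["mu_b"], gamma=pp["gamma"],
                           theta_n=pp["theta_n"], theta_d=pp["theta_d"])
    enc_bits, proofs = [], []
    for item in doc["bits"]:
        enc_bits.append(Ciphertext.from_hex(spec, item["ct"]))
        proofs.append(BitProof.from_hex(pk, item["proof"]))
    if len(enc_bits) != doc["length"]:
        raise ProtocolError("query length field does not match payload")
    return QueryMessage(pk=pk, enc_bits=enc_bits, proofs=proofs, params=params)


def reply_to_text(reply: ReplyMessage, decode_range: PlaintextRange) -> str:
    doc = {
        "format": "sscc-reply/1",
        "protocol": _PROTOCOL_VERSION,
        "s_d": reply.s_d,
        "range": [decode_range.lo, decode_range.hi],
        "items": [ct.to_hex() for ct in reply.items],
    }
    return json.dumps(doc)


def reply_from_text(text: str, spec: Optional[crypto.GroupSpec] = None
                    ) -> tuple[ReplyMessage, PlaintextRange]:
    doc = json.loads(text)
    if doc.get("format") != "sscc-reply/1":
        raise ProtocolError("not an sscc reply document")
    spec = spec or crypto.GroupSpec()
    items = [Ciphertext.from_hex(spec, h) for h in doc["items"]]
    prange = PlaintextRange(doc["range"][0], doc["range"][1])
    return ReplyMessage(items=items, s_d=doc["s_d"]), prange
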