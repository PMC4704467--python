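"""Binary molecular fingerprints: representation, FPS-style I/O, synthesis.

A fingerprint is a fixed-length bit vector recording presence/absence of
structural keys in a molecule (the 166-bit MACCS keys being the standard
variant for compound similarity search).  Files use an FPS-style text
dialect: ``#`` header lines including ``#num_bits=<ℓ>``, then one
``<hex>\\t<id>`` record per line.  Hex bytes run left to right; within each
byte bit 0 is the least significant bit, so fingerprint index ``i``
(0-based) lives in byte ``i // 8`` at bit ``i % 8``.  Pad bits beyond ℓ in
the last byte must be zero — the serialization is canonical.

The synthetic generator draws i.i.d. Bernoulli bits and stands in for a
real compound collection; an optional blockwise-correlated mode mimics the
co-occurrence of related structural keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

import numpy as np


class FingerprintError(ValueError):
    """Invalid fingerprint data or malformed FPS input."""


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit vector; equivalently the set of indices set to 1."""

    bits: tuple[int, ...]
    id: Optional[str] = None

    def __post_init__(self):
        if len(self.bits) == 0:
            raise FingerprintError("fingerprint length must be positive")
        if any(b not in (0, 1) for b in self.bits):
            raise FingerprintError("fingerprint bits must be 0 or 1")

    @property
    def length(self) -> int:
        return len(self.bits)

    def indices(self) -> frozenset[int]:
        """The index set {i : bit i = 1} (0-based)."""
        return frozenset(i for i, b in enumerate(self.bits) if b)

    @classmethod
    def from_indices(cls, length: int, indices: Iterable[int],
                     id: Optional[str] = None) -> "Fingerprint":
        idx = set(indices)
        if idx and (min(idx) < 0 or max(idx) >= length):
            raise FingerprintError("index out of range")
        return cls(tuple(1 if i in idx else 0 for i in range(length)), id=id)

    def __len__(self) -> int:
        return len(self.bits)


def popcount(fp: Fingerprint) -> int:
    """Number of set bits |p|."""
    return sum(fp.bits)


def intersection_size(a: Fingerprint, b: Fingerprint) -> int:
    """|a ∩ b| for two fingerprints of equal length."""
    if a.length != b.length:
        raise FingerprintError(
            f"length mismatch: {a.length} vs {b.length}")
    return sum(x & y for x, y in zip(a.bits, b.bits))


# ---------------------------------------------------------------------------
# FPS-style text I/O

def _hex_to_bits(hexstr: str, num_bits: int) -> tuple[int, ...]:
    nbytes = (num_bits + 7) // 8
    if len(hexstr) != 2 * nbytes:
        raise FingerprintError(
            f"hex field has {len(hexstr)} chars, expected {2 * nbytes} for {num_bits} bits")
    try:
        raw = bytes.fromhex(hexstr)
    except ValueError as exc:
        raise FingerprintError(f"malformed hex: {exc}") from exc
    bits = []
    for i in range(num_bits):
        bits.append((raw[i // 8] >> (i % 8)) & 1)
    for i in range(num_bits, 8 * nbytes):  # canonical padding
        if (raw[i // 8] >> (i % 8)) & 1:
            raise FingerprintError("nonzero pad bits beyond declared num_bits")
    return tuple(bits)


def _bits_to_hex(bits: Sequence[int]) -> str:
    nbytes = (len(bits) + 7) // 8
    raw = bytearray(nbytes)
    for i, b in enumerate(bits):
        if b:
            raw[i // 8] |= 1 << (i % 8)
    return raw.hex()


def read_fps(stream: Union[TextIO, Iterable[str]]) -> list[Fingerprint]:
    """Parse an FPS-style text stream into fingerprints.

    Raises :class:`FingerprintError` naming the offending line on malformed
    hex, a missing ``#num_bits`` header, or a length mismatch.
    """
    num_bits: Optional[int] = None
    out: list[Fingerprint] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#num_bits="):
                try:
                    num_bits = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise FingerprintError(f"line {lineno}: bad #num_bits header") from exc
                if num_bits <= 0:
                    raise FingerprintError(f"line {lineno}: num_bits must be positive")
            continue
        if num_bits is None:
            raise FingerprintError(f"line {lineno}: data before #num_bits header")
        fields = line.split("\t")
        hexstr = fields[0].strip()
        fp_id = fields[1] if len(fields) > 1 else None
        try:
            bits = _hex_to_bits(hexstr, num_bits)
        except FingerprintError as exc:
            raise FingerprintError(f"line {lineno}: {exc}") from exc
        out.append(Fingerprint(bits, id=fp_id))
    return out


def write_fps(stream: TextIO, fingerprints: Sequence[Fingerprint],
              num_bits: Optional[int] = None) -> None:
    """Write fingerprints in the FPS-style dialect read by :func:`read_fps`."""
    if num_bits is None:
        if not fingerprints:
            raise FingerprintError("num_bits required for an empty collection")
        num_bits = fingerprints[0].length
    stream.write(f"#num_bits={num_bits}\n")
    for i, fp in enumerate(fingerprints):
        if fp.length != num_bits:
            raise FingerprintError(
                f"fingerprint {i} has length {fp.length}, expected {num_bits}")
        label = fp.id if fp.id is not None else f"FP{i}"
        stream.write(f"{_bits_to_hex(fp.bits)}\t{label}\n")


# ---------------------------------------------------------------------------
# Synthetic generation

def random_fingerprints(count: int, length: int, density: float,
                        seed: Optional[int] = None,
                        block_size: Optional[int] = None,
                        block_activity: float = 0.5) -> list[Fingerprint]:
    """Generate ``count`` random fingerprints of ``length`` bits.

    By default each bit is independently 1 with probability ``density``.
    With ``block_size`` set, a blockwise-correlated mode is used instead:
    each block of adjacent keys is active with probability
    ``block_activity`` and bits inside active blocks fire with probability
    ``density / block_activity`` (capped at 1), preserving the marginal
    density while inducing within-block correlation.
    """
    if not 0.0 <= density <= 1.0:
        raise FingerprintError("density must be a probability")
    rng = np.random.default_rng(seed)
    if block_size is None:
        mat = rng.random((count, length)) < density
    else:
        if block_size <= 0 or not 0.0 < block_activity <= 1.0:
            raise FingerprintError("invalid block parameters")
        nblocks = (length + block_size - 1) // block_size
        active = rng.random((count, nblocks)) < block_activity
        active_bits = np.repeat(active, block_size, axis=1)[:, :length]
        p_in = min(1.0, density / block_activity)
        mat = active_bits & (rng.random((count, length)) < p_in)
    return [Fingerprint(tuple(int(b) for b in row), id=f"RND{i}")
            for i, row in enumerate(mat)]
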