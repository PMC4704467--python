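"""Tversky similarity and its integer "threshold" rescaling.

The Tversky index of two fingerprints (as index sets) is

    TI_{α,β}(p, q) = |p∩q| / (|p∩q| + α|p\\q| + β|q\\p|),

with α = β = 1 the Jaccard/Tanimoto index and α = β = 1/2 the Dice index.
A similarity search asks whether TI ≥ θ.  With rational parameters
α = μa/γ, β = μb/γ, θ = θn/θd, that predicate is equivalent to the sign of
an integer linear form

    λ1·|p∩q| − λ2·|p| − λ3·|q|  ≥ 0,

where the non-negative integers λ1, λ2, λ3 come from clearing denominators
and dividing by g = gcd(γ(θd−θn) + θn(μa+μb), θn·μa, θn·μb).  The linear
form is what the encrypted protocol evaluates: it needs only additions and
integer scalings, both available homomorphically, and its small range keeps
lifted-ElGamal decryption cheap.

All arithmetic here is exact (integers and fractions); sign decisions are
never made in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence, Union

from .fingerprints import Fingerprint, intersection_size, popcount


class ParameterError(ValueError):
    """Invalid Tversky/threshold parameters."""


def parse_fraction(value: Union[str, int, Fraction]) -> Fraction:
    """Parse "N/D" strings (or integers) into an exact fraction.

    Decimal floats are deliberately rejected: similarity thresholds must be
    exact for the sign equivalence to hold.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        try:
            if "/" in value:
                num, den = value.split("/", 1)
                return Fraction(int(num), int(den))
            return Fraction(int(value))
        except (ValueError, ZeroDivisionError) as exc:
            raise ParameterError(f"bad fraction {value!r}: expected 'N/D' or integer") from exc
    raise ParameterError(f"bad fraction {value!r}: floats are not accepted")


@dataclass(frozen=True)
class TverskyParams:
    """Rational similarity parameters α = μa/γ, β = μb/γ, θ = θn/θd."""

    mu_a: int
    mu_b: int
    gamma: int
    theta_n: int
    theta_d: int

    def __post_init__(self):
        if self.gamma <= 0 or self.theta_d <= 0:
            raise ParameterError("gamma and theta_d must be positive")
        if self.mu_a <= 0 or self.mu_b <= 0:
            raise ParameterError("alpha and beta must be positive (mu_a, mu_b >= 1)")
        if self.theta_n <= 0 or self.theta_n > self.theta_d:
            raise ParameterError("theta must satisfy 0 < theta <= 1")

    @property
    def alpha(self) -> Fraction:
        return Fraction(self.mu_a, self.gamma)

    @property
    def beta(self) -> Fraction:
        return Fraction(self.mu_b, self.gamma)

    @property
    def theta(self) -> Fraction:
        return Fraction(self.theta_n, self.theta_d)

    @classmethod
    def from_fractions(cls, alpha: Union[str, int, Fraction] = 1,
                       beta: Union[str, int, Fraction] = 1,
                       theta: Union[str, int, Fraction] = Fraction(4, 5)) -> "TverskyParams":
        """Build from α, β, θ given as "N/D" strings, integers or fractions.

        α and β are put over the common denominator γ = lcm of theirs.
        """
        fa, fb, ft = parse_fraction(alpha), parse_fraction(beta), parse_fraction(theta)
        if fa <= 0 or fb <= 0:
            raise ParameterError("alpha and beta must be positive")
        g = gcd(fa.denominator, fb.denominator)
        gamma = fa.denominator * fb.denominator // g
        return cls(
            mu_a=int(fa * gamma),
            mu_b=int(fb * gamma),
            gamma=gamma,
            theta_n=ft.numerator,
            theta_d=ft.denominator,
        )


@dataclass(frozen=True)
class LambdaParams:
    """Derived integer coefficients of the threshold score, gcd-normalized."""

    lambda1: int
    lambda2: int
    lambda3: int
    g: int

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0 or self.g <= 0:
            raise ParameterError("lambda parameters must be non-negative, g positive")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.lambda1, self.lambda2, self.lambda3)


def derive_lambdas(params: TverskyParams) -> LambdaParams:
    """Integer coefficients (λ1, λ2, λ3) whose linear form shares its sign
    with the predicate TI ≥ θ.

    g is the gcd of γ(θd−θn) + θn(μa+μb), θn·μa and θn·μb; dividing by it
    makes the coefficients coprime and as small as possible.
    """
    head = params.gamma * (params.theta_d - params.theta_n) \
        + params.theta_n * (params.mu_a + params.mu_b)
    ta = params.theta_n * params.mu_a
    tb = params.theta_n * params.mu_b
    g = gcd(head, ta, tb)
    return LambdaParams(head // g, ta // g, tb // g, g)


def tversky_index(p: Fingerprint, q: Fingerprint,
                  params: TverskyParams) -> Fraction:
    """Exact Tversky index TI_{α,β}(p, q) as a fraction in [0, 1].

    Undefined (raises) when both fingerprints are empty — the 0/0 case.
    """
    c = intersection_size(p, q)
    a, b = popcount(p), popcount(q)
    if a == 0 and b == 0:
        raise ParameterError("Tversky index undefined for two empty fingerprints")
    denom = c + params.alpha * (a - c) + params.beta * (b - c)
    return Fraction(c) / denom


def threshold_tversky(p: Fingerprint, q: Fingerprint, lam: LambdaParams) -> int:
    """Integer score λ1|p∩q| − λ2|p| − λ3|q|.

    Non-negative exactly when TI ≥ θ wherever TI is defined.  For the
    empty/empty pair (TI undefined) the score is 0, so the protocol counts
    the pair as similar.
    """
    if p.length != q.length:
        raise ParameterError(f"length mismatch: {p.length} vs {q.length}")
    c = intersection_size(p, q)
    return lam.lambda1 * c - lam.lambda2 * popcount(p) - lam.lambda3 * popcount(q)


def score_range(length: int, lam: LambdaParams) -> tuple[int, int]:
    """Exact (min, max) of the integer score over all fingerprint pairs.

    Enumerates the feasible cardinality cells (a, b) with the
    inclusion–exclusion bounds max(0, a+b−ℓ) ≤ c ≤ min(a, b); within a
    cell the score is monotone in c, so only the two extremes matter.
    """
    lo = hi = 0  # a = b = 0 is always feasible with score 0
    l1, l2, l3 = lam.lambda1, lam.lambda2, lam.lambda3
    for a in range(length + 1):
        base_a = -l2 * a
        for b in range(length + 1):
            base = base_a - l3 * b
            cmin = a + b - length
            if cmin < 0:
                cmin = 0
            cmax = a if a < b else b
            s_min = base + l1 * cmin
            s_max = base + l1 * cmax
            if s_min < lo:
                lo = s_min
            if s_max > hi:
                hi = s_max
    return (lo, hi)


def range_size(length: int, lam: LambdaParams) -> int:
    """k = max − min + 1: the size of the integer score interval, which is
    the number of possible dummy values in the padding analysis."""
    lo, hi = score_range(length, lam)
    return hi - lo + 1


def is_similar(p: Fingerprint, q: Fingerprint, params: TverskyParams) -> bool:
    """Plaintext similarity predicate TI ≥ θ, with the empty/empty pair
    counted as similar (matching the integer score's convention)."""
    if popcount(p) == 0 and popcount(q) == 0:
        return True
    return tversky_index(p, q, params) >= params.theta


def count_similar(q: Fingerprint, db: Iterable[Fingerprint],
                  params: TverskyParams) -> int:
    """Plaintext count of database entries similar to the query."""
    return sum(1 for p in db if is_similar(p, q, params))
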