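"""Protocol configuration: defaults, validation, file round trip.

Defaults follow the standard compound-search operating point: 166-bit
MACCS-style fingerprints, Jaccard similarity (α = β = 1) with threshold
θ = 4/5, 10,000 dummies, the secp192k1 group.  Similarity parameters are
accepted only as exact fractions ("N/D" strings or integers) — never as
decimal floats, since the sign equivalence of the integer score demands
exact rationals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

from .crypto import GroupSpec, PlaintextRange
from .protocol import DummyConfig
from .tversky import (
    ParameterError,
    TverskyParams,
    derive_lambdas,
    score_range,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolConfig:
    length: int = 166
    params: TverskyParams = field(
        default_factory=lambda: TverskyParams(mu_a=1, mu_b=1, gamma=1, theta_n=4, theta_d=5))
    dummies: DummyConfig = field(default_factory=DummyConfig)
    group: str = "secp192k1"
    seed_policy: str = "secure"  # "secure" | "test"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigError("length: must be positive")
        if self.seed_policy not in ("secure", "test"):
            raise ConfigError("seed_policy: must be 'secure' or 'test'")
        if self.seed is not None and self.seed_policy != "test":
            raise ConfigError("seed: only honored under seed_policy 'test'")
        GroupSpec(self.group)  # raises on unknown group
        derive_lambdas(self.params)  # raises on invalid similarity parameters

    def lambdas(self):
        return derive_lambdas(self.params)

    def decode_range(self) -> PlaintextRange:
        lo, hi = score_range(self.length, self.lambdas())
        if self.dummies.domain is not None:
            lo = min(lo, self.dummies.domain[0])
            hi = max(hi, self.dummies.domain[1])
        return PlaintextRange(lo, hi)

    def effective_dummies(self) -> DummyConfig:
        """Dummy config with the domain defaulted to the score range."""
        if self.dummies.domain is not None:
            return self.dummies
        return DummyConfig(n=self.dummies.n, domain=score_range(self.length, self.lambdas()),
                           distribution=None, seed=self.dummies.seed)


def load_config(path: Optional[str] = None, **flags) -> ProtocolConfig:
    """Build a validated config from an optional JSON file plus overrides.

    Recognized keys: length, alpha, beta, theta (fraction strings or
    integers), dummies, group, seed_policy, seed.  Command-line flags win
    over file values.  Raises :class:`ConfigError` naming the bad key.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            try:
                values.update(json.load(fh))
            except json.JSONDecodeError as exc:
                raise ConfigError(f"config file {path}: not valid JSON ({exc})") from exc
    values.update({k: v for k, v in flags.items() if v is not None})

    def fraction_key(key: str, default):
        try:
            from .tversky import parse_fraction
            return parse_fraction(values.get(key, default))
        except ParameterError as exc:
            raise ConfigError(f"{key}: {exc}") from exc

    alpha = fraction_key("alpha", 1)
    beta = fraction_key("beta", 1)
    theta = fraction_key("theta", "4/5")
    try:
        params = TverskyParams.from_fractions(alpha=alpha, beta=beta, theta=theta)
    except ParameterError as exc:
        raise ConfigError(f"alpha/beta/theta: {exc}") from exc
    try:
        dummies = DummyConfig(n=int(values.get("dummies", 10_000)))
    except Exception as exc:
        raise ConfigError(f"dummies: {exc}") from exc
    try:
        return ProtocolConfig(
            length=int(values.get("length", 166)),
            params=params,
            dummies=dummies,
            group=values.get("group", "secp192k1"),
            seed_policy=values.get("seed_policy", "secure"),
            seed=values.get("seed"),
        )
    except (ConfigError, ParameterError) as exc:
        raise
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: ProtocolConfig) -> str:
    """Serialize a config to canonical JSON (load ∘ dump is the identity
    up to normalization of the fraction fields)."""
    p = cfg.params
    doc = {
        "length": cfg.length,
        "alpha": f"{p.mu_a}/{p.gamma}",
        "beta": f"{p.mu_b}/{p.gamma}",
        "theta": f"{p.theta_n}/{p.theta_d}",
        "dummies": cfg.dummies.n,
        "group": cfg.group,
        "seed_policy": cfg.seed_policy,
    }
    if cfg.seed is not None:
        doc["seed"] = cfg.seed
    return json.dumps(doc, indent=1)
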