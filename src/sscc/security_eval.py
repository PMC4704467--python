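"""Simulators quantifying what the protocol's design choices buy.

Three questions are answered empirically, all on plaintext scores (the
analyses concern information disclosure, not the cryptography):

1. How fast does a score-revealing server fall?  A server that returns the
   exact integer threshold score leaks one database bit per unit-vector
   probe: after an all-zero baseline query, ``score(e_i) − score(0)`` is
   positive exactly when bit i of the hidden entry is set, so ℓ probes
   recover a length-ℓ fingerprint deterministically
   (:func:`plain_score_attack`).

2. How safe is a sign-only server?  :func:`hit_probability` Monte-Carlo
   estimates the chance that x random queries produce even one "hit"
   (positive score) — the prerequisite for any regression attack when only
   the sign is revealed.

3. How well do dummies hide the true score?  The attacker knows the prior
   ``w`` over the k possible score values and sees the true value buried
   in n dummies.  The optimal single-query guess maximizes ``a_i·w_i``
   (observed count times prior); over L repeated queries the products
   multiply.  :func:`dummy_guess_experiment` measures the attack success
   ratio, which starts at 1 with no dummies and falls to the no-observation
   ideal ``max_i w_i`` as n grows.

Priors and observations are plain probability/count vectors (numpy
arrays); indices into the k possible values are 0-based.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .fingerprints import Fingerprint
from .tversky import LambdaParams

QuerySampler = Callable[[np.random.Generator, int], np.ndarray]

# cap on the entries of one vectorized batch (trials × L × k)
_BATCH_CELLS = 8_000_000


def _check_prior(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("prior must be a 1-D weight vector")
    if (w < 0).any():
        raise ValueError("prior weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("prior weights must sum to 1")
    return w


# ---------------------------------------------------------------------------
# Regression attack against a score-revealing server

def plain_score_attack(oracle: Callable[[Fingerprint], int],
                       length: int) -> tuple[Fingerprint, int]:
    """Recover a hidden fingerprint from an exact-score oracle.

    Sends the all-zero baseline query, then exactly ``length`` unit-vector
    probes; bit i is declared set iff score(e_i) − score(0) > 0.  Returns
    the recovered fingerprint and the number of unit-vector probes used.
    """
    zero = Fingerprint(tuple([0] * length))
    baseline = oracle(zero)
    bits = []
    probes = 0
    for i in range(length):
        probe = Fingerprint.from_indices(length, [i])
        probes += 1
        bits.append(1 if oracle(probe) - baseline > 0 else 0)
    return Fingerprint(tuple(bits)), probes


def uniform_query_sampler(rng: np.random.Generator, length: int) -> np.ndarray:
    """One uniformly random fingerprint as a 0/1 vector."""
    return rng.integers(0, 2, size=length, dtype=np.int64)


def hit_probability(p: Fingerprint, lam: LambdaParams,
                    query_sampler: Optional[QuerySampler] = None,
                    trials: int = 10_000, x: int = 1,
                    seed: Optional[int] = None) -> float:
    """Estimate the chance of at least one hit query among x attempts.

    A "hit" is a query with strictly positive integer score against ``p``
    — the foothold a sign-only regression attack needs.  The single-trial
    hit probability f_p is estimated by Monte Carlo over ``query_sampler``
    (uniform fingerprints by default) and the result is 1 − (1 − f_p)^x.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if x == 0:
        return 0.0
    sampler = query_sampler or uniform_query_sampler
    rng = np.random.default_rng(seed)
    p_arr = np.asarray(p.bits, dtype=np.int64)
    a = int(p_arr.sum())
    hits = 0
    for _ in range(trials):
        q_arr = sampler(rng, p.length)
        c = int(p_arr @ q_arr)
        b = int(q_arr.sum())
        if lam.lambda1 * c - lam.lambda2 * a - lam.lambda3 * b > 0:
            hits += 1
    f_hat = hits / trials
    return 1.0 - (1.0 - f_hat) ** x


# ---------------------------------------------------------------------------
# Guessing strategies against the dummy-padded reply

def _safe_log(x: np.ndarray) -> np.ndarray:
    """Elementwise log with log(0) = -inf and no divide warnings."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)


def _argmax_tiebreak(values: np.ndarray, rng: random.Random) -> int:
    best = values.max()
    ties = np.flatnonzero(values == best)
    if len(ties) == 1:
        return int(ties[0])
    return int(rng.choice(ties))


def best_guess_prior(w, seed: Optional[int] = None) -> int:
    """Optimal guess from the prior alone: argmax w_i, uniform tie-break.

    Its success probability — max_i w_i — is the "ideal" floor no amount
    of dummy padding can go below.
    """
    w = _check_prior(w)
    return _argmax_tiebreak(w, random.Random(seed))


def best_guess_posterior(w, counts, seed: Optional[int] = None) -> int:
    """Optimal guess from one observation: argmax a_i·w_i.

    ``counts`` are the received-value frequencies a_1..a_k over the k
    possible values (the true score plus n uniform dummies).
    """
    w = _check_prior(w)
    a = np.asarray(counts, dtype=float)
    if a.shape != w.shape:
        raise ValueError("counts and prior must have the same length")
    return _argmax_tiebreak(a * w, random.Random(seed))


def multi_query_posterior(w, obs_list: Sequence, seed: Optional[int] = None) -> int:
    """Optimal guess from L repeated-query observations.

    Maximizes the product over queries of a_i^{(j)}·w_i (the per-query
    normalizers do not depend on i); accumulated in log space, any value
    absent from some observation is eliminated outright.
    """
    w = _check_prior(w)
    if len(obs_list) == 0:
        raise ValueError("at least one observation required")
    A = np.asarray(obs_list, dtype=float)
    if A.ndim != 2 or A.shape[1] != w.size:
        raise ValueError("observations must be L x k counts")
    log_scores = _safe_log(A).sum(axis=0) + len(obs_list) * _safe_log(w)
    return _argmax_tiebreak(log_scores, random.Random(seed))


# ---------------------------------------------------------------------------
# Monte-Carlo experiments

def make_random_prior(k: int, m: Optional[int] = None,
                      seed: Optional[int] = None) -> np.ndarray:
    """Synthetic score prior: frequencies of m uniform draws from k values.

    The default m = 5k gives a rough, spiky prior (mean cell count 5)
    mimicking an empirical score histogram without any reference dataset.
    """
    if m is None:
        m = 5 * k
    rng = np.random.default_rng(seed)
    h = np.bincount(rng.integers(0, k, size=m), minlength=k)
    return h / m


@dataclass(frozen=True)
class PerturbedDummyDistribution:
    """Near-uniform dummy weights u_i = r_i/k with r_i ~ N(1, δ²),
    truncated at zero and renormalized."""

    delta: float
    weights: np.ndarray


def perturbed_dummy_distribution(k: int, delta: float,
                                 seed: Optional[int] = None) -> PerturbedDummyDistribution:
    """Dummy distribution the server actually uses when it deviates from
    uniform by relative noise δ (δ = 0 recovers exact uniformity)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta == 0:
        u = np.full(k, 1.0 / k)
        return PerturbedDummyDistribution(delta=0.0, weights=u)
    rng = np.random.default_rng(seed)
    r = rng.normal(1.0, delta, size=k)
    u = np.clip(r, 0.0, None) / k
    total = u.sum()
    if total == 0:
        raise ValueError("all weights truncated to zero; delta too large")
    return PerturbedDummyDistribution(delta=float(delta), weights=u / total)


def dummy_guess_experiment(w, n: int, L: int = 1,
                           dummy_dist=None,
                           trials: int = 10_000,
                           seed: Optional[int] = None) -> float:
    """Fraction of trials in which the optimal guess finds the true score.

    Each trial draws a true value from ``w`` and, for each of the L
    (identical) queries, n dummies from ``dummy_dist`` (uniform by
    default); the attacker — who always assumes uniform dummies — applies
    the single- or multi-query argmax rule with uniform tie-breaking.
    """
    w = _check_prior(w)
    if trials <= 0 or L < 1 or n < 0:
        raise ValueError("trials and L must be positive, n non-negative")
    k = w.size
    dd = np.full(k, 1.0 / k) if dummy_dist is None else _check_prior(dummy_dist)
    if dd.size != k:
        raise ValueError("dummy distribution must cover the same k values")
    rng = np.random.default_rng(seed)
    tie_rng = random.Random(None if seed is None else seed + 0x5ee)
    log_w = _safe_log(w)
    batch = max(1, _BATCH_CELLS // (L * k))
    successes = 0
    done = 0
    while done < trials:
        t = min(batch, trials - done)
        true_idx = rng.choice(k, size=t, p=w)
        if n > 0:
            counts = rng.multinomial(n, dd, size=(t, L))
        else:
            counts = np.zeros((t, L, k), dtype=np.int64)
        counts[np.arange(t), :, true_idx] += 1  # the true value is in every reply
        scores = _safe_log(counts).sum(axis=1) + L * log_w
        best = scores.max(axis=1, keepdims=True)
        is_max = scores == best
        n_ties = is_max.sum(axis=1)
        guesses = scores.argmax(axis=1)
        tied_rows = np.flatnonzero(n_ties > 1)
        for row in tied_rows:
            guesses[row] = tie_rng.choice(np.flatnonzero(is_max[row]))
        successes += int((guesses == true_idx).sum())
        done += t
    return successes / trials
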