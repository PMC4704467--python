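# Methods

## Problem and model

Two parties: a client holding one binary fingerprint `q` of length ℓ and
a server holding a database `P = {p(1), …, p(M)}` of fingerprints of the
same length. The protocol's contract is that the client learns only
`#{j : TI_{α,β}(p(j), q) ≥ θ}` and the server learns nothing about `q`.
The adversary model is semi-honest on the server side (semantic security
of the encryption covers the query unconditionally) and malicious on the
client side to the extent of submitting malformed queries, which the
bit proofs detect; a client deviating in other ways can only hurt its
own output.

## Integer threshold score

All similarity decisions are made through the integer linear form
`λ1|p∩q| − λ2|p| − λ3|q|` with

```
g  = gcd(γ(θd−θn) + θn(μa+μb),  θn·μa,  θn·μb)
λ1 = (γ(θd−θn) + θn(μa+μb)) / g
λ2 = θn·μa / g
λ3 = θn·μb / g
```

The division by g keeps the coefficients coprime and the score range —
hence the decryption table — as small as possible. All parameter
handling is exact (integers / `fractions.Fraction`); decimal floats are
rejected at the interface because the sign equivalence `score ≥ 0 ⟺
TI ≥ θ` must be exact. Score extremes are found by enumerating the
feasible cardinality cells `(a, b) = (|p|, |q|)` with the
inclusion–exclusion bounds `max(0, a+b−ℓ) ≤ c ≤ min(a, b)`; the score is
monotone in `c` inside a cell, so ~(ℓ+1)² cells suffice. The "number of
possible score values" `k` is defined as the size `max − min + 1` of the
inclusive integer interval, although a few interior integers are not
attainable under the inclusion–exclusion constraint; this is the
convention under which k = 831 at ℓ = 166, λ = (9,4,4).

Degenerate input: for the empty/empty pair the Tversky index is 0/0 and
`tversky_index` raises, but the integer score is 0 (≥ 0), so the
protocol counts the pair as similar. The plaintext counter
`count_similar` follows the same convention so the two paths always
agree; the pair is excluded from sign-equivalence tests.

A "hit" in the security analysis means a *strictly* positive score
(TI strictly above θ). Consequently at θ = 1 no query — not even `q = p`,
which scores exactly 0 — is a hit, and the estimated hit probability is
identically zero there.

## Cryptography

* **Group.** secp192k1 (SEC 2), a prime-order short-Weierstrass curve;
  the group abstraction is pluggable but this is the only registered
  backend. Curve arithmetic is implemented in the package (Jacobian
  coordinates, width-4 wNAF for arbitrary bases, comb tables for the
  generator and each public key); it is standard machinery, kept
  self-contained so the protocol has no crypto dependencies.
* **Encryption.** Lifted ElGamal: `Enc(m) = (rG, rQ + mG)`. Negative
  plaintexts are group inverses, not modular offsets, so plaintexts
  split into negative / zero / positive exactly as the counting step
  needs. Decryption solves the small discrete log over a configured
  interval: a precomputed table (point → m) for widths up to 2²⁰, with
  baby-step/giant-step beyond. The protocol's decode interval is the
  union of the score range and the dummy domain, so honest decryption
  cannot fail; a decode failure therefore signals misuse or attack and
  raises.
* **Bit proofs.** Two-branch disjunctive Chaum–Pedersen ("plaintext is
  0" OR "plaintext is 1"), non-interactive via Fiat–Shamir over a
  domain-separated SHA-256 hash of (group, public key, ciphertext, all
  four commitments), reduced mod group order. The hash binds the proof
  to the exact ciphertext and key — any substitution or tampering
  rejects. Zero-knowledge rests on the standard special-honest-verifier
  simulator, which the test suite exercises through an
  explicit-challenge verification entry point.
* **Randomness.** System CSPRNG everywhere by default. Seeded
  deterministic randomness is accepted only through explicit test-mode
  paths (`seed=` arguments, `seed_policy="test"`); the CLI warns loudly
  when a seeded key is requested.

## Protocol flow and server-side choices

The server derives λ itself from the public similarity parameters,
computes `Enc(−|q|)` homomorphically from the query ciphertexts (a
client-supplied `Enc(−|q|)` would need its own validity proof), scores
each entry with ⊕ and ⊗ only, and rerandomizes every outgoing
ciphertext — scores and dummies alike — before the uniform shuffle, so
serialized bytes carry no positional signal. Dummies default to the
uniform distribution over the full integer score range, the assumption
under which the padding analysis is done; the count `n` defaults to
10,000. Whether unattainable interior integers should be excluded from
the dummy domain is an open choice; the uniform-over-k analysis treats
the full interval as acceptable and we follow it.

## Attack simulators

All simulators run on plaintext scores: the questions are
information-theoretic, not cryptographic, and this keeps 10⁵-trial
experiments in seconds. (The full encrypted stack is separately tested
for exact agreement with the plaintext counter.)

* **Score-revealing regression attack.** Baseline query `0`, then unit
  vectors `e_i`; `score(e_i) − score(0) = λ1·p_i − λ3` is positive iff
  `p_i = 1`, so recovery is deterministic in exactly ℓ probes.
* **Hit probability under sign-only replies.** Monte-Carlo estimate of
  `f_p = Pr(score(p, Q) > 0)` under a pluggable query distribution
  (uniform by default — the true query distribution of an attacker is
  unknowable, so it is an argument, not a constant), reported as
  `1 − (1−f_p)^x` for an x-query budget.
* **Dummy guessing.** The attacker knows the prior `w` over the k score
  values and sees counts `a_i` (n dummies + the true value). Optimal
  rules: argmax `w_i` (no observation), argmax `a_i·w_i` (one query),
  argmax `∏_j a_i^(j)·w_i` over L repeated queries — accumulated in log
  space, with uniform random tie-breaking. The experiment draws the
  true value from `w`, dummies i.i.d. from the server's dummy
  distribution (uniform, or the perturbed `u_i ∝ max(r_i,0)/k`,
  `r_i ~ N(1, δ²)`, renormalized — a distribution must sum to 1, so
  normalization is applied after truncation), while the attacker always
  *assumes* uniform dummies. Success ratio is 1.0 at n = 0, decreases in
  n, and converges to the ideal `max_i w_i`.

Priors: empirical score histograms of a reference compound collection
are not reproducible offline, so experiments use (a) the synthetic
"random histogram" prior — frequencies of m = 5k uniform draws over the
k values — and (b) priors computable from the synthetic fingerprint
generator. Indices into the k possible values are 0-based throughout.

## Synthetic fingerprints

The generator draws i.i.d. Bernoulli(density) bits; default density 0.3
gives a mean popcount of ~50 of 166, a realistic occupancy for MACCS
keys of drug-like molecules. An optional blockwise-correlated mode
(blocks active with probability `block_activity`, bits inside active
blocks upweighted to preserve the marginal density) mimics co-occurring
structural keys. What it does **not** emulate: the heavy-tailed,
strongly correlated key statistics of real libraries, near-duplicate
analog series, or any particular database's score distribution. Passing
tests therefore demonstrate protocol correctness and the *shape* of the
privacy trade-offs, not the numeric attack ratios of any real library.

File I/O uses an FPS-style hex text dialect (`#num_bits=ℓ` header,
`hex<TAB>id` records). Bit order: bytes left to right, bit 0 of each
byte is the least significant — fingerprint index i lives in byte
`i // 8`, bit `i % 8`; pad bits beyond ℓ must be zero. Computing MACCS
keys from structures (SMILES/SDF) is out of scope.

## Test and experiment sizes

Chosen as the package's own desk-scale defaults: the end-to-end
equivalence test runs 100 protocol instances at ℓ = 166 (database sizes
drawn in [1, 50] plus two instances at the 200-entry bound; dummy counts
0 and 1000), each checked exactly against a brute-force Fraction-based
counter. Dummy-padding experiments use k = 831, 10,000 trials and
n up to 831×100; the known small-n excess over the ideal and its decay
match the expected trend within three Monte-Carlo standard errors.
Exhaustive checks (sign equivalence, regression attack, score-range
oracle) run at ℓ = 8 or less, where full enumeration is feasible.

## Known limitations

* Bit-proof generation and verification dominate runtime (~4 ms per bit
  round trip in pure Python); a production deployment would use a
  compiled group backend behind the same `GroupSpec` interface.
* The protocol returns a count only; returning the matching compounds,
  multi-round sign-extraction variants, and sign-preserving score
  randomization are out of scope.
* No side-channel hardening; serialization is constant-width but
  execution time is not audited for secret-dependence.
* The curve's security level is taken as given for a research artifact;
  no formal security proof is attempted here (the dummy-padding
  indistinguishability argument is evaluated empirically).
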