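# sscc — secure similar compounds counter

Similarity search against someone else's compound library is a standoff:
the query structure is the searcher's most sensitive asset, and the
library is the owner's. `sscc` implements a two-party protocol that
resolves it — the client learns **only the number of database
fingerprints whose Tversky similarity to its query meets a threshold**,
and the server learns **nothing about the query**. It is aimed at
settings like pre-purchase inspection of a focused library, patent-
compound filtering, or privately checking a candidate against another
lab's failed compounds.

## The method

Compounds are binary fingerprints `p, q ∈ {0,1}^ℓ` (166-bit MACCS-style
keys by default), compared by the Tversky index

```
TI_{α,β}(p, q) = |p∩q| / (|p∩q| + α|p\q| + β|q\p|)
```

(α=β=1 is Jaccard/Tanimoto, α=β=1/2 is Dice). With rational parameters
α=μa/γ, β=μb/γ and threshold θ=θn/θd, the predicate `TI ≥ θ` equals the
sign of an integer linear form — the *threshold Tversky index*

```
λ1·|p∩q| − λ2·|p| − λ3·|q|   ≥ 0   ⟺   TI ≥ θ,
```

with `λ = (γ(θd−θn)+θn(μa+μb), θn·μa, θn·μb) / g`, `g` their gcd. For
the standard Jaccard search at θ=4/5 this gives λ=(9,4,4), and every
score of 166-bit fingerprints lies in [−664, 166] (k = 831 values).

Because the form needs only additions and known-integer scalings, the
server can evaluate it under additively homomorphic *lifted ElGamal*
encryption (secp192k1) on a bit-wise encrypted query — without ever
seeing the query. Two further mechanisms protect the *database*:

* **Zero-knowledge bit proofs.** Each query ciphertext carries a
  non-interactive proof (disjunctive Chaum–Pedersen, Fiat–Shamir) that
  its plaintext is 0 or 1, so a malicious client cannot plant a huge
  component and read a database bit out of the reply.
* **Dummy padding.** The server shuffles the M encrypted scores with n
  encrypted dummies drawn uniformly from the score range and reveals
  only `s_d`, its count of non-negative dummies. The client decrypts,
  counts non-negatives `s_c`, and obtains the answer `s_c − s_d` — but
  not the individual scores. A server that returned exact scores would
  surrender a hidden entry to ℓ unit-vector probes; `sscc`'s simulators
  quantify both that attack and what the padding buys.

One search is exactly two messages: query+proofs out, shuffled
ciphertexts + `s_d` back.

## Worked example

```python
from sscc import *

params = TverskyParams.from_fractions("1/1", "1/1", "4/5")   # Jaccard, θ=4/5
lam = derive_lambdas(params)
print("lambda =", lam.as_tuple())
print("score range =", score_range(166, lam), " k =", range_size(166, lam))

db = random_fingerprints(100, 166, 0.3, seed=11)
query = db[42]                      # search for a compound the server holds
result = run_protocol(query, db, params, DummyConfig(n=1000), seed=7)
print("similar compounds:", result.count, f"(s_c={result.s_c}, s_d={result.s_d})")
print("plaintext check  :", count_similar(query, db, params))
```

prints

```
lambda = (9, 4, 4)
score range = (-664, 166)  k = 831
similar compounds: 1 (s_c=198, s_d=197)
plaintext check  : 1
```

The client decrypted 1100 shuffled values (100 scores + 1000 dummies),
found 198 non-negative ones, was told 197 of the dummies are
non-negative — and so learns that exactly 1 database compound is
Jaccard-similar to its query at θ=0.8 (here, the planted entry itself),
nothing more. The encrypted count always equals the plaintext counter.

The same flow is available from the shell (`sscc keygen`, `sscc query`,
`sscc respond`, `sscc evaluate`, `sscc fps-gen`), with fingerprints in an
FPS-style hex text format. The attack simulators run as
`sscc simulate regression|hitprob|dummies`; for example
`sscc simulate dummies --k 831 --trials 2000 --seed 0` prints the attack
success ratio falling from 1.0 (no dummies) toward the prior-only ideal
0.0036 as n grows to 831×100.

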