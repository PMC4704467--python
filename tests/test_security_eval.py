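"""Attack simulators: regression attack, hit probability, dummy guessing."""

import numpy as np
import pytest

from sscc import security_eval as se
from sscc.fingerprints import Fingerprint, random_fingerprints
from sscc.tversky import LambdaParams, TverskyParams, derive_lambdas, threshold_tversky

LAM_08 = LambdaParams(9, 4, 4, 1)


def _oracle(hidden, lam):
    return lambda q: threshold_tversky(hidden, q, lam)


class TestPlainScoreAttack:
    def test_recovers_random_hidden_fingerprint(self):
        hidden = random_fingerprints(1, 64, 0.5, seed=1)[0]
        recovered, probes = se.plain_score_attack(_oracle(hidden, LAM_08), 64)
        assert recovered.bits == hidden.bits
        assert probes == 64

    def test_all_zero_hidden(self):
        hidden = Fingerprint(tuple([0] * 16))
        recovered, _ = se.plain_score_attack(_oracle(hidden, LAM_08), 16)
        assert recovered.bits == hidden.bits

    def test_exhaustive_small(self):
        # every hidden fingerprint at ℓ=8 is recovered exactly
        for mask in range(256):
            hidden = Fingerprint(tuple(mask >> i & 1 for i in range(8)))
            recovered, probes = se.plain_score_attack(_oracle(hidden, LAM_08), 8)
            assert recovered.bits == hidden.bits and probes == 8


class TestHitProbability:
    def test_zero_queries(self):
        p = random_fingerprints(1, 10, 0.5, seed=2)[0]
        assert se.hit_probability(p, LAM_08, trials=10, x=0, seed=0) == 0.0

    def test_theta_one_admits_no_strict_hit(self):
        # a hit requires a strictly positive score, i.e. TI > θ; at θ=1
        # even q = p only reaches TI = 1, so the hit probability is 0
        lam = derive_lambdas(TverskyParams.from_fractions(1, 1, 1))
        p = random_fingerprints(1, 10, 0.5, seed=3)[0]
        assert se.hit_probability(p, lam, trials=5_000, x=10 ** 6, seed=4) == 0.0

    def test_estimate_matches_exhaustive_hit_fraction(self):
        # ℓ=10, θ=1/2 Jaccard: enumerate all 2^10 queries for the exact f_p
        lam = derive_lambdas(TverskyParams.from_fractions(1, 1, "1/2"))
        p = random_fingerprints(1, 10, 0.5, seed=6)[0]
        pm = sum(b << i for i, b in enumerate(p.bits))
        pc = [bin(m).count("1") for m in range(1024)]
        hits = sum(1 for qm in range(1024)
                   if lam.lambda1 * pc[pm & qm] - lam.lambda2 * pc[pm]
                   - lam.lambda3 * pc[qm] > 0)
        f = hits / 1024
        est = se.hit_probability(p, lam, trials=20_000, x=1, seed=7)
        serr = np.sqrt(f * (1 - f) / 20_000)
        assert abs(est - f) < 3 * serr

    def test_empty_query_sampler_never_hits(self):
        p = random_fingerprints(1, 12, 0.5, seed=5)[0]
        sampler = lambda rng, length: np.zeros(length, dtype=np.int64)
        for x in (1, 100, 10 ** 6):
            assert se.hit_probability(p, LAM_08, query_sampler=sampler,
                                      trials=200, x=x, seed=0) == 0.0


class TestGuessingRules:
    def test_prior_argmax(self):
        assert se.best_guess_prior([0.2, 0.5, 0.3]) == 1
        assert se.best_guess_prior([1.0, 0.0, 0.0]) == 0

    def test_prior_tie_break_uniform(self):
        w = np.full(4, 0.25)
        picks = [se.best_guess_prior(w, seed=s) for s in range(400)]
        counts = np.bincount(picks, minlength=4)
        assert (counts > 50).all()  # each index near 100 of 400

    def test_posterior_argmax_product(self):
        assert se.best_guess_posterior([0.5, 0.3, 0.2], [1, 2, 1]) == 1

    def test_posterior_zero_count_excludes_prior_max(self):
        assert se.best_guess_posterior([0.5, 0.3, 0.2], [0, 1, 1]) == 1

    def test_posterior_tie_break(self):
        # dyadic weights keep the tie exact in binary floating point
        w, a = [0.5, 0.25, 0.25], [1, 2, 1]  # products 0.5, 0.5, 0.25
        picks = {se.best_guess_posterior(w, a, seed=s) for s in range(50)}
        assert picks == {0, 1}

    def test_multi_query_reduces_to_single(self):
        w, a = [0.5, 0.3, 0.2], [1, 2, 1]
        assert se.multi_query_posterior(w, [a]) == se.best_guess_posterior(w, a)

    def test_multi_query_zero_eliminates(self):
        w = [0.5, 0.5]
        assert se.multi_query_posterior(w, [[1, 2], [3, 0]]) == 0

    def test_multi_query_product_example(self):
        # products (1·3, 2·1)·w² → index 0
        assert se.multi_query_posterior([0.5, 0.5], [[1, 2], [3, 1]]) == 0

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            se.best_guess_prior([0.5, 0.6])


class TestPerturbedDummyDistribution:
    def test_delta_zero_is_uniform(self):
        u = se.perturbed_dummy_distribution(100, 0.0).weights
        assert np.allclose(u, 1 / 100)

    def test_sums_to_one(self):
        u = se.perturbed_dummy_distribution(831, 0.15, seed=1).weights
        assert u.min() >= 0 and abs(u.sum() - 1.0) < 1e-12

    def test_relative_spread_matches_delta(self):
        k, delta = 831, 0.1
        u = se.perturbed_dummy_distribution(k, delta, seed=2).weights
        # before normalization k·u_i ~ N(1, δ²); normalization barely moves it
        spread = np.std(k * u)
        assert abs(spread - delta) < 3 * delta / np.sqrt(2 * (k - 1))

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            se.perturbed_dummy_distribution(10, -0.1)


class TestDummyGuessExperiment:
    def test_no_dummies_no_concealment(self):
        w = se.make_random_prior(50, seed=1)
        assert se.dummy_guess_experiment(w, n=0, trials=300, seed=2) == 1.0

    def test_degenerate_prior_always_succeeds(self):
        w = np.zeros(20)
        w[7] = 1.0
        assert se.dummy_guess_experiment(w, n=200, trials=300, seed=3) == 1.0

    def test_large_n_approaches_ideal(self):
        # synthetic prior over a small k for speed: at n = 100k the
        # posterior rule should do no better than the prior-only ideal
        k = 50
        w = se.make_random_prior(k, seed=4)
        ideal = float(w.max())
        ratio = se.dummy_guess_experiment(w, n=100 * k, trials=4000, seed=5)
        serr = np.sqrt(max(ratio, ideal) * (1 - min(ratio, ideal)) / 4000)
        assert abs(ratio - ideal) < 3 * serr + 0.01

    def test_success_non_increasing_in_n(self):
        k = 50
        w = se.make_random_prior(k, seed=6)
        ratios = [se.dummy_guess_experiment(w, n=n, trials=3000, seed=7)
                  for n in (0, k, 10 * k, 100 * k)]
        noise = 3 * np.sqrt(0.25 / 3000)
        assert all(r2 <= r1 + noise for r1, r2 in zip(ratios, ratios[1:]))

    def test_repeated_queries_sharpen_attack(self):
        # multi-query posterior (same query L times) does at least as well
        # as a single look, up to Monte-Carlo noise
        k = 30
        w = se.make_random_prior(k, seed=8)
        r1 = se.dummy_guess_experiment(w, n=5 * k, L=1, trials=2500, seed=9)
        r10 = se.dummy_guess_experiment(w, n=5 * k, L=10, trials=2500, seed=9)
        noise = 3 * np.sqrt(0.25 / 2500)
        assert r10 >= r1 - noise

    def test_reproducible_under_seed(self):
        w = se.make_random_prior(20, seed=10)
        a = se.dummy_guess_experiment(w, n=40, trials=500, seed=11)
        b = se.dummy_guess_experiment(w, n=40, trials=500, seed=11)
        assert a == b


def test_make_random_prior_matches_recipe():
    # m draws over k cells: non-negative, sums to 1, mean cell mass 1/k
    w = se.make_random_prior(831, m=5 * 831, seed=12)
    assert w.shape == (831,)
    assert abs(w.sum() - 1.0) < 1e-12
    assert (w >= 0).all()
    # frequencies are multiples of 1/m
    scaled = w * (5 * 831)
    assert np.allclose(scaled, np.round(scaled))
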