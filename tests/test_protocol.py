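"""Protocol stages and end-to-end counting on small instances."""

import random
from fractions import Fraction

import pytest

from sscc import crypto, protocol
from sscc.crypto import PlaintextRange, decrypt, encrypt
from sscc.fingerprints import Fingerprint, random_fingerprints
from sscc.protocol import (
    DummyConfig,
    InvalidQueryError,
    ReplyMessage,
    assemble_reply,
    build_query,
    decode_range_for,
    encrypted_scores,
    evaluate_reply,
    make_dummies,
    run_protocol,
    verify_query,
)
from sscc.tversky import TverskyParams, derive_lambdas, score_range


def fp(*indices, length=8):
    return Fingerprint.from_indices(length, indices)


PARAMS_HALF = TverskyParams.from_fractions(1, 1, "1/2")
LAM_HALF = derive_lambdas(PARAMS_HALF)  # (3, 1, 1)


@pytest.fixture(scope="module")
def query_msg(keys):
    rng = random.Random(11)
    msg = build_query(keys, fp(0, 1), rng=rng)
    return msg


class TestBuildAndVerifyQuery:
    def test_round_trip_bits_and_proofs(self, keys):
        rng = random.Random(1)
        q = fp(0, 3, 7)
        msg = build_query(keys, q, rng=rng)
        assert msg.length == 8
        pr = PlaintextRange(-1, 1)
        assert tuple(decrypt(keys, ct, pr) for ct in msg.enc_bits) == q.bits
        assert verify_query(msg)

    def test_all_zero_query(self, keys):
        msg = build_query(keys, fp(), rng=random.Random(2))
        pr = PlaintextRange(-1, 1)
        assert all(decrypt(keys, ct, pr) == 0 for ct in msg.enc_bits)
        assert verify_query(msg)

    def test_non_bit_component_rejected(self, keys, query_msg):
        import dataclasses

        bad = dataclasses.replace(query_msg)
        bad.enc_bits = list(query_msg.enc_bits)
        bad.proofs = list(query_msg.proofs)
        r = 777
        bad.enc_bits[5] = encrypt(keys.pk, 2, randomness=r)
        from sscc.bitproof import prove_bit

        bad.proofs[5] = prove_bit(keys.pk, 2, r, bad.enc_bits[5])
        assert not verify_query(bad)
        with pytest.raises(InvalidQueryError):
            encrypted_scores(bad, [fp(1, 2)], LAM_HALF)

    def test_swapped_proofs_rejected(self, keys, query_msg):
        import dataclasses

        bad = dataclasses.replace(query_msg)
        bad.proofs = list(query_msg.proofs)
        bad.proofs[0], bad.proofs[1] = bad.proofs[1], bad.proofs[0]
        assert not verify_query(bad)

    def test_length_mismatch_rejected(self, query_msg):
        import dataclasses

        bad = dataclasses.replace(query_msg)
        bad.proofs = query_msg.proofs[:-1]
        assert not verify_query(bad)


class TestEncryptedScores:
    def test_worked_three_entry_example(self, keys, query_msg):
        """q={0,1} vs db {0,1,2},{3,4},{0,3} under λ=(3,1,1) → (1, −4, −1)."""
        db = [fp(0, 1, 2), fp(3, 4), fp(0, 3)]
        scores = encrypted_scores(query_msg, db, LAM_HALF, verified=True)
        pr = PlaintextRange(*score_range(8, LAM_HALF))
        assert [decrypt(keys, ct, pr) for ct in scores] == [1, -4, -1]

    def test_identical_entry_scores_popcount(self, keys):
        lam = derive_lambdas(TverskyParams.from_fractions(1, 1, "4/5"))
        q = fp(1, 4, 6)
        msg = build_query(keys, q, rng=random.Random(3))
        scores = encrypted_scores(msg, [q], lam, verified=True)
        pr = PlaintextRange(*score_range(8, lam))
        assert decrypt(keys, scores[0], pr) == 3  # 9a − 8a = |q|

    def test_disjoint_entry(self, keys, query_msg):
        lam = derive_lambdas(TverskyParams.from_fractions(1, 1, "4/5"))
        scores = encrypted_scores(query_msg, [fp(4, 5, 6)], lam, verified=True)
        pr = PlaintextRange(*score_range(8, lam))
        assert decrypt(keys, scores[0], pr) == -4 * 3 - 4 * 2  # c = 0

    def test_length_mismatch_raises(self, keys, query_msg):
        with pytest.raises(protocol.ProtocolError):
            encrypted_scores(query_msg, [Fingerprint((1, 0))], LAM_HALF, verified=True)


class TestDummies:
    def test_s_d_counts_non_negatives_including_zero(self, keys):
        # force known draws through a seeded rng over a tiny domain
        cfg = DummyConfig(n=1000, domain=(-2, 2), seed=5)
        cts, s_d = make_dummies(keys.pk, cfg)
        pr = PlaintextRange(-2, 2)
        values = [decrypt(keys, ct, pr) for ct in cts]
        assert s_d == sum(1 for v in values if v >= 0)
        assert len(cts) == 1000

    def test_zero_dummies(self, keys):
        cts, s_d = make_dummies(keys.pk, DummyConfig(n=0, domain=(-5, 5), seed=1))
        assert cts == [] and s_d == 0

    def test_uniform_non_negative_fraction(self, keys):
        # over [−664, 166] there are 167 non-negative of 831 values;
        # binomial SE at n=4000 is sqrt(0.201·0.799/4000) ≈ 0.0063
        cfg = DummyConfig(n=4000, domain=(-664, 166), seed=7)
        rng = random.Random(7)
        lo, hi = cfg.domain
        values = [rng.randrange(lo, hi + 1) for _ in range(cfg.n)]
        frac = sum(v >= 0 for v in values) / cfg.n
        assert abs(frac - 167 / 831) < 3 * 0.0063

    def test_seeded_draw_reproducible(self, keys):
        cfg = DummyConfig(n=20, domain=(-10, 10), seed=3)
        _, s1 = make_dummies(keys.pk, cfg)
        _, s2 = make_dummies(keys.pk, cfg)
        assert s1 == s2


class TestAssembleAndEvaluate:
    def test_conservation_of_plaintext_multiset(self, keys, query_msg):
        db = [fp(0, 1, 2), fp(3, 4), fp(0, 3)]
        scores = encrypted_scores(query_msg, db, LAM_HALF, verified=True)
        cfg = DummyConfig(n=7, domain=(-5, 5), seed=9)
        dummies, s_d = make_dummies(keys.pk, cfg)
        reply = assemble_reply(scores, dummies, s_d, seed=13)
        assert len(reply.items) == 10
        pr = PlaintextRange(-24, 24)
        got = sorted(decrypt(keys, ct, pr) for ct in reply.items)
        want = sorted([decrypt(keys, ct, pr) for ct in scores]
                      + [decrypt(keys, ct, pr) for ct in dummies])
        assert got == want

    def test_fixed_seed_fixed_permutation(self, keys, query_msg):
        scores = encrypted_scores(query_msg, [fp(0, 1)], LAM_HALF, verified=True)
        dummies, s_d = make_dummies(keys.pk, DummyConfig(n=5, domain=(-3, 3), seed=1))
        r1 = assemble_reply(scores, dummies, s_d, seed=4)
        r2 = assemble_reply(scores, dummies, s_d, seed=4)
        assert [c.to_hex() for c in r1.items] == [c.to_hex() for c in r2.items]

    def test_counting_example(self, keys):
        # decryptions {5, −2, −7, 1, 0} with s_d = 2 → s_c = 3, count = 1
        items = [encrypt(keys.pk, v) for v in (5, -2, -7, 1, 0)]
        res = evaluate_reply(keys, ReplyMessage(items=items, s_d=2),
                             PlaintextRange(-10, 10))
        assert res.s_c == 3 and res.count == 1

    def test_all_dummy_reply_counts_zero(self, keys):
        dummies, s_d = make_dummies(keys.pk, DummyConfig(n=30, domain=(-4, 4), seed=2))
        res = evaluate_reply(keys, ReplyMessage(items=dummies, s_d=s_d),
                             PlaintextRange(-4, 4))
        assert res.count == 0


class TestRunProtocol:
    def test_worked_example_any_dummy_count(self):
        q = fp(0, 1)
        db = [fp(0, 1, 2), fp(3, 4), fp(0, 3)]
        for n in (0, 4, 50):
            res = run_protocol(q, db, PARAMS_HALF, DummyConfig(n=n), seed=21)
            assert res.count == 1

    def test_database_of_query_copies(self):
        q = fp(0, 2, 5)
        res = run_protocol(q, [q] * 4, TverskyParams.from_fractions(1, 1, "4/5"),
                           DummyConfig(n=10), seed=22)
        assert res.count == 4

    def test_matches_plaintext_counter_small_random(self):
        """Brute-force Fraction oracle vs the encrypted path, ℓ=16."""
        rng = random.Random(23)
        params = TverskyParams.from_fractions(1, 1, "1/2")
        for trial in range(5):
            q = random_fingerprints(1, 16, 0.4, seed=100 + trial)[0]
            db = random_fingerprints(8, 16, 0.4, seed=200 + trial)
            expected = 0
            for p in db:
                a, b = sum(p.bits), sum(q.bits)
                c = sum(x & y for x, y in zip(p.bits, q.bits))
                if a == 0 and b == 0:
                    expected += 1
                elif b + a > 0 and Fraction(c, c + (a - c) + (b - c)) >= Fraction(1, 2):
                    expected += 1
            res = run_protocol(q, db, params, DummyConfig(n=20), seed=rng.randrange(2 ** 20))
            assert res.count == expected

    def test_two_message_transcript(self, keys):
        """One client→server and one server→client document per search."""
        q = fp(0, 1)
        db = [fp(0, 1, 2), fp(3, 4)]
        rng = random.Random(31)
        msg = build_query(keys, q, rng=rng)
        msg.params = PARAMS_HALF
        query_doc = protocol.query_to_text(msg)  # the single client→server message

        server_msg = protocol.query_from_text(query_doc)
        assert verify_query(server_msg)
        lam = derive_lambdas(server_msg.params)
        scores = encrypted_scores(server_msg, db, lam, verified=True, rng=rng)
        cfg = DummyConfig(n=6, domain=score_range(8, lam))
        dummies, s_d = make_dummies(server_msg.pk, cfg, rng=rng)
        reply = assemble_reply(scores, dummies, s_d, rng=rng)
        prange = decode_range_for(8, lam, cfg)
        reply_doc = protocol.reply_to_text(reply, prange)  # the single reply

        back, back_range = protocol.reply_from_text(reply_doc)
        res = evaluate_reply(keys, back, back_range)
        assert res.count == 1
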