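"""Tag/value encodings, chunking, hashing, and database construction."""

import hashlib

import numpy as np
import pytest

from genomatch import (
    CapacityError,
    DataError,
    FormatError,
    RingElt,
    build_db_direct,
    build_db_hashed,
    chunk_value,
    encode_alleles,
    encode_query,
    encode_tag,
    encode_value,
    hash_tag,
    monomial,
    ring_mult,
    unchunk_value,
)
from genomatch.encoding import (
    VariantRecord,
    chunk_count,
    decode_alleles,
    decode_value,
    encode_record,
)


class TestEncodeTag:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("1", 161235340, 3869648161),
            ("1", 161237503, 3869700073),
            ("X", 1, 24),
            ("Y", 1, 47),
            ("22", 10, 262),
        ],
    )
    def test_published_and_boundary_values(self, chrom, pos, expected):
        assert encode_tag(chrom, pos) == expected

    def test_chr_prefix_and_int_accepted(self):
        assert encode_tag("chr1", 5) == encode_tag(1, 5)

    @pytest.mark.parametrize("chrom,pos", [("Z", 1), ("0", 1), ("23", 1),
                                           ("1", 0), ("1", -4)])
    def test_invalid_inputs_rejected(self, chrom, pos):
        with pytest.raises(FormatError):
            encode_tag(chrom, pos)


class TestEncodeAlleles:
    def test_worked_example(self):
        # 'GC' -> 1|10|11 binary = 27
        assert encode_alleles("GC", 10) == 27

    def test_unknown_encodes_to_zero(self):
        assert encode_alleles(".", 10) == 0
        assert encode_alleles("", 10) == 0

    def test_longer_sequence(self):
        # 'TGAT' -> 1|01|10|00|01 = 353
        assert encode_alleles("TGAT", 10) == 353

    def test_case_insensitive(self):
        assert encode_alleles("gc", 10) == 27

    def test_round_trip(self):
        for seq in ("A", "T", "G", "C", "GC", "TGAT", "TTTTTGT", "."):
            assert decode_alleles(encode_alleles(seq, 10), 10) == seq

    def test_errors(self):
        with pytest.raises(FormatError):
            encode_alleles("AN", 10)
        with pytest.raises(FormatError):
            encode_alleles("A" * 11, 10)


class TestEncodeValue:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("G", "A", 12582916),
            (".", "TTTTTGT", 21849),
            ("AG", ".", 37748736),
            ("C", "T", 14680069),
        ],
    )
    def test_published_values(self, ref, alt, expected):
        assert encode_value(ref, alt, 10) == expected

    def test_decode_inverse(self):
        assert decode_value(12582916, 10) == ("G", "A")
        assert decode_value(21849, 10) == (".", "TTTTTGT")


class TestChunking:
    @pytest.mark.parametrize("n_snp,expected", [(2, 1), (5, 2), (10, 4)])
    def test_chunk_count_formula(self, n_snp, expected):
        assert chunk_count(n_snp, 2**11) == expected

    def test_known_digits(self):
        # 12582916 = 4 + 0*t + 3*t^2 + 0*t^3 at t = 2**11
        assert chunk_value(12582916, 10, 2**11) == (4, 0, 3, 0)

    def test_zero_value(self):
        assert chunk_value(0, 10, 2**11) == (0, 0, 0, 0)

    def test_round_trip_random(self, rng):
        t = 2**11
        for _ in range(100):
            alpha = int(rng.integers(0, 2**42))
            assert unchunk_value(chunk_value(alpha, 10, t), t) == alpha

    def test_single_chunk_is_value(self):
        assert chunk_value(27, 2, 2**11) == (27,)


class TestHashTag:
    def test_range_and_determinism(self, rng):
        N = 2048
        for d in rng.integers(0, 2**33, size=50):
            hp1 = hash_tag(int(d), N)
            hp2 = hash_tag(int(d), N)
            assert hp1 == hp2
            assert 0 <= hp1.d_star < N and 0 <= hp1.d_dagger < N

    def test_frozen_regression_value(self):
        # independent SHA3-256 evaluation of the convention, frozen
        hp = hash_tag(3869648161, 2048)
        assert (hp.d_star, hp.d_dagger) == (1522, 913)

    def test_matches_independent_hash_oracle(self):
        d, N = 123456789, 2048
        digest = hashlib.sha3_256(d.to_bytes(8, "little")).digest()
        h = int.from_bytes(digest, "little")
        hp = hash_tag(d, N)
        assert hp.d_star == h % N
        assert hp.d_dagger == (h >> 11) % N


def _small_tag_records(n, rng):
    """Records whose tags stay below N: chromosome X keeps d = 24*pos."""
    poss = rng.choice(np.arange(1, 85), size=n, replace=False)
    bases = np.array(list("ATGC"))
    return [
        VariantRecord("X", int(p), str(rng.choice(bases)),
                      str(rng.choice(bases)))
        for p in poss
    ]


class TestBuildDbDirect:
    def test_single_record_coefficient(self, params, rng):
        rec = VariantRecord("X", 5, "G", "A")
        enc = encode_record(rec, 2, params.t)
        db = build_db_direct([rec], params, rng, n_snp=2)
        assert db.C == 1
        star, dagger = db.polys[0][0]
        assert dagger is None
        assert star.coeffs[enc.d] % params.t == enc.chunks[0]

    def test_zero_filler(self, params, rng):
        rec = VariantRecord("X", 5, "G", "A")
        db = build_db_direct([rec], params, rng, n_snp=2, filler="zero")
        star, _ = db.polys[0][0]
        enc = encode_record(rec, 2, params.t)
        others = np.delete(star.coeffs, enc.d)
        assert not others.any()

    def test_all_constraints_on_random_records(self, params, rng):
        recs = _small_tag_records(50, rng)
        db = build_db_direct(recs, params, rng, n_snp=10)
        for i, r in enumerate(recs):
            enc = encode_record(r, 10, params.t)
            for c in range(db.C):
                assert db.polys[c][0][0].coeffs[enc.d] % params.t == enc.chunks[c]

    def test_duplicate_tags_rejected(self, params, rng):
        rec = VariantRecord("X", 5, "G", "A")
        with pytest.raises(DataError):
            build_db_direct([rec, rec], params, rng, n_snp=2)

    def test_large_tags_redirect_to_hashed(self, params, rng):
        rec = VariantRecord("1", 161235340, "G", "A")
        with pytest.raises(CapacityError):
            build_db_direct([rec], params, rng, n_snp=10)


class TestBuildDbHashed:
    def _assert_invariant(self, db, recs, params, n_snp):
        from genomatch.encoding import hash_tag as H

        for i, r in enumerate(recs):
            enc = encode_record(r, n_snp, params.t)
            hp = H(enc.d, params.N)
            b = db.placement[i]
            for c in range(db.C):
                star, dag = db.polys[c][b]
                got = (int(star.coeffs[hp.d_star])
                       + int(dag.coeffs[hp.d_dagger])) % params.t
                assert got == enc.chunks[c]

    def test_single_record_sum_constraint(self, params, rng):
        recs = [VariantRecord("7", 123456, "G", "A")]
        db = build_db_hashed(recs, params, rng, n_snp=10)
        self._assert_invariant(db, recs, params, 10)

    def test_hundred_random_records(self, params, rng):
        from genomatch.io_synth import SynthConfig, generate_synthetic

        recs = generate_synthetic(SynthConfig(n_records=100, seed=3))
        db = build_db_hashed(recs, params, rng, n_snp=10)
        self._assert_invariant(db, recs, params, 10)
        assert db.n_blocks == 1

    def test_capacity_spills_to_new_block(self, params, rng):
        from genomatch.io_synth import SynthConfig, generate_synthetic

        recs = generate_synthetic(SynthConfig(n_records=25, seed=4))
        db = build_db_hashed(recs, params, rng, n_snp=10, block_capacity=10)
        assert db.n_blocks == 3
        self._assert_invariant(db, recs, params, 10)

    def test_forced_hash_collision_splits_blocks(self, params, rng):
        # find two chromosome-X positions whose tags share the same hash
        # pair, give them conflicting values: they cannot share a block
        seen = {}
        pair = None
        pos = 1
        while pair is None:
            hp = hash_tag(encode_tag("X", pos), params.N)
            key = (hp.d_star, hp.d_dagger)
            if key in seen:
                pair = (seen[key], pos)
            else:
                seen[key] = pos
            pos += 1
        p1, p2 = pair
        recs = [
            VariantRecord("X", p1, "G", "A"),
            VariantRecord("X", p2, "C", "T"),
        ]
        db = build_db_hashed(recs, params, rng, n_snp=10)
        assert db.n_blocks == 2
        self._assert_invariant(db, recs, params, 10)

    def test_unconstrained_coefficients_look_uniform(self, params, rng):
        # with a single record almost every coefficient of DB*/DB+ is a
        # free uniform draw from Z_t
        from scipy import stats

        recs = [VariantRecord("7", 123456, "G", "A")]
        db = build_db_hashed(recs, params, rng, n_snp=2)
        for idx in (0, 1):
            coeffs = db.polys[0][0][idx].coeffs % params.t
            counts, _ = np.histogram(coeffs, bins=16, range=(0, params.t))
            assert stats.chisquare(counts).pvalue > 1e-4


class TestEncodeQuery:
    def test_zero_exponent_monomial_is_one(self, params):
        assert monomial(params.N, 0, params.t) == RingElt.constant(
            1, params.N, params.t
        )

    def test_unit_exponent_is_negated_top_coefficient(self, params):
        m = monomial(params.N, -1, params.t)
        expected = np.zeros(params.N, dtype=np.int64)
        expected[params.N - 1] = -1
        assert np.array_equal(m.coeffs, expected)

    def test_inverse_identity_over_full_range(self, params):
        one = RingElt.constant(1, params.N, params.t)
        for d in range(0, params.N, 37):  # stride covers sign wrap cases
            prod = ring_mult(
                monomial(params.N, d, params.t),
                monomial(params.N, -d, params.t),
            )
            assert prod == one

    def test_inverse_identity_exhaustive_small_ring(self):
        from genomatch import HEParams

        p = HEParams(N=64, h=8)
        one = RingElt.constant(1, 64, p.t)
        for d in range(64):
            assert ring_mult(monomial(64, d, p.t),
                             monomial(64, -d, p.t)) == one

    def test_query_carries_consistent_chunks(self, params):
        q = encode_query("1", 161235340, "G", "A", params, n_snp=10)
        assert q.alpha == 12582916
        assert unchunk_value(q.chunks, params.t) == q.alpha
        assert q.monomial_dagger is not None

    def test_direct_mode_requires_small_tag(self, params):
        with pytest.raises(CapacityError):
            encode_query("1", 161235340, "G", "A", params, n_snp=10,
                         mode="direct")
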