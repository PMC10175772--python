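"""The packed-vector contract: encoding round trips, SIMD primitive
semantics, multi-ciphertext rotation, depth accounting and the agreement of
the fixed-point backend with the exact simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hesimd as hs
from hesimd import (
    BigPackedVector,
    HEParams,
    big_rotate,
    counter_scope,
    decrypt_decode,
    elementwise,
    encode_encrypt,
    invert_mask,
    keygen,
    make_bitmask,
    poly_eval,
    rotate,
)
from hesimd.errors import DecryptionError, LevelExhaustedError
from hesimd.fixtures import oracle_poly, oracle_rotate


class TestEncoding:
    def test_zero_fill_convention(self):
        params = HEParams(N=8)
        keys = keygen(params, 1)
        ct = encode_encrypt([1, 2, 3], params, keys)
        assert list(decrypt_decode(ct, keys, 8)) == [1, 2, 3, 0, 0, 0, 0, 0]

    def test_long_vectors_split_into_parts(self):
        params = HEParams(N=8)
        keys = keygen(params, 1)
        ct = encode_encrypt(np.arange(16.0), params, keys)
        assert isinstance(ct, BigPackedVector)
        assert ct.r == 2
        np.testing.assert_array_equal(decrypt_decode(ct, keys, 16), np.arange(16.0))

    def test_simulator_roundtrip_is_exact(self, rng):
        params = HEParams(N=128)
        keys = keygen(params, 1)
        values = rng.uniform(-1, 1, 100)
        got = decrypt_decode(encode_encrypt(values, params, keys), keys, 100)
        np.testing.assert_array_equal(got, values)

    def test_empty_input_rejected(self, sim_env):
        params, keys = sim_env
        with pytest.raises(ValueError):
            encode_encrypt([], params, keys)

    def test_all_zero_roundtrip(self, sim_env):
        params, keys = sim_env
        got = decrypt_decode(encode_encrypt(np.zeros(10), params, keys), keys, 10)
        assert not got.any()

    def test_wrong_key_rejected_on_fixed_backend(self, rng):
        params = HEParams(N=64, backend="fixed")
        ct = encode_encrypt(rng.uniform(-1, 1, 8), params, keygen(params, 1))
        with pytest.raises(DecryptionError):
            decrypt_decode(ct, keygen(params, 2), 8)

    def test_public_keys_cannot_decrypt(self, sim_env):
        params, keys = sim_env
        ct = encode_encrypt([5.0], params, keys)
        with pytest.raises(DecryptionError):
            decrypt_decode(ct, keys.public_only(), 1)
        assert list(decrypt_decode(ct, keys, 1)) == [5.0]

    def test_fixed_backend_decode_error_small(self, rng):
        params = HEParams(N=64, backend="fixed")
        keys = keygen(params, 1)
        values = rng.uniform(-1, 1, 64)
        got = decrypt_decode(encode_encrypt(values, params, keys), keys, 64)
        assert np.max(np.abs(got - values)) <= 1e-4


class TestElementwise:
    def test_examples(self):
        params = HEParams(N=2)
        keys = keygen(params, 1)
        a = encode_encrypt([1, 2], params, keys)
        b = encode_encrypt([3, 4], params, keys)
        assert list(decrypt_decode(elementwise("sum", a, b), keys, 2)) == [4, 6]
        assert list(decrypt_decode(elementwise("sub", a, b), keys, 2)) == [-2, -2]
        assert list(decrypt_decode(elementwise("mul", a, b), keys, 2)) == [3, 8]

    def test_mask_semantics(self):
        params = HEParams(N=4)
        keys = keygen(params, 1)
        v = encode_encrypt([1, 2, 3, 4], params, keys)
        ones = make_bitmask(range(4), params)
        np.testing.assert_array_equal(
            decrypt_decode(elementwise("mul", v, ones), keys, 4), [1, 2, 3, 4])
        some = make_bitmask({0, 2}, params)
        np.testing.assert_array_equal(
            decrypt_decode(elementwise("mul", v, some), keys, 4), [1, 0, 3, 0])

    @pytest.mark.parametrize("N", [8, 16, 64, 1024])
    def test_simulator_matches_slotwise_numpy(self, N, rng):
        params = HEParams(N=N)
        keys = keygen(params, 1)
        for _ in range(50):
            x = rng.uniform(-2, 2, N)
            y = rng.uniform(-2, 2, N)
            a = encode_encrypt(x, params, keys)
            b = encode_encrypt(y, params, keys)
            np.testing.assert_array_equal(
                decrypt_decode(elementwise("sum", a, b), keys, N), x + y)
            np.testing.assert_array_equal(
                decrypt_decode(elementwise("sub", a, b), keys, N), x - y)
            np.testing.assert_array_equal(
                decrypt_decode(elementwise("mul", a, b), keys, N), x * y)
            k = int(rng.integers(0, N))
            np.testing.assert_array_equal(
                decrypt_decode(rotate(a, k), keys, N), np.roll(x, -k))

    @pytest.mark.parametrize("N", [8, 64])
    def test_fixed_backend_agrees_with_simulator(self, N, rng):
        sp = HEParams(N=N, backend="sim")
        fp = HEParams(N=N, backend="fixed")
        sk, fk = keygen(sp, 1), keygen(fp, 1)
        for _ in range(25):
            x = rng.uniform(-1, 1, N)
            y = rng.uniform(-1, 1, N)
            for op in ("sum", "sub", "mul"):
                ref = decrypt_decode(
                    elementwise(op, encode_encrypt(x, sp, sk),
                                encode_encrypt(y, sp, sk)), sk, N)
                got = decrypt_decode(
                    elementwise(op, encode_encrypt(x, fp, fk),
                                encode_encrypt(y, fp, fk)), fk, N)
                assert np.max(np.abs(got - ref)) <= 1e-3

    def test_depth_budget_enforced_with_named_error(self):
        params = HEParams(N=4, depth_budget=1)
        keys = keygen(params, 1)
        v = encode_encrypt([1, 1, 1, 1], params, keys)
        v2 = elementwise("mul", v, v, opname="first square")
        with pytest.raises(LevelExhaustedError, match="second square"):
            elementwise("mul", v2, v2, opname="second square")


class TestRotation:
    def test_cyclic_definition(self):
        params = HEParams(N=4)
        keys = keygen(params, 1)
        v = encode_encrypt([1, 2, 3, 4], params, keys)
        assert list(decrypt_decode(rotate(v, 1), keys, 4)) == [2, 3, 4, 1]
        assert list(decrypt_decode(rotate(v, 4), keys, 4)) == [1, 2, 3, 4]
        assert list(decrypt_decode(rotate(v, -1), keys, 4)) == [4, 1, 2, 3]

    @given(st.integers(-20, 20), st.integers(-20, 20))
    def test_group_action(self, a, b):
        params = HEParams(N=8)
        keys = keygen(params, 3)
        x = np.arange(8.0)
        v = encode_encrypt(x, params, keys)
        composed = decrypt_decode(rotate(rotate(v, a), b), keys, 8)
        direct = decrypt_decode(rotate(v, (a + b) % 8), keys, 8)
        np.testing.assert_array_equal(composed, direct)
        np.testing.assert_array_equal(
            decrypt_decode(rotate(rotate(v, a), -a), keys, 8), x)

    def test_matches_permutation_oracle(self):
        params = HEParams(N=8)
        keys = keygen(params, 3)
        x = np.arange(8.0) + 1
        v = encode_encrypt(x, params, keys)
        got = decrypt_decode(rotate(rotate(v, 3), 6), keys, 8)
        np.testing.assert_array_equal(got, oracle_rotate(oracle_rotate(x, 3), 6))


class TestBigRotate:
    params = HEParams(N=8)

    def test_exhaustive_against_concatenation_oracle(self):
        keys = keygen(self.params, 1)
        x = np.arange(16.0)
        v = encode_encrypt(x, self.params, keys)
        for k in range(16):
            got = decrypt_decode(big_rotate(v, k), keys, 16)
            np.testing.assert_array_equal(got, oracle_rotate(x, k), err_msg=f"k={k}")

    def test_zero_amount_is_identity(self):
        keys = keygen(self.params, 1)
        x = np.arange(16.0)
        v = encode_encrypt(x, self.params, keys)
        np.testing.assert_array_equal(decrypt_decode(big_rotate(v, 0), keys, 16), x)

    def test_single_part_matches_plain_rotate(self, rng):
        keys = keygen(self.params, 1)
        x = rng.uniform(-1, 1, 8)
        v = encode_encrypt(x, self.params, keys)
        big = BigPackedVector([v], 8)
        np.testing.assert_array_equal(
            decrypt_decode(big_rotate(big, 3), keys, 8),
            decrypt_decode(rotate(encode_encrypt(x, self.params, keys), 3),
                           keys, 8))

    @pytest.mark.parametrize("r", [1, 2, 3, 4])
    def test_cost_ledger_closed_form(self, r):
        keys = keygen(self.params, 1)
        v = encode_encrypt(np.arange(8.0 * r), self.params, keys)
        if r == 1:
            v = BigPackedVector([v], 8)
        with counter_scope() as scope:
            big_rotate(v, 3)
        rep = scope.report
        assert (rep.dc, rep.osum, rep.omul, rep.orot) == (1, 2 * r, r, r)
        assert rep.omem <= 2 * r


class TestBitmask:
    def test_even_index_mask(self):
        params = HEParams(N=4)
        assert list(make_bitmask({t for t in range(4) if t % 2 == 0}, params)) \
            == [1, 0, 1, 0]

    def test_empty_and_inverted(self):
        params = HEParams(N=4)
        assert not make_bitmask(set(), params).any()
        assert list(invert_mask([1, 0, 1, 0])) == [0, 1, 0, 1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_bitmask({4}, HEParams(N=4))


class TestPolyEval:
    def test_square_and_constant(self, sim_env):
        params, keys = sim_env
        v = encode_encrypt([1, 2, 3], params, keys)
        got = decrypt_decode(poly_eval(v, [0, 0, 1]), keys, 4)
        np.testing.assert_array_equal(got, [1, 4, 9, 0])
        const = decrypt_decode(poly_eval(v, [7]), keys, 4)
        np.testing.assert_array_equal(const, [7, 7, 7, 7])

    def test_degree_three_matches_scalar_loop(self, rng, sim_env):
        params, keys = sim_env
        x = rng.uniform(-1, 1, 8)
        coeffs = [0.5, -1.0, 0.25, 2.0]
        v = encode_encrypt(x, params, keys)
        got = decrypt_decode(poly_eval(v, coeffs), keys, 8)
        np.testing.assert_allclose(got, oracle_poly(x, coeffs), atol=1e-12)

    def test_square_costs_one_level(self):
        params = HEParams(N=4, depth_budget=1)
        keys = keygen(params, 1)
        v = encode_encrypt([2.0], params, keys)
        assert poly_eval(v, [0, 0, 1]).level_used == 1
        with pytest.raises(LevelExhaustedError):
            poly_eval(v, [0, 0, 0, 0, 1])  # x^4 needs two levels


class TestCounterScope:
    def test_basic_and_empty_scope(self, sim_env):
        params, keys = sim_env
        v = encode_encrypt([1.0], params, keys)
        with counter_scope() as scope:
            w = elementwise("mul", v, v)
            rotate(w, 1)
        rep = scope.report
        assert (rep.dc, rep.omul, rep.orot) == (1, 1, 1)
        with counter_scope() as empty:
            pass
        assert empty.report.as_dict() == {"dc": 0, "osum": 0, "omul": 0,
                                          "orot": 0, "omem": 0}

    def test_sequential_chain_depth(self, sim_env):
        params, keys = sim_env
        for d in (1, 2, 3):
            v = encode_encrypt([1.0], params, keys)
            with counter_scope() as scope:
                for _ in range(d):
                    v = elementwise("mul", v, v)
            assert scope.report.dc == d

    def test_parallel_multiplications_depth_one(self, sim_env):
        params, keys = sim_env
        vs = [encode_encrypt([float(i)], params, keys) for i in range(4)]
        with counter_scope() as scope:
            for v in vs:
                elementwise("mul", v, v)
        assert scope.report.dc == 1
        assert scope.report.omul == 4

    def test_nested_scopes_compose_additively(self, sim_env):
        params, keys = sim_env
        v = encode_encrypt([1.0], params, keys)
        with counter_scope() as outer:
            with counter_scope() as inner:
                elementwise("sum", v, v)
            elementwise("sub", v, v)
        assert inner.report.osum == 1
        assert outer.report.osum == 2

    def test_big_rotate_scope_matches_closed_form(self):
        params = HEParams(N=8)
        keys = keygen(params, 1)
        v = encode_encrypt(np.arange(16.0), params, keys)
        with counter_scope() as scope:
            big_rotate(v, 2)
        rep = scope.report
        assert (rep.dc, rep.osum, rep.omul, rep.orot) == (1, 4, 2, 2)
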