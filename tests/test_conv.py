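"""Streamlined convolution block versus brute-force oracles, plus its exact
operation ledgers and depth behaviour."""

import itertools

import numpy as np
import pytest

import hesimd as hs
from hesimd import (
    ConvSpec,
    Filter,
    HEParams,
    PoolSpec,
    SCBFLayout,
    average_pooling,
    counter_scope,
    decrypt_decode,
    encode_encrypt,
    keygen,
    poly_eval,
    rc_encode,
    rt_scbf_to_rc,
    streamlined_convolution,
    streamlined_padding,
)
from hesimd.errors import CapacityError
from hesimd.layouts import encode_matrix
from hesimd.fixtures import oracle_conv, oracle_pool

PARAMS = HEParams(N=1024)
KEYS = keygen(PARAMS, 11)


def _sweep_configs():
    rng = np.random.default_rng(5)
    configs = []
    grid = list(itertools.product([4, 7, 9, 12], [1, 2, 3], [1, 2], [0, 1]))
    for idx, (h, f, s, p) in enumerate(grid):
        w = h + int(rng.integers(0, 3))
        if f > h:
            continue
        configs.append((idx, h, w, f, s, p))
    return configs  # 48 swept configurations


def _run_conv(h, w, f, s, p, seed):
    rng = np.random.default_rng(seed)
    M = rng.uniform(-1, 1, (h, w))
    F = rng.uniform(-1, 1, (f, f))
    grid = (h + 2 * p, w + 2 * p) if p else None
    layout, ct = encode_matrix(M, PARAMS, KEYS, grid=grid)
    with counter_scope() as conv_scope:
        res = streamlined_convolution(ct, ConvSpec(Filter(F), (s, s), p), layout)
    with counter_scope() as rt_scope:
        rc = rt_scbf_to_rc(res.vector, res.layout)
    return M, F, res, rc, conv_scope.report, rt_scope.report


class TestConvolutionOracle:
    def test_identity_filter(self, rng):
        M = rng.uniform(-1, 1, (4, 4))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        res = streamlined_convolution(ct, ConvSpec(Filter([[1.0]])), layout)
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), KEYS, 16)
        np.testing.assert_allclose(got, M.reshape(-1), atol=1e-12)

    def test_seeded_4x4_against_sliding_window(self, rng):
        M = rng.uniform(-1, 1, (4, 4))
        F = rng.uniform(-1, 1, (2, 2))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        res = streamlined_convolution(ct, ConvSpec(Filter(F)), layout)
        assert (res.hout, res.wout) == (3, 3)
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), KEYS, 9)
        np.testing.assert_allclose(got, oracle_conv(M, F).reshape(-1), atol=1e-12)

    def test_same_padding_preserves_shape(self):
        # 20x20 input, 3x3 kernel, stride 1, padding 1
        rng = np.random.default_rng(2)
        M = rng.uniform(-1, 1, (20, 20))
        F = rng.uniform(-1, 1, (3, 3))
        layout, ct = encode_matrix(M, PARAMS, KEYS, grid=(22, 22))
        res = streamlined_convolution(ct, ConvSpec(Filter(F), (1, 1), 1), layout)
        assert (res.hout, res.wout) == (20, 20)
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), KEYS, 400)
        np.testing.assert_allclose(got, oracle_conv(M, F, (1, 1), 1).reshape(-1),
                                   atol=1e-12)

    @pytest.mark.parametrize("idx,h,w,f,s,p", _sweep_configs())
    def test_sweep_exact_equality(self, idx, h, w, f, s, p):
        M, F, res, rc, conv_rep, rt_rep = _run_conv(h, w, f, s, p, seed=100 + idx)
        want = oracle_conv(M, F, (s, s), p)
        got = decrypt_decode(rc, KEYS, res.hout * res.wout)
        np.testing.assert_array_equal(got, want.reshape(-1))
        # ledger equality with the closed forms, single-ciphertext regime
        expect_conv = hs.predict_cost(
            "streamlined_convolution", {"h": h + 2 * p, "w": w + 2 * p,
                                        "fx": f, "fy": f}, PARAMS)
        if p:
            expect_conv = expect_conv + hs.predict_cost(
                "streamlined_padding", {"h0": h + 2 * p, "w0": w + 2 * p}, PARAMS)
            expect_conv.dc = 2
        assert (conv_rep.dc, conv_rep.osum, conv_rep.omul, conv_rep.orot) == \
            (expect_conv.dc, expect_conv.osum, expect_conv.omul, expect_conv.orot)
        expect_rt = hs.predict_cost(
            "rt_scbf_to_rc", {"h": h, "w": w, "hout": res.hout,
                              "wout": res.wout}, PARAMS)
        assert (rt_rep.dc, rt_rep.osum, rt_rep.omul, rt_rep.orot) == \
            (expect_rt.dc, expect_rt.osum, expect_rt.omul, expect_rt.orot)

    def test_chained_stride_two_convolutions(self, rng):
        M = rng.uniform(-1, 1, (16, 16))
        F1 = rng.uniform(-1, 1, (3, 3))
        F2 = rng.uniform(-1, 1, (2, 2))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        r1 = streamlined_convolution(ct, ConvSpec(Filter(F1), (2, 2)), layout)
        r2 = streamlined_convolution(r1.vector, ConvSpec(Filter(F2), (2, 2)),
                                     r1.layout)
        assert (r2.layout.Sx, r2.layout.Sy) == (4, 4)
        want = oracle_conv(oracle_conv(M, F1, (2, 2)), F2, (2, 2))
        got = decrypt_decode(rt_scbf_to_rc(r2.vector, r2.layout), KEYS,
                             r2.hout * r2.wout)
        np.testing.assert_array_equal(got, want.reshape(-1))
        # SCBF metadata predicts every output slot before the transformation
        full = decrypt_decode(r2.vector, KEYS)
        for i in range(r2.hout):
            for j in range(r2.wout):
                assert full[r2.layout.slot(i, j)] == pytest.approx(want[i, j],
                                                                   abs=1e-12)

    def test_multi_ciphertext_lift(self, rng):
        small = HEParams(N=16)
        skeys = keygen(small, 2)
        M = rng.uniform(-1, 1, (6, 6))
        F = rng.uniform(-1, 1, (3, 3))  # 4x4 output fits one ciphertext
        flat = np.zeros(48)  # 3 ciphertexts of 16 slots
        flat[:36] = M.reshape(-1)
        ct = encode_encrypt(flat, small, skeys)
        res = streamlined_convolution(ct, ConvSpec(Filter(F)),
                                      SCBFLayout.first_layer(6, 6))
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), skeys,
                             res.hout * res.wout)
        np.testing.assert_allclose(got, oracle_conv(M, F).reshape(-1), atol=1e-12)


class TestPadding:
    def test_zero_padding_is_free(self, rng):
        M = rng.uniform(-1, 1, (4, 4))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        with counter_scope() as scope:
            out, out_layout = streamlined_padding(ct, 0, layout)
        assert out is ct and out_layout is layout
        assert scope.report.as_dict()["osum"] == 0
        assert scope.report.omul == 0

    def test_first_layer_pad_on_enlarged_grid(self):
        layout, ct = encode_matrix(np.array([[1.0, 2], [3, 4]]), PARAMS, KEYS,
                                   grid=(4, 4))
        with counter_scope() as scope:
            out, out_layout = streamlined_padding(ct, 1, layout)
        assert (out_layout.h, out_layout.w) == (4, 4)
        got = decrypt_decode(rt_scbf_to_rc(out, out_layout), KEYS, 16)
        want = np.zeros((4, 4))
        want[1:3, 1:3] = [[1, 2], [3, 4]]
        np.testing.assert_array_equal(got, want.reshape(-1))
        rep = scope.report
        assert (rep.dc, rep.osum, rep.omul, rep.orot) == (1, 0, 1, 1)
        assert rep.omem <= 2

    def test_pad_then_convolve_equals_padded_convolution(self, rng):
        M = rng.uniform(-1, 1, (5, 5))
        F = rng.uniform(-1, 1, (3, 3))
        layout, ct = encode_matrix(M, PARAMS, KEYS, grid=(7, 7))
        direct = streamlined_convolution(ct, ConvSpec(Filter(F), (1, 1), 1), layout)
        padded, pl = streamlined_padding(ct, 1, layout)
        composed = streamlined_convolution(padded, ConvSpec(Filter(F)), pl)
        a = decrypt_decode(rt_scbf_to_rc(direct.vector, direct.layout), KEYS, 25)
        b = decrypt_decode(rt_scbf_to_rc(composed.vector, composed.layout), KEYS, 25)
        np.testing.assert_array_equal(a, b)

    def test_capacity_error_when_grid_too_small(self, rng):
        M = rng.uniform(-1, 1, (6, 6))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        with pytest.raises(CapacityError):
            streamlined_padding(ct, 1, layout)


class TestPooling:
    def test_window_mean_examples(self):
        layout, ct = encode_matrix(np.array([[1.0, 2], [3, 4]]), PARAMS, KEYS)
        res = average_pooling(ct, PoolSpec(2, 2), layout)
        assert decrypt_decode(res.vector, KEYS, 1)[0] == pytest.approx(2.5)
        layout, ct = encode_matrix(np.full((4, 4), 3.25), PARAMS, KEYS)
        res = average_pooling(ct, PoolSpec(2, 2), layout)
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), KEYS, 4)
        np.testing.assert_allclose(got, 3.25)

    def test_seeded_6x6_block_means(self, rng):
        M = rng.uniform(-1, 1, (6, 6))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        res = average_pooling(ct, PoolSpec(2, 2), layout)
        assert (res.hout, res.wout) == (3, 3)
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), KEYS, 9)
        np.testing.assert_allclose(got, oracle_pool(M, (2, 2)).reshape(-1),
                                   atol=1e-12)

    def test_identical_to_uniform_filter_convolution(self, rng):
        M = rng.uniform(-1, 1, (6, 6))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        pooled = average_pooling(ct, PoolSpec(2, 2), layout)
        uniform = streamlined_convolution(
            ct, ConvSpec(Filter(np.full((2, 2), 0.25)), (2, 2)), layout)
        np.testing.assert_array_equal(
            decrypt_decode(pooled.vector, KEYS),
            decrypt_decode(uniform.vector, KEYS))


class TestResultTransformation:
    def test_identity_layout_masks_prefix(self, rng):
        M = rng.uniform(-1, 1, (3, 3))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        got = decrypt_decode(rt_scbf_to_rc(ct, layout), KEYS)
        np.testing.assert_allclose(got[:9], M.reshape(-1), atol=1e-12)
        assert not got[9:].any()

    def test_after_strided_convolution(self, rng):
        M = rng.uniform(-1, 1, (6, 6))
        F = rng.uniform(-1, 1, (2, 2))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        res = streamlined_convolution(ct, ConvSpec(Filter(F), (2, 2)), layout)
        got = decrypt_decode(rt_scbf_to_rc(res.vector, res.layout), KEYS)
        want = rc_encode(oracle_conv(M, F, (2, 2)))
        np.testing.assert_array_equal(got[: want.size], want)
        assert not got[want.size:].any()


class TestDepthAndMemory:
    @pytest.mark.parametrize("chain", [1, 2, 3])
    def test_chain_depth_is_stages_plus_one(self, chain, rng):
        M = rng.uniform(-1, 1, (12, 12))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        with counter_scope() as scope:
            vec = ct
            for _ in range(chain):
                res = streamlined_convolution(
                    vec, ConvSpec(Filter(rng.uniform(-1, 1, (2, 2)))), layout)
                vec, layout = res.vector, res.layout
            rt_scbf_to_rc(vec, layout)
        assert scope.report.dc == chain + 1

    def test_conv_and_activation_depth_composition(self, rng):
        M = rng.uniform(-1, 1, (8, 8))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        with counter_scope() as scope:
            res = streamlined_convolution(
                ct, ConvSpec(Filter(rng.uniform(-1, 1, (2, 2)))), layout)
            squared = poly_eval(res.vector, [0, 0, 1])
            rt_scbf_to_rc(squared, res.layout)
        assert scope.report.dc == 3  # conv + square + transformation

    def test_working_set_bounds(self, rng):
        M = rng.uniform(-1, 1, (6, 6))
        F = rng.uniform(-1, 1, (3, 3))
        layout, ct = encode_matrix(M, PARAMS, KEYS)
        with counter_scope() as scope:
            streamlined_convolution(ct, ConvSpec(Filter(F)), layout)
        assert scope.report.omem <= 3
        layout, ct = encode_matrix(M, PARAMS, KEYS, grid=(8, 8))
        with counter_scope() as scope:
            streamlined_padding(ct, 1, layout)
        assert scope.report.omem <= 2
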