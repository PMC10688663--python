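"""Unit and property tests for the pure computational blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lwseg.blocks import (
    LHAParams,
    SSPDCParams,
    apply_lha,
    bilinear_upsample2x,
    channel_attention,
    max_unpool,
    maxpool_with_indices,
    spatial_attention,
    sspdc_forward,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def brute_force_pool(fm):
    """Exhaustive per-window 2x2 max pooling oracle."""
    h, w, c = fm.shape
    out = np.zeros((h // 2, w // 2, c))
    idx = np.zeros((h // 2, w // 2, c, 2), dtype=int)
    for i in range(h // 2):
        for j in range(w // 2):
            for ch in range(c):
                best, best_pos = -np.inf, None
                for di in range(2):
                    for dj in range(2):
                        v = fm[2 * i + di, 2 * j + dj, ch]
                        if v > best:
                            best, best_pos = v, (2 * i + di, 2 * j + dj)
                out[i, j, ch] = best
                idx[i, j, ch] = best_pos
    return out, idx


class TestChannelAttention:
    def test_zero_input_gives_half(self):
        fm = np.zeros((4, 4, 5))
        out = channel_attention(fm, LHAParams(channel_kernel=[0.3, -0.2, 0.7]))
        np.testing.assert_allclose(out, 0.5)

    def test_single_active_band_identity_kernel(self):
        # band 0 constant 1, others 0: max = avg = 1 so the identity-centre
        # kernel yields sigmoid(2) for band 0 and sigmoid(0) elsewhere
        fm = np.zeros((3, 3, 5))
        fm[:, :, 0] = 1.0
        out = channel_attention(fm, LHAParams(channel_kernel=[0.0, 1.0, 0.0]))
        np.testing.assert_allclose(out, [sigmoid(2.0), 0.5, 0.5, 0.5, 0.5],
                                   atol=1e-12)
        assert abs(out[0] - 0.8808) < 1e-4

    def test_rejects_non_finite(self):
        fm = np.zeros((2, 2, 3))
        fm[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            channel_attention(fm, LHAParams())

    @settings(deadline=None, max_examples=25)
    @given(hnp.arrays(np.float64, (4, 5, 8), elements=st.floats(-5, 5)),
           hnp.arrays(np.float64, (3,), elements=st.floats(-1, 1)))
    def test_weights_strictly_in_unit_interval(self, fm, kernel):
        out = channel_attention(fm, LHAParams(channel_kernel=kernel))
        assert out.shape == (8,)
        assert np.all(out > 0) and np.all(out < 1)


class TestSpatialAttention:
    def test_zero_input_gives_half_map(self):
        out = spatial_attention(np.zeros((5, 6, 3)), LHAParams())
        assert out.shape == (5, 6)
        np.testing.assert_allclose(out, 0.5)

    def test_center_tap_kernel_single_pixel(self):
        # channels (2, 4): max 4, mean 3, centre-tap kernel passes 7 through
        fm = np.zeros((1, 1, 2))
        fm[0, 0] = [2.0, 4.0]
        k = np.zeros((7, 7))
        k[3, 3] = 1.0
        out = spatial_attention(fm, LHAParams(spatial_kernel=k))
        np.testing.assert_allclose(out, sigmoid(7.0))
        assert abs(out[0, 0] - 0.99909) < 1e-5

    @settings(deadline=None, max_examples=25)
    @given(hnp.arrays(np.float64, (6, 7, 3), elements=st.floats(-5, 5)))
    def test_same_spatial_shape_and_range(self, fm):
        params = LHAParams(spatial_kernel=np.full((7, 7), 0.02))
        out = spatial_attention(fm, params)
        assert out.shape == fm.shape[:2]
        assert np.all((out > 0) & (out < 1))


class TestApplyLHA:
    def test_zero_parameters_quarter_scaling(self):
        fm = np.random.default_rng(0).normal(size=(8, 8, 5))
        out = apply_lha(fm, LHAParams())
        np.testing.assert_allclose(out, 0.25 * fm, rtol=1e-12)

    def test_zero_input_stays_zero(self):
        params = LHAParams(channel_kernel=[1.0, 2.0, 3.0],
                           spatial_kernel=np.ones((7, 7)))
        np.testing.assert_array_equal(apply_lha(np.zeros((4, 4, 2)), params), 0.0)

    @settings(deadline=None, max_examples=25)
    @given(hnp.arrays(np.float64, (4, 4, 3), elements=st.floats(-10, 10)))
    def test_never_amplifies(self, fm):
        params = LHAParams(channel_kernel=[0.5, -1.0, 0.2],
                           spatial_kernel=np.eye(7) * 0.3)
        out = apply_lha(fm, params)
        assert out.shape == fm.shape
        assert np.all(np.abs(out) <= np.abs(fm) + 1e-12)


class TestSSPDC:
    def test_identity_configuration(self):
        fm = np.random.default_rng(1).normal(size=(9, 11, 4))
        out = sspdc_forward(fm, SSPDCParams.identity(4))
        np.testing.assert_allclose(out, fm, rtol=1e-10, atol=1e-12)

    def test_constant_input_constant_interior(self):
        rng = np.random.default_rng(2)
        params = SSPDCParams(depthwise=rng.normal(size=(3, 3, 3, 3)),
                             pointwise=rng.normal(size=(6, 9)),
                             bias=rng.normal(size=6))
        out = sspdc_forward(np.full((16, 16, 3), 2.5), params)
        assert out.shape == (16, 16, 6)
        interior = out[3:-3, 3:-3]     # beyond the widest dilation halo
        np.testing.assert_allclose(
            interior, np.broadcast_to(interior[0, 0], interior.shape), rtol=1e-9)

    def test_output_channels_follow_pointwise(self):
        rng = np.random.default_rng(3)
        params = SSPDCParams(depthwise=rng.normal(size=(3, 5, 3, 3)),
                             pointwise=rng.normal(size=(8, 15)))
        assert sspdc_forward(rng.normal(size=(6, 6, 5)), params).shape == (6, 6, 8)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel mismatch"):
            sspdc_forward(np.zeros((4, 4, 3)), SSPDCParams.identity(5))


class TestPoolingAndUnpooling:
    def test_simple_window(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        pooled, idx = maxpool_with_indices(fm)
        assert pooled[0, 0, 0] == 4.0
        assert tuple(idx[0, 0, 0]) == (1, 1)

    def test_tie_breaks_first_row_major(self):
        pooled, idx = maxpool_with_indices(np.full((2, 2, 1), 5.0))
        assert pooled[0, 0, 0] == 5.0
        assert tuple(idx[0, 0, 0]) == (0, 0)

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError, match="even"):
            maxpool_with_indices(np.zeros((3, 4, 1)))

    @settings(deadline=None, max_examples=20)
    @given(hnp.arrays(np.float64, (8, 8, 2), elements=st.floats(-100, 100)))
    def test_matches_exhaustive_oracle(self, fm):
        pooled, idx = maxpool_with_indices(fm)
        exp_pool, exp_idx = brute_force_pool(fm)
        np.testing.assert_array_equal(pooled, exp_pool)
        np.testing.assert_array_equal(idx, exp_idx)

    def test_unpool_places_single_value(self):
        fm = np.array([[[4.0]]])
        idx = np.array([[[[1, 1]]]])
        np.testing.assert_array_equal(max_unpool(fm, idx),
                                      np.array([[0.0, 0.0], [0.0, 4.0]]).reshape(2, 2, 1))

    def test_unpool_nonzeros_at_argmax_positions(self, rng):
        fm = rng.normal(size=(10, 12, 3)) + 10.0   # positive so zeros are background
        pooled, idx = maxpool_with_indices(fm)
        up = max_unpool(pooled, idx)
        # positions of nonzeros equal the stored argmax indices exactly
        got = {(int(r), int(c), int(ch)) for r, c, ch in np.argwhere(up != 0)}
        want = set()
        for i in range(idx.shape[0]):
            for j in range(idx.shape[1]):
                for ch in range(idx.shape[2]):
                    want.add((int(idx[i, j, ch, 0]), int(idx[i, j, ch, 1]), ch))
        assert got == want

    def test_pool_of_unpool_is_identity(self, rng):
        fm = rng.normal(size=(16, 16, 4))
        pooled, idx = maxpool_with_indices(fm)
        roundtrip, _ = maxpool_with_indices(max_unpool(np.abs(pooled) + 1.0, idx))
        np.testing.assert_array_equal(roundtrip, np.abs(pooled) + 1.0)

    def test_index_outside_window_rejected(self):
        fm = np.ones((1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            max_unpool(fm, np.array([[[[2, 0]]]]))


class TestBilinearUpsample:
    def test_constant_map(self):
        out = bilinear_upsample2x(np.full((3, 5, 2), 7.0))
        assert out.shape == (6, 10, 2)
        np.testing.assert_allclose(out, 7.0)

    def test_single_pixel_extrapolates(self):
        np.testing.assert_allclose(bilinear_upsample2x(np.full((1, 1, 1), 3.0)),
                                   np.full((2, 2, 1), 3.0))

    def test_ramp_half_pixel_convention(self):
        # source samples (0, 1): output coordinates read -0.25, 0.25, 0.75,
        # 1.25 which clamp/interpolate to 0, 0.25, 0.75, 1
        fm = np.array([[0.0, 1.0]]).reshape(1, 2, 1)
        out = bilinear_upsample2x(fm)
        np.testing.assert_allclose(out[0, :, 0], [0.0, 0.25, 0.75, 1.0])
        np.testing.assert_allclose(out[1, :, 0], [0.0, 0.25, 0.75, 1.0])

    def test_deterministic(self, rng):
        fm = rng.normal(size=(5, 4, 3))
        np.testing.assert_array_equal(bilinear_upsample2x(fm), bilinear_upsample2x(fm))
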