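"""Snake convolution: coordinate laws, sampling oracle, zero-offset limit."""

import numpy as np
import pytest

from serpensgate import dysnake
from serpensgate.blocks import InvalidConfigError
from serpensgate.engine import Tensor, bilinear_sample


def zero_offsets(b=1, k=3, h=4, w=5):
    return Tensor(np.zeros((b, 2 * k, h, w), np.float32))


class TestSnakeCoordinates:
    def test_zero_offsets_axis_aligned(self):
        ys, xs = dysnake.snake_coordinates(zero_offsets(), "x", 4, 5)
        # kernel extends along width: (0,-1) (0,0) (0,+1) relative offsets
        np.testing.assert_allclose(ys.data[0, :, 2, 3], [2, 2, 2])
        np.testing.assert_allclose(xs.data[0, :, 2, 3], [2, 3, 4])
        ys, xs = dysnake.snake_coordinates(zero_offsets(), "y", 4, 5)
        np.testing.assert_allclose(ys.data[0, :, 2, 3], [1, 2, 3])
        np.testing.assert_allclose(xs.data[0, :, 3, 3], [3, 3, 3])

    def test_center_anchored_at_own_pixel(self, rng):
        off = Tensor(rng.uniform(-0.99, 0.99, (1, 6, 4, 5)).astype(np.float32))
        ys, xs = dysnake.snake_coordinates(off, "x", 4, 5)
        np.testing.assert_allclose(ys.data[0, 1], np.arange(4)[:, None]
                                   * np.ones((1, 5)))
        np.testing.assert_allclose(xs.data[0, 1], np.arange(5)[None, :]
                                   * np.ones((4, 1)))

    def test_constant_elastic_offsets_stretch_arms(self):
        off = Tensor(np.full((1, 6, 2, 2), 0.5, np.float32))
        _, xs = dysnake.snake_coordinates(off, "x", 2, 2)
        rel = xs.data[0, :, 0, 0] - 0.0
        np.testing.assert_allclose(rel, [-1.5, 0.0, 1.5])

    def test_perpendicular_drift_accumulates(self):
        """Drift offsets (0.2, 0.4) on the positive arm give drifts (0.2, 0.6)."""
        k = 5
        off = np.zeros((1, 2 * k, 1, 1), np.float32)
        off[0, k + 3] = 0.2
        off[0, k + 4] = 0.4
        ys, _ = dysnake.snake_coordinates(Tensor(off), "x", 1, 1)
        np.testing.assert_allclose(ys.data[0, 3:, 0, 0], [0.2, 0.6], atol=1e-6)

    def test_continuity_bound(self, rng):
        """Successive morph-axis coordinates differ from the unit step by < 1."""
        off = Tensor(rng.uniform(-0.999, 0.999, (2, 6, 5, 5)).astype(np.float32))
        _, xs = dysnake.snake_coordinates(off, "x", 5, 5)
        d = np.diff(xs.data, axis=1)
        assert np.all(np.abs(d - 1.0) < 1.0)

    def test_invalid_morph(self):
        with pytest.raises(InvalidConfigError):
            dysnake.snake_coordinates(zero_offsets(), "z", 4, 5)


class TestOffsets:
    def test_tanh_bound(self, rng):
        pred = dysnake.OffsetPredictor(4, 3)
        x = Tensor(rng.normal(0, 10, (2, 4, 6, 6)).astype(np.float32))
        off = pred(x)
        assert np.all(np.abs(off.data) < 1.0)
        assert off.shape == (2, 6, 6, 6)

    def test_zero_weights_give_straight_line(self, rng):
        pred = dysnake.OffsetPredictor(4, 3)
        pred.conv.weight.data[:] = 0.0
        pred.eval()
        x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        assert np.abs(pred(x).data).max() == 0.0

    def test_even_kernel_rejected(self):
        with pytest.raises(InvalidConfigError):
            dysnake.OffsetPredictor(4, 4)


def test_bilinear_sampler_matches_loop_oracle(rng):
    """Vectorised sampling equals a scalar per-point interpolation loop."""
    f = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    ys = rng.uniform(0, 3, (1, 3, 2, 2)).astype(np.float32)
    xs = rng.uniform(0, 3, (1, 3, 2, 2)).astype(np.float32)
    out = bilinear_sample(Tensor(f), Tensor(ys), Tensor(xs)).data
    for c in range(2):
        for k in range(3):
            for i in range(2):
                for j in range(2):
                    y, x = ys[0, k, i, j], xs[0, k, i, j]
                    y0, x0 = int(np.floor(y)), int(np.floor(x))
                    y0, x0 = min(y0, 2), min(x0, 2)
                    fy, fx = y - y0, x - x0
                    ref = (f[0, c, y0, x0] * (1 - fy) * (1 - fx)
                           + f[0, c, y0, x0 + 1] * (1 - fy) * fx
                           + f[0, c, y0 + 1, x0] * fy * (1 - fx)
                           + f[0, c, y0 + 1, x0 + 1] * fy * fx)
                    assert out[0, c, k, i, j] == pytest.approx(ref, abs=1e-5)


def _zero_the_offsets(ds: dysnake.DSConv):
    ds.offset.conv.weight.data[:] = 0.0
    ds.eval()


def test_zero_offset_equivalence_with_axis_aligned_conv(rng):
    """With zeroed offset weights each snake branch equals a plain axis-aligned
    (1xk / kx1) convolution with replicated borders, to 1e-5."""
    x = rng.normal(size=(1, 3, 7, 8)).astype(np.float32)
    for morph, pad in (("x", ((0, 0), (1, 1))), ("y", ((1, 1), (0, 0)))):
        ds = dysnake.DSConv(3, 4, 3, morph=morph)
        _zero_the_offsets(ds)
        got = ds.conv(ds.sample(Tensor(x))).data
        xp = np.pad(x, ((0, 0), (0, 0)) + pad, mode="edge")
        ref = np.zeros_like(got)
        w = ds.conv.weight.data.reshape(4, 3, 3)  # (out, c, kernel pos)
        for o in range(4):
            for c in range(3):
                for j in range(3):
                    if morph == "x":
                        ref[0, o] += w[o, c, j] * xp[0, c, :, j:j + 8]
                    else:
                        ref[0, o] += w[o, c, j] * xp[0, c, j:j + 7, :]
        np.testing.assert_allclose(got, ref, atol=1e-5)


def test_translation_consistency_zero_offsets(rng):
    """Whole-pixel input shifts shift the sampled convolution identically at
    zero offset (compared before the map-global normalisation, whose
    statistics are not translation invariant on finite maps)."""
    ds = dysnake.DSConv(2, 2, 3, morph="x")
    _zero_the_offsets(ds)
    x = rng.normal(size=(1, 2, 6, 10)).astype(np.float32)
    y = ds.conv(ds.sample(Tensor(x))).data
    y_shift = ds.conv(ds.sample(Tensor(np.roll(x, 2, axis=3)))).data
    np.testing.assert_allclose(y_shift[..., 3:9], y[..., 1:7], atol=1e-5)


class TestDySnakeBlocks:
    def test_three_branch_shape_and_count(self, rng):
        blk = dysnake.build_dysnakeconv(8, 8, 3)
        x = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
        assert blk(x).shape == (1, 8, 16, 16)
        # component hand-sum: std conv block + 2 snake branches + fuse block
        def snake_branch(c_in, c_out, k):
            return (c_in * 2 * k * 9 + 2 * 2 * k    # offset conv + BN
                    + c_in * k * c_out              # k-point conv
                    + 2 * c_out)                    # group norm
        expected = (8 * 8 * 9 + 16) + 2 * snake_branch(8, 8, 3) \
            + (24 * 8 + 16)
        assert blk.num_params() == (expected, 0)

    def test_c2f_dysnake_accepts_any_spatial_size(self, rng):
        blk = dysnake.build_c2f_dysnake(8, 8, True)
        for h, w in [(20, 20), (13, 17), (8, 32)]:
            x = Tensor(rng.normal(size=(1, 8, h, w)).astype(np.float32))
            assert blk(x).shape == (1, 8, h, w)

    def test_c2f_dysnake_count_matches_component_sum(self):
        blk = dysnake.build_c2f_dysnake(16, 16, True)
        total = blk.cv1.num_params()[0] + blk.cv2.num_params()[0]
        for b in blk.m:
            total += b.cv1.num_params()[0] + b.cv2.num_params()[0]
        assert blk.num_params() == (total, 0)

    def test_odd_output_required(self):
        with pytest.raises(InvalidConfigError):
            dysnake.build_c2f_dysnake(8, 7, True)
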