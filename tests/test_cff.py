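"""Properties of the fusion-block operators: pooling invariance, strided-conv
collisions, receptive fields, and the discrimination the concatenation buys."""

import numpy as np
import pytest

from cffemg.cff import (
    CffBlockConfig,
    ConvConfig,
    PoolConfig,
    ShapeError,
    cff_block,
    find_collision,
    max_pool,
    receptive_field,
    receptive_field_bruteforce,
    strided_conv,
)


class TestMaxPool:
    def test_constant_input(self):
        np.testing.assert_array_equal(max_pool(np.full(4, 3.7)), [3.7, 3.7])

    def test_per_window_max(self):
        np.testing.assert_array_equal(max_pool(np.array([1.0, 3, 2, 0])), [3, 2])

    def test_order_invariance_within_windows(self):
        # the two inputs differ only in within-window order; outputs collide
        a = max_pool(np.array([1.0, 3, 2, 0]))
        b = max_pool(np.array([3.0, 1, 0, 2]))
        np.testing.assert_array_equal(a, b)

    def test_output_length_formula(self):
        for L, s_p, s_s in [(10, 2, 2), (11, 3, 2), (7, 2, 1)]:
            out = max_pool(np.arange(L, dtype=float), PoolConfig(s_p, s_s))
            assert len(out) == (L - s_p) // s_s + 1

    def test_input_shorter_than_window_raises(self):
        with pytest.raises(ShapeError):
            max_pool(np.array([1.0]), PoolConfig(2, 2))

    def test_within_window_permutation_invariance_randomized(self):
        # >= 1000 trials: permuting samples inside pooling windows never
        # changes the pooled output, bit-for-bit
        rng = np.random.default_rng(0)
        for _ in range(1000):
            L = int(rng.integers(4, 40)) & ~1
            x = rng.normal(size=L)
            xp = x.copy()
            for t in range(0, L, 2):
                xp[t : t + 2] = xp[t : t + 2][rng.permutation(2)]
            np.testing.assert_array_equal(max_pool(x), max_pool(xp))


class TestStridedConv:
    def test_zero_kernel_gives_zero_output(self):
        y = strided_conv(np.random.default_rng(0).normal(size=8),
                         ConvConfig(kernel=np.zeros(3)))
        np.testing.assert_array_equal(y, 0.0)

    def test_printed_kernel_collision_pair(self):
        cfg = ConvConfig(kernel=np.array([-1.0, 1, 2]))
        y1 = strided_conv(np.array([1.0, 1, 1]), cfg)
        y2 = strided_conv(np.array([3.0, 1, 2]), cfg)
        assert y1[0] == y2[0] == 2.0

    def test_constant_input_with_rescaled_kernel_reproduces_output(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=4)
        x = rng.normal(size=4)
        y = strided_conv(x, ConvConfig(kernel=c))[0]
        a = 2.5
        c_prime = c * x / a
        y2 = strided_conv(np.full(4, a), ConvConfig(kernel=c_prime))[0]
        assert np.isclose(y, y2)

    def test_output_length_valid_and_same(self):
        x = np.arange(11, dtype=float)
        for k, s in [(3, 1), (3, 2), (4, 3)]:
            cfg_v = ConvConfig(kernel=np.ones(k), stride=s, padding="valid")
            cfg_s = ConvConfig(kernel=np.ones(k), stride=s, padding="same")
            assert len(strided_conv(x, cfg_v)) == (11 - k) // s + 1
            assert len(strided_conv(x, cfg_s)) == -(-11 // s)

    def test_matches_direct_dot_products(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        c = rng.normal(size=3)
        y = strided_conv(x, ConvConfig(kernel=c, stride=2))
        expected = [c @ x[2 * t : 2 * t + 3] for t in range(5)]
        np.testing.assert_allclose(y, expected)


class TestFindCollision:
    def test_printed_example(self):
        cfg = ConvConfig(kernel=np.array([-1.0, 1, 2]))
        x2 = find_collision(cfg, np.array([1.0, 1, 1]))
        np.testing.assert_array_equal(x2, [3.0, 1, 2])

    def test_k1_kernel_is_injective(self):
        assert find_collision(ConvConfig(kernel=np.array([2.0])),
                              np.array([1.0])) is None

    def test_all_zero_kernel_flagged_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            find_collision(ConvConfig(kernel=np.zeros(3)), np.ones(3))

    @pytest.mark.parametrize("seed", range(100))
    def test_constructed_collision_always_verifies(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        c = rng.normal(size=k)
        if rng.random() < 0.3:  # exercise the zero-weight path too
            c[rng.integers(k)] = 0.0
        if not np.any(c):
            c[0] = 1.0
        x = rng.normal(size=k)
        cfg = ConvConfig(kernel=c)
        x2 = find_collision(cfg, x)
        assert np.any(x2 != x)
        assert np.isclose(strided_conv(x, cfg)[0], strided_conv(x2, cfg)[0])


class TestReceptiveField:
    @pytest.mark.parametrize("n,k,expected", [(1, 3, 3), (2, 3, 5), (3, 3, 7)])
    def test_formula_examples(self, n, k, expected):
        assert receptive_field(n, k) == expected

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_formula_matches_bruteforce_sensitivity(self, n, k):
        assert receptive_field(n, k) == receptive_field_bruteforce(n, k, rng=n * 10 + k)

    def test_perturbation_outside_field_leaves_output_unchanged(self):
        # two stacked k=3 convs: indices 0..4 matter for y_0, index 5 does not
        rng = np.random.default_rng(0)
        kernels = [rng.normal(size=3) for _ in range(2)]

        def stack(x):
            for ker in kernels:
                x = strided_conv(x, ConvConfig(kernel=ker))
            return x[0]

        x = rng.normal(size=8)
        y0 = stack(x)
        x_out = x.copy()
        x_out[5] += 10
        assert np.isclose(stack(x_out), y0)
        x_in = x.copy()
        x_in[2] += 10
        assert not np.isclose(stack(x_in), y0)


class TestCffBlock:
    def block(self, c_in, filters, seed=0):
        rng = np.random.default_rng(seed)
        return CffBlockConfig(conv=ConvConfig(
            kernel=rng.normal(size=(filters, 3, c_in)), stride=2))

    def test_64_channel_input_gives_128_fused_channels(self):
        x = np.random.default_rng(1).normal(size=(10, 64))
        out = cff_block(x, self.block(64, 64))
        assert out.shape == (5, 128)

    def test_all_zero_input(self):
        out = cff_block(np.zeros((8, 4)), self.block(4, 6))
        np.testing.assert_array_equal(out, 0.0)

    def test_fusion_discriminates_where_single_branches_collide(self):
        # x1/x2 collide under pooling (within-window swap); x1/x3 collide
        # under the stride-2 conv (mass transfer in the kernel null space)
        rng = np.random.default_rng(2)
        kernel = rng.normal(size=(1, 3, 1))
        cfg = CffBlockConfig(conv=ConvConfig(kernel=kernel, stride=2))
        x1 = np.array([1.0, 3.0, 2.0, 0.5])
        x2 = np.array([3.0, 1.0, 2.0, 0.5])  # pool-collides with x1
        c = kernel[0, :, 0]
        x3 = x1.copy()  # conv-collides with x1 on the first step
        x3[0] += 1.0
        x3[2] -= c[0] / c[2]
        p = lambda x: max_pool(x)
        assert np.array_equal(p(x1), p(x2))
        y = lambda x: cff_block(x, cfg)
        f1, f2, f3 = y(x1), y(x2), y(x3)
        assert np.allclose(
            strided_conv(x1[:3], ConvConfig(kernel=c))[0],
            strided_conv(x3[:3], ConvConfig(kernel=c))[0])
        assert not np.allclose(f1, f2)
        assert not np.allclose(f1, f3)
        assert not np.allclose(f2, f3)

    def test_randomized_triples_have_no_joint_collision(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            kernel = rng.normal(size=(1, 3, 1))
            c = kernel[0, :, 0]
            cfg = CffBlockConfig(conv=ConvConfig(kernel=kernel, stride=2))
            x1 = rng.normal(size=6)
            x2 = x1.copy()
            x2[0], x2[1] = x2[1], x2[0]  # pool collision
            x3 = x1.copy()
            x3[0] += 1.0
            x3[2] -= c[0] / c[2]  # conv collision at step 0
            outs = [cff_block(x, cfg) for x in (x1, x2, x3)]
            if np.allclose(x1, x2):  # degenerate swap (equal values)
                continue
            assert not np.allclose(outs[0], outs[1])
            assert not np.allclose(outs[0], outs[2])

    def test_branch_shapes_always_agree_on_odd_lengths(self):
        x = np.random.default_rng(4).normal(size=(9, 3))
        out = cff_block(x, self.block(3, 5))
        assert out.shape == (5, 8)  # ceil(9/2) spatial, 3 + 5 channels
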