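"""Super token attention: association stochasticity, convexity, dense oracle."""

import numpy as np
import pytest

from serpensgate import super_token as st
from serpensgate.blocks import InvalidConfigError
from serpensgate.engine import Tensor


def grid(rng, b=1, c=4, h=4, w=4):
    return Tensor(rng.normal(size=(b, c, h, w)).astype(np.float32))


def dense_association_oracle(X, S, mask):
    """Unvectorised per-row masked softmax of X_i . S_j / sqrt(C)."""
    N, C = X.shape
    m = S.shape[0]
    Q = np.zeros((N, m))
    for i in range(N):
        logits = np.array([X[i] @ S[j] / np.sqrt(C) if mask[i, j] else -np.inf
                           for j in range(m)])
        e = np.exp(logits - logits[mask[i]].max())
        e[~mask[i]] = 0.0
        Q[i] = e / e.sum()
    return Q


class TestInitSuperTokens:
    def test_global_cell_is_global_mean(self, rng):
        x = grid(rng)
        tg = st.TokenGrid.from_map(x)
        sup = st.init_super_tokens(tg, 4, 4)
        assert sup.m == 1
        np.testing.assert_allclose(sup.S.data[0, 0],
                                   x.data[0].mean(axis=(1, 2)), atol=1e-6)

    def test_constant_map_gives_constant_tokens(self):
        x = Tensor(np.full((1, 3, 6, 6), 2.5, np.float32))
        sup = st.init_super_tokens(st.TokenGrid.from_map(x), 2, 3)
        np.testing.assert_allclose(sup.S.data, 2.5)

    def test_2x2_cell_means_hand_computed(self):
        vals = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        sup = st.init_super_tokens(st.TokenGrid.from_map(Tensor(vals)), 2, 2)
        np.testing.assert_allclose(sup.S.data[0, :, 0], [2.5, 4.5, 10.5, 12.5])

    def test_cell_larger_than_grid_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            st.init_super_tokens(st.TokenGrid.from_map(grid(rng)), 5, 2)

    def test_ceil_sized_edge_cells(self, rng):
        x = grid(rng, h=5, w=7)
        sup = st.init_super_tokens(st.TokenGrid.from_map(x), 2, 3)
        assert (sup.gh, sup.gw, sup.m) == (3, 3, 9)


class TestAssociation:
    def test_single_super_token_all_ones(self, rng):
        tg = st.TokenGrid.from_map(grid(rng))
        sup = st.init_super_tokens(tg, 4, 4)
        Q = st.token_association(tg, sup).Q.data
        np.testing.assert_allclose(Q, 1.0, atol=1e-7)

    def test_uniform_logits_give_uniform_neighborhood_weights(self):
        x = Tensor(np.ones((1, 2, 9, 9), np.float32))
        tg = st.TokenGrid.from_map(x)
        sup = st.init_super_tokens(tg, 3, 3)
        Q = st.token_association(tg, sup).Q.data[0]
        center_token = 4 * 9 + 4       # sees the full 3x3 neighbourhood
        nz = Q[center_token][Q[center_token] > 0]
        assert len(nz) == 9
        np.testing.assert_allclose(nz, 1 / 9, atol=1e-6)

    def test_rows_stochastic_columns_normalised(self, rng):
        tg = st.TokenGrid.from_map(grid(rng, h=6, w=8))
        sup = st.init_super_tokens(tg, 2, 2)
        a = st.token_association(tg, sup)
        np.testing.assert_allclose(a.Q.data.sum(-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(a.Qhat.data.sum(1), 1.0, atol=1e-5)
        assert a.d == 4

    def test_matches_dense_oracle(self, rng):
        for h, w, ch, cw in [(4, 4, 2, 2), (8, 8, 3, 3), (6, 8, 2, 4)]:
            tg = st.TokenGrid.from_map(grid(rng, h=h, w=w))
            sup = st.init_super_tokens(tg, ch, cw)
            Q = st.token_association(tg, sup).Q.data[0]
            offs = np.array([(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)])
            mask = st._neighbor_mask(h, w, ch, cw, offs)
            ref = dense_association_oracle(tg.X.data[0], sup.S.data[0], mask)
            np.testing.assert_allclose(Q, ref, atol=1e-5)


def test_ssn_reference_shares_support_and_stochasticity(rng):
    """The distance-form reference association is row-stochastic on the same
    3x3 support as the attention-form production path, but ranks differently
    (proximity vs correlation)."""
    tg = st.TokenGrid.from_map(grid(rng, h=6, w=6))
    sup = st.init_super_tokens(tg, 2, 2)
    q_ref = st.ssn_association_reference(tg, sup)
    q_prod = st.token_association(tg, sup).Q.data
    np.testing.assert_allclose(q_ref.sum(-1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(q_ref[0] > 0, q_prod[0] > 1e-12)


class TestUpdate:
    def test_identity_association_returns_tokens(self, rng):
        tg = st.TokenGrid.from_map(grid(rng, h=2, w=2))
        I = np.eye(4, dtype=np.float32)[None]
        a = st.AssociationMap(Tensor(I), Tensor(I), 4, np.zeros((1, 4), bool))
        S = st.update_super_tokens(a, tg)
        np.testing.assert_allclose(S.data, tg.X.data, atol=1e-6)

    def test_identical_tokens_collapse(self):
        x = Tensor(np.full((1, 3, 4, 4), 1.5, np.float32))
        tg = st.TokenGrid.from_map(x)
        sup = st.init_super_tokens(tg, 2, 2)
        a = st.token_association(tg, sup)
        S = st.update_super_tokens(a, tg)
        np.testing.assert_allclose(S.data, 1.5, atol=1e-6)

    def test_matches_dense_matrix_product(self, rng):
        X = rng.normal(size=(1, 6, 3)).astype(np.float32)
        Q = rng.uniform(0.1, 1.0, (1, 6, 2)).astype(np.float32)
        Q /= Q.sum(-1, keepdims=True)
        Qhat = Q / Q.sum(1, keepdims=True)
        a = st.AssociationMap(Tensor(Q), Tensor(Qhat), 3, np.zeros((1, 2), bool))
        tg = st.TokenGrid(Tensor(X), 2, 3)
        S = st.update_super_tokens(a, tg)
        np.testing.assert_allclose(S.data, Qhat.transpose(0, 2, 1) @ X, atol=1e-6)

    def test_convex_hull_invariant(self, rng):
        tg = st.TokenGrid.from_map(grid(rng, h=8, w=8))
        sup = st.init_super_tokens(tg, 3, 3)
        for _ in range(3):
            a = st.token_association(tg, sup)
            S = st.update_super_tokens(a, tg, sup)
            lo = tg.X.data.min(axis=1, keepdims=True) - 1e-5
            hi = tg.X.data.max(axis=1, keepdims=True) + 1e-5
            assert np.all(S.data >= lo) and np.all(S.data <= hi)
            sup = st.SuperTokenSet(S, 3, 3, sup.gh, sup.gw)


class TestComplexity:
    def test_unit_case(self):
        assert st.sts_complexity(1, 1)["total"] == 19

    def test_printed_decomposition(self):
        parts = st.sts_complexity(400, 256)
        assert parts["total"] == 1_945_600
        assert (parts["init"], parts["association"], parts["update"]) == \
            (400 * 256, 9 * 400 * 256, 9 * 400 * 256)

    def test_components_sum_for_random_sizes(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 5000))
            c = int(rng.integers(1, 512))
            parts = st.sts_complexity(n, c)
            assert parts["init"] + parts["association"] + parts["update"] \
                == parts["total"] == 19 * n * c


class TestAttentionBlock:
    def test_param_count_at_256(self):
        assert st.sta_param_count(256) == (262400, 162)
        assert sum(st.sta_param_count(256)) == 262562
        blk = st.StokenAttention(256)
        assert blk.num_params() == st.sta_param_count(256)

    def test_param_count_minimal_dim(self):
        assert st.sta_param_count(1) == (3 + 2, 162)
        assert sum(st.sta_param_count(1)) == 167

    def test_fixed_count_independent_of_dim(self):
        for d in (4, 64, 512):
            assert st.sta_param_count(d)[1] == 162

    def test_shape_preserving_any_extent(self, rng):
        blk = st.StokenAttention(8, grid=(5, 5), heads=2)
        for h, w in [(20, 20), (8, 8), (7, 11)]:
            x = grid(rng, c=8, h=h, w=w)
            assert blk(x).shape == x.shape

    def test_identity_limit(self):
        """Orthogonal tokens, 1x1 cells, sharp attention, identity projection:
        the block returns input + (association-upsampled) input."""
        C = 4
        x = (10 * np.eye(C, dtype=np.float32)).reshape(1, C, 2, 2, order="F")
        x = np.transpose(10 * np.eye(C, dtype=np.float32).reshape(2, 2, C),
                         (2, 0, 1))[None]
        blk = st.StokenAttention(C, grid=(1, 1), heads=1)
        blk.qkv.data[:] = 0.0
        blk.qkv.data[:, :C] = 50 * np.eye(C)       # sharp q
        blk.qkv.data[:, C:2 * C] = 50 * np.eye(C)  # sharp k
        blk.qkv.data[:, 2 * C:] = np.eye(C)        # v = S
        blk.proj.data[:] = np.eye(C)
        blk.proj_b.data[:] = 0.0
        y = blk(Tensor(x))
        np.testing.assert_allclose(y.data, 2 * x, atol=1e-3)

    def test_mirror_equivariance(self, rng):
        """The block has no preferred position: mirroring the map (a spatial
        permutation that maps grid cells onto grid cells and borders onto
        borders) mirrors the output exactly. Cyclic translation is only
        approximately equivariant on finite maps, because border cells keep
        truncated association neighbourhoods wherever they land."""
        blk = st.StokenAttention(4, grid=(2, 2), heads=2)
        x = grid(rng, c=4, h=8, w=8)
        flipped = Tensor(x.data[:, :, :, ::-1].copy())
        y = blk(x).data
        yf = blk(flipped).data
        np.testing.assert_allclose(yf, y[:, :, :, ::-1], atol=1e-5)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(InvalidConfigError):
            st.StokenAttention(6, heads=4)
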