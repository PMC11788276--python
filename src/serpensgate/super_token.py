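"""Super token attention: global context at sub-quadratic cost.

A feature map is flattened to N = H*W visual tokens X (N x C). A small set of
m super tokens S is initialised as grid-cell means and refined by a soft
k-means style association restricted to each token's 3x3 super-token
neighbourhood:

    Q = softmax(X S^T / sqrt(d))   (row-stochastic, d = C)
    S = Q_hat^T X                  (Q_hat = column-normalised Q)

Multi-head self-attention then runs over the m super tokens only, and the
result is mapped back to tokens by X' = Q S_att and added residually. One
sampling pass costs 19*N*C flops: N*C for the grid initialisation and 9*N*C
each for the sparse association and the update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import InvalidConfigError
from .engine import Tensor, softmax


# ---------------------------------------------------------------------------
# token containers
# ---------------------------------------------------------------------------

@dataclass
class TokenGrid:
    """Row-major flattening of a (B, C, H, W) feature map to (B, N, C)."""

    X: Tensor
    H: int
    W: int

    @property
    def N(self) -> int:
        return self.H * self.W

    @property
    def C(self) -> int:
        return self.X.shape[-1]

    @classmethod
    def from_map(cls, fmap: Tensor) -> "TokenGrid":
        B, C, H, W = fmap.shape
        return cls(fmap.reshape(B, C, H * W).transpose(0, 2, 1), H, W)

    def to_map(self) -> Tensor:
        B, N, C = self.X.shape
        return self.X.transpose(0, 2, 1).reshape(B, C, self.H, self.W)


@dataclass
class SuperTokenSet:
    S: Tensor          # (B, m, C)
    grid_h: int        # cell height h
    grid_w: int        # cell width w
    gh: int            # super-token rows = ceil(H / h)
    gw: int            # super-token cols = ceil(W / w)

    @property
    def m(self) -> int:
        return self.gh * self.gw


@dataclass
class AssociationMap:
    """Row-stochastic token/super-token association and its column norm."""

    Q: Tensor          # (B, N, m), <= 9 nonzeros per row
    Qhat: Tensor       # column-normalised Q
    d: int             # scaling constant = channel count C
    empty_columns: np.ndarray  # (B, m) flags: columns with no support


def _cell_index(H: int, W: int, h: int, w: int) -> tuple[np.ndarray, int, int]:
    """Map each token (row-major) to its super-token cell; ceil-sized edge cells."""
    gh, gw = -(-H // h), -(-W // w)
    rows = np.arange(H) // h
    cols = np.arange(W) // w
    cell = (rows[:, None] * gw + cols[None, :]).ravel()
    return cell, gh, gw


def _neighbor_mask(H: int, W: int, h: int, w: int,
                   offsets: np.ndarray) -> np.ndarray:
    """(N, m) boolean support: token i may associate with the 3x3 cell
    neighbourhood given by `offsets` (pairs of (dy, dx) cell shifts)."""
    cell, gh, gw = _cell_index(H, W, h, w)
    cr, cc = cell // gw, cell % gw
    mask = np.zeros((H * W, gh * gw), dtype=bool)
    for dy, dx in offsets:
        nr, nc = cr + dy, cc + dx
        ok = (nr >= 0) & (nr < gh) & (nc >= 0) & (nc < gw)
        mask[np.arange(H * W)[ok], (nr * gw + nc)[ok]] = True
    return mask


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def init_super_tokens(tokens: TokenGrid, h: int, w: int) -> SuperTokenSet:
    """Initial super tokens: the mean of the tokens in each grid cell."""
    if h > tokens.H or w > tokens.W:
        raise InvalidConfigError(
            f"grid cell ({h}x{w}) larger than token grid ({tokens.H}x{tokens.W})")
    if h < 1 or w < 1:
        raise InvalidConfigError("grid cell sizes must be positive")
    cell, gh, gw = _cell_index(tokens.H, tokens.W, h, w)
    m = gh * gw
    # averaging matrix A (m, N): A[j, i] = 1/|cell j| if token i in cell j
    counts = np.bincount(cell, minlength=m).astype(np.float32)
    A = np.zeros((m, tokens.N), dtype=np.float32)
    A[cell, np.arange(tokens.N)] = 1.0 / counts[cell]
    S = Tensor(A) @ tokens.X          # (m, N) @ (B, N, C) -> (B, m, C)
    return SuperTokenSet(S, h, w, gh, gw)


def token_association(tokens: TokenGrid, supers: SuperTokenSet,
                      neighbor_offsets: np.ndarray | None = None) -> AssociationMap:
    """Sparse soft association over each token's 3x3 super-token neighbourhood.

    Logits are X_i . S_j / sqrt(d) with d = C; softmax is taken over the
    (at most 9) super tokens in the token's cell neighbourhood, so every row
    of Q sums to one.
    """
    if neighbor_offsets is None:
        neighbor_offsets = np.array([(dy, dx) for dy in (-1, 0, 1)
                                     for dx in (-1, 0, 1)])
    d = tokens.C
    logits = (tokens.X @ supers.S.transpose(0, 2, 1)) * (1.0 / math.sqrt(d))
    mask = _neighbor_mask(tokens.H, tokens.W, supers.grid_h, supers.grid_w,
                          neighbor_offsets)
    bias = np.where(mask, 0.0, -1e9).astype(np.float32)[None]
    Q = softmax(logits + Tensor(bias), axis=-1)
    colsum = Q.sum(axis=1, keepdims=True)                      # (B, 1, m)
    empty = colsum.data[:, 0] <= 1e-12
    Qhat = Q / colsum.clamp(lo=1e-12)
    return AssociationMap(Q, Qhat, d, empty)


def update_super_tokens(assoc: AssociationMap, tokens: TokenGrid,
                        previous: SuperTokenSet | None = None) -> Tensor:
    """S = Q_hat^T X — each super token a convex combination of its tokens.

    A super token whose Q column is all zero keeps its previous value (the
    flag lives in ``assoc.empty_columns``); this requires `previous`.
    """
    S = assoc.Qhat.transpose(0, 2, 1) @ tokens.X
    if assoc.empty_columns.any():
        if previous is None:
            raise ValueError("empty association column but no previous super tokens")
        keep = Tensor(assoc.empty_columns[..., None].astype(np.float32))
        S = S * (1.0 - keep) + previous.S * keep
    return S


def ssn_association_reference(tokens: TokenGrid, supers: SuperTokenSet,
                              neighbor_offsets: np.ndarray | None = None
                              ) -> np.ndarray:
    """Distance-form association Q_ij = exp(-||X_i - S_j||^2) of the
    superpixel-sampling ancestor, row-normalised over the same 3x3 support.

    Reference implementation only: the production path uses the attention-form
    softmax of scaled dot products, which differs numerically (it ranks by
    correlation, not Euclidean proximity). Kept for comparison studies.
    """
    if neighbor_offsets is None:
        neighbor_offsets = np.array([(dy, dx) for dy in (-1, 0, 1)
                                     for dx in (-1, 0, 1)])
    X = tokens.X.data
    S = supers.S.data
    d2 = ((X[:, :, None, :] - S[:, None, :, :]) ** 2).sum(-1)
    mask = _neighbor_mask(tokens.H, tokens.W, supers.grid_h, supers.grid_w,
                          neighbor_offsets)
    q = np.where(mask[None], np.exp(-(d2 - d2.min(-1, keepdims=True))), 0.0)
    return q / q.sum(-1, keepdims=True)


def sts_complexity(N: int, C: int) -> dict[str, int]:
    """Flop count of one super-token sampling pass: 19*N*C total.

    Components: N*C (grid initialisation), 9*N*C (sparse association),
    9*N*C (super-token update).
    """
    if N < 1 or C < 1:
        raise InvalidConfigError("N and C must be >= 1")
    parts = {"init": N * C, "association": 9 * N * C, "update": 9 * N * C}
    parts["total"] = sum(parts.values())
    assert parts["total"] == 19 * N * C
    return parts


# ---------------------------------------------------------------------------
# the attention block
# ---------------------------------------------------------------------------

def _identity_scatter_kernels() -> tuple[np.ndarray, np.ndarray]:
    """The two frozen 3x3 kernels implementing the 9-neighbourhood gather and
    scatter as convolution-style unfold/fold (81 one-hot entries each)."""
    unfold = np.zeros((9, 1, 3, 3), dtype=np.float32)
    for j in range(9):
        unfold[j, 0, j // 3, j % 3] = 1.0
    fold = unfold[:, :, ::-1, ::-1].copy()
    return unfold, fold


class StokenAttention(nn.Module):
    """Super token attention block (shape-preserving, residual).

    Parameters: a bias-free 1x1 qkv projection (3*dim^2), a biased 1x1 output
    projection (dim^2 + dim) and the two frozen unfold/fold kernels (2*81,
    non-trainable). Default grid cell is 5x5 — m = 16 super tokens on the
    20x20 map the block sits on; non-divisible extents get ceil-sized edge
    cells. `n_iter` sampling iterations (default 1), `heads` attention heads.
    """

    def __init__(self, dim: int, grid: tuple[int, int] = (5, 5),
                 n_iter: int = 1, heads: int = 4):
        super().__init__()
        if dim % heads:
            raise InvalidConfigError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.grid, self.n_iter, self.heads = dim, grid, n_iter, heads
        scale = 1.0 / math.sqrt(dim)
        rng = np.random.default_rng(dim)
        self.qkv = nn.Parameter(rng.normal(0, scale, (dim, 3 * dim)).astype(np.float32))
        self.proj = nn.Parameter(rng.normal(0, scale, (dim, dim)).astype(np.float32))
        self.proj_b = nn.Parameter(np.zeros(dim, dtype=np.float32))
        unfold, fold = _identity_scatter_kernels()
        self.unfold_kernel = nn.Buffer(unfold)
        self.fold_kernel = nn.Buffer(fold)

    def neighbor_offsets(self) -> np.ndarray:
        """Decode the (dy, dx) cell shifts from the frozen unfold kernel."""
        k = self.unfold_kernel.data
        offs = [(int(np.argwhere(k[j, 0])[0][0]) - 1,
                 int(np.argwhere(k[j, 0])[0][1]) - 1) for j in range(k.shape[0])]
        return np.array(offs)

    def _attend(self, S: Tensor) -> Tensor:
        B, m, C = S.shape
        h, dh = self.heads, C // self.heads
        qkv = S @ self.qkv                                 # (B, m, 3C)
        q = qkv[:, :, :C].reshape(B, m, h, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, C:2 * C].reshape(B, m, h, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * C:].reshape(B, m, h, dh).transpose(0, 2, 1, 3)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, m, C)
        return out @ self.proj + self.proj_b

    def forward(self, x: Tensor) -> Tensor:
        tokens = TokenGrid.from_map(x)
        h = min(self.grid[0], tokens.H)
        w = min(self.grid[1], tokens.W)
        supers = init_super_tokens(tokens, h, w)
        offsets = self.neighbor_offsets()
        assoc = None
        for _ in range(self.n_iter):
            assoc = token_association(tokens, supers, offsets)
            supers = SuperTokenSet(update_super_tokens(assoc, tokens, supers),
                                   h, w, supers.gh, supers.gw)
        S_att = self._attend(supers.S)
        X_up = assoc.Q @ S_att                              # token upsampling
        return x + TokenGrid(X_up, tokens.H, tokens.W).to_map()


def sta_forward(features: Tensor, n_iter: int = 1, grid: tuple[int, int] = (5, 5),
                heads: int = 4) -> Tensor:
    """Functional form of :class:`StokenAttention` with fresh weights."""
    return StokenAttention(features.shape[1], grid, n_iter, heads)(features)


def sta_param_count(dim: int) -> tuple[int, int]:
    """(trainable, fixed) parameter count of the attention block at `dim`
    channels: 3*dim^2 + dim^2 + dim trainable, 162 fixed."""
    if dim < 1:
        raise InvalidConfigError(f"dim must be >= 1, got {dim}")
    return 3 * dim * dim + dim * dim + dim, 162
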