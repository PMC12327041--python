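"""Encoder building blocks.

Three block families make up the feature-extraction backbone:

* :class:`GRBlock` — shallow stage. Parallel two-branch downsampling (max
  pooling and strided 1x1 convolution feeding asymmetric 1x3/3x1 convs),
  channel concatenation, then a *cross* residual pair: the second residual
  sum reaches back over the intermediate map to the concatenated features.
* :class:`WGRBlock` — deeper stages. One max-pooling branch plus three
  stride-2 convolutional branches (two of them expanded by asymmetric conv
  pairs), concatenated and fused by a stacked-conv residual.
* :class:`OTBlock` — attention refinement of the top stage: outlooker
  (neighborhood) attention layers on the full token grid, a patch-projection
  downsampling with learned positional embedding, transformer self-attention
  layers, and bilinear re-expansion back to the stage resolution.

All convolutions are stride-1 'same'-padded unless noted; every convolution
is followed by batch normalization, with ReLU only where the block
definition calls for it.  Blocks operate on batched NCHW tensors.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.tensor import no_grad


def _check_even(x: Tensor) -> None:
    h, w = x.shape[2], x.shape[3]
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for a downsampling block, got {h}x{w}")


def _check_channels(x: Tensor, cin: int) -> None:
    if x.shape[1] != cin:
        raise ValueError(f"expected {cin} input channels, got {x.shape[1]}")


class GRBlock(nn.Module):
    """Shallow downsampling block: 3-branch parallel head + cross residual.

    Output channel count is ``cout``; each of the three parallel branches
    emits ``branch`` channels, so the concatenated map has ``3*branch``.
    """

    def __init__(self, cin: int, cout: int, branch: int, rng: np.random.Generator):
        super().__init__()
        self.cin = cin
        self.b1_conv = nn.ConvBN(cin, branch, 3, rng=rng)          # after max pool
        self.b2_down = nn.ConvBN(cin, branch, 1, stride=2, rng=rng)
        self.b2_conv = nn.ConvBN(branch, branch, (1, 3), rng=rng)
        self.b3_down = nn.ConvBN(cin, branch, 1, stride=2, rng=rng)
        self.b3_conv = nn.ConvBN(branch, branch, (3, 1), rng=rng)
        h = 3 * branch
        self.mid_conv3 = nn.ConvBN(h, cout, 3, rng=rng)     # C33(H)
        self.mid_conv1 = nn.ConvBN(h, cout, 1, rng=rng)     # C111(H), stride 1 (see note)
        self.out_conv3 = nn.ConvBN(cout, cout, 3, rng=rng)  # C33(M)
        self.out_conv1 = nn.ConvBN(h, cout, 1, rng=rng)     # C11(H) — the cross residual

    def forward(self, x: Tensor) -> Tensor:
        _check_even(x)
        _check_channels(x, self.cin)
        h = nn.concat([
            self.b1_conv(nn.maxpool2x2(x)),
            self.b2_conv(self.b2_down(x)),
            self.b3_conv(self.b3_down(x)),
        ], axis=1)
        m = nn.relu(self.mid_conv3(h) + self.mid_conv1(h))
        return nn.relu(self.out_conv3(m) + self.out_conv1(h))


class WGRBlock(nn.Module):
    """Wide downsampling block: six-way concat + stacked-conv residual."""

    def __init__(self, cin: int, cout: int, branch: int, rng: np.random.Generator):
        super().__init__()
        self.cin = cin
        self.g1 = nn.ConvBN(cin, branch, 1, stride=2, rng=rng)       # C111(F)
        self.g2 = nn.ConvBN(cin, branch, 1, rng=rng)                 # C11 after max pool
        self.s1_down = nn.ConvBN(cin, branch, 1, stride=2, rng=rng)  # s1
        self.s2_down = nn.ConvBN(cin, branch, 1, stride=2, rng=rng)
        self.s2_conv = nn.ConvBN(branch, branch, 3, rng=rng)         # s2
        self.s1_13 = nn.ConvBN(branch, branch, (1, 3), rng=rng)
        self.s1_31 = nn.ConvBN(branch, branch, (3, 1), rng=rng)
        self.s2_13 = nn.ConvBN(branch, branch, (1, 3), rng=rng)
        self.s2_31 = nn.ConvBN(branch, branch, (3, 1), rng=rng)
        g = 6 * branch
        self.fuse_a = nn.ConvBN(g, cout, 3, rng=rng)
        self.fuse_b = nn.ConvBN(cout, cout, 3, rng=rng)
        self.fuse_res = nn.ConvBN(g, cout, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_even(x)
        _check_channels(x, self.cin)
        s1 = self.s1_down(x)
        s2 = self.s2_conv(self.s2_down(x))
        g = nn.concat([
            self.g1(x),
            self.g2(nn.maxpool2x2(x)),
            self.s1_13(s1),
            self.s1_31(s1),
            self.s2_13(s2),
            self.s2_31(s2),
        ], axis=1)
        return nn.relu(self.fuse_b(self.fuse_a(g)) + self.fuse_res(g))


class OutlookAttention(nn.Module):
    """Multi-head outlook attention over K x K neighborhoods.

    For every grid location, a K^2 x K^2 attention matrix per head is
    predicted linearly from the center token, softmax-normalized over its
    last axis (then restricted to in-bounds neighbors and renormalized), and
    applied to linearly projected values of the K x K
    neighborhood; overlapping windows are fold-accumulated back onto the
    grid, normalized by the per-pixel overlap count (so a constant grid maps
    to a constant grid), and passed through the output projection.
    """

    def __init__(self, dim: int, heads: int, k: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"token dim {dim} not divisible by heads {heads}")
        if k % 2 == 0:
            raise ValueError("neighborhood size K must be odd")
        self.dim, self.heads, self.k = dim, heads, k
        self.v = nn.Linear(dim, dim, bias=False, rng=rng, std=0.02)
        self.attn = nn.Linear(dim, heads * k**2 * k**2, rng=rng, std=0.02)
        self.proj = nn.Linear(dim, dim, rng=rng, std=0.02)

    def attention_weights(self, x: Tensor) -> Tensor:
        """Softmax-normalized attention, shape [N, heads, H*W, K^2, K^2]."""
        n, h, w, _ = x.shape
        k2 = self.k ** 2
        logits = self.attn(x).reshape(n, h * w, self.heads, k2, k2).transpose(0, 2, 1, 3, 4)
        return nn.softmax(logits, axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, d = x.shape
        hd = d // self.heads
        k2 = self.k ** 2
        attn = self.attention_weights(x)
        # restrict attention to neighbors that exist (no probability mass on
        # the zero padding) and renormalize, so a constant grid is a fixed
        # point of the aggregation
        with no_grad():
            valid = nn.unfold(Tensor(np.ones((1, 1, h, w), dtype=np.float32)), self.k)
        mask = Tensor(valid.data.reshape(1, 1, k2, h * w).transpose(0, 1, 3, 2)[:, :, :, None, :])
        attn = attn * mask
        attn = attn * ((attn.sum(axis=-1, keepdims=True) + 1e-12) ** -1.0)
        v = self.v(x)                                      # [N,H,W,D]
        v = v.transpose(0, 3, 1, 2)                        # [N,D,H,W]
        v = nn.unfold(v, self.k)                           # [N,D,K2,HW]
        v = v.reshape(n, self.heads, hd, k2, h * w).transpose(0, 1, 4, 3, 2)
        out = attn @ v                                     # [N,heads,HW,K2,hd]
        out = out.transpose(0, 1, 4, 3, 2).reshape(n, d, k2, h * w)
        out = nn.fold(out, self.k, (h, w))                 # [N,D,H,W]
        ones = Tensor(np.ones((1, 1, k2, h * w), dtype=np.float32))
        counts = nn.fold(ones, self.k, (h, w)).data        # overlap count per pixel
        out = out * Tensor(1.0 / counts)
        return self.proj(out.transpose(0, 2, 3, 1))


class SelfAttention(nn.Module):
    """Standard multi-head scaled-dot-product self-attention on [N,T,D]."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"token dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.q = nn.Linear(dim, dim, rng=rng, std=0.02)
        self.k = nn.Linear(dim, dim, rng=rng, std=0.02)
        self.v = nn.Linear(dim, dim, rng=rng, std=0.02)
        self.proj = nn.Linear(dim, dim, rng=rng, std=0.02)

    def attention_weights(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        hd = d // self.heads
        q = self.q(x).reshape(n, t, self.heads, hd).transpose(0, 2, 1, 3)
        k = self.k(x).reshape(n, t, self.heads, hd).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        return nn.softmax(logits, axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        hd = d // self.heads
        attn = self.attention_weights(x)
        v = self.v(x).reshape(n, t, self.heads, hd).transpose(0, 2, 1, 3)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(out)


class OutlookerLayer(nn.Module):
    """Pre-norm residual outlooker: h' = MHOA(LN(h)) + h; out = MLP(LN(h')) + h'."""

    def __init__(self, dim: int, heads: int, k: int, mlp_hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = nn.LayerNorm(dim)
        self.mhoa = OutlookAttention(dim, heads, k, rng)
        self.ln2 = nn.LayerNorm(dim)
        self.mlp = nn.MLP(dim, mlp_hidden, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.mhoa(self.ln1(x)) + x
        return self.mlp(self.ln2(h)) + h


class TransformerLayer(nn.Module):
    """Pre-norm residual transformer: G' = MHSA(LN(G)) + G; out = MLP(LN(G')) + G'."""

    def __init__(self, dim: int, heads: int, mlp_hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = nn.LayerNorm(dim)
        self.mhsa = SelfAttention(dim, heads, rng)
        self.ln2 = nn.LayerNorm(dim)
        self.mlp = nn.MLP(dim, mlp_hidden, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        g = self.mhsa(self.ln1(x)) + x
        return self.mlp(self.ln2(g)) + g


class OTBlock(nn.Module):
    """Outlooker + transformer refinement of the top encoder stage.

    Steps: 1x1 token embedding of the stage-4 feature map; ``outlook_depth``
    outlooker layers on the full grid; non-overlapping ``patch_step`` patch
    flattening projected to the token dim with a learned positional
    embedding added; ``transformer_depth`` self-attention layers; bilinear
    re-expansion to the stage grid and projection back to the stage channel
    count, so the block preserves its input shape.
    """

    def __init__(self, cin: int, grid: tuple[int, int], dim: int, heads: int,
                 k: int, outlook_depth: int, transformer_depth: int,
                 outlook_mlp_hidden: int, transformer_mlp_hidden: int,
                 patch_step: int, rng: np.random.Generator):
        super().__init__()
        gh, gw = grid
        if gh % patch_step or gw % patch_step:
            raise ValueError(
                f"stage grid {gh}x{gw} not divisible by patch step {patch_step}")
        self.cin, self.patch_step = cin, patch_step
        self.grid = grid
        self.embed = nn.Linear(cin, dim, rng=rng, std=0.02)
        self.outlookers = [OutlookerLayer(dim, heads, k, outlook_mlp_hidden, rng)
                           for _ in range(outlook_depth)]
        self.patch_proj = nn.Linear(patch_step**2 * dim, dim, rng=rng, std=0.02)
        n_tok = (gh // patch_step) * (gw // patch_step)
        self.pos = Tensor(rng.normal(0.0, 0.02, (n_tok, dim)).astype(np.float32), requires_grad=True)
        self.transformers = [TransformerLayer(dim, heads, transformer_mlp_hidden, rng)
                             for _ in range(transformer_depth)]
        self.out_proj = nn.Linear(dim, cin, rng=rng, std=0.02)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        if (h, w) != self.grid:
            raise ValueError(f"expected {self.grid} grid, got {(h, w)}")
        s = self.patch_step
        tokens = self.embed(x.transpose(0, 2, 3, 1))       # [N,H,W,D]
        for layer in self.outlookers:
            tokens = layer(tokens)
        d = tokens.shape[-1]
        # patch flattening: [N, H/s, s, W/s, s, D] -> [N, T, s*s*D]
        patches = tokens.reshape(n, h // s, s, w // s, s, d)
        patches = patches.transpose(0, 1, 3, 2, 4, 5).reshape(n, (h // s) * (w // s), s * s * d)
        g = self.patch_proj(patches) + self.pos
        for layer in self.transformers:
            g = layer(g)
        g = g.reshape(n, h // s, w // s, d).transpose(0, 3, 1, 2)
        g = nn.upsample_bilinear(g, s)                     # back to [N,D,H,W]
        return self.out_proj(g.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
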