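"""Encoder block semantics, checked against naive loop oracles."""

import numpy as np
import pytest

import grotunet.nn as nn
from grotunet.blocks import (GRBlock, OTBlock, OutlookAttention, OutlookerLayer,
                             SelfAttention, TransformerLayer, WGRBlock)
from grotunet.nn import Tensor

from conftest import zero_params

BN_SCALE = 1.0 / np.sqrt(1.0 + 1e-5)  # eval-mode BN with fresh running stats


# -- naive reference implementations (loops, float64) -------------------------

def conv_ref(x, w, stride=1, pad=None):
    """Plain-loop cross-correlation; x [H,W,C], w [O,C,kh,kw]."""
    o, c, kh, kw = w.shape
    ph, pw = (kh // 2, kw // 2) if pad is None else pad
    xp = np.pad(x.astype(np.float64), ((ph, ph), (pw, pw), (0, 0)))
    ho = (x.shape[0] + 2 * ph - kh) // stride + 1
    wo = (x.shape[1] + 2 * pw - kw) // stride + 1
    y = np.zeros((ho, wo, o))
    for i in range(ho):
        for j in range(wo):
            patch = xp[i * stride:i * stride + kh, j * stride:j * stride + kw]
            for k in range(o):
                y[i, j, k] = (patch * w[k].transpose(1, 2, 0)).sum()
    return y


def maxpool_ref(x):
    h, w, c = x.shape
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


def avg_weights(o, c, kh, kw):
    return np.full((o, c, kh, kw), 1.0 / (kh * kw * c))


def set_averaging(block):
    """Give every conv in the block averaging weights; leave BN at defaults
    and put the block in eval mode so BN is a pure 1/sqrt(1+eps) scale."""
    for m in block.modules():
        if isinstance(m, nn.Conv2d):
            o, c, kh, kw = m.weight.data.shape
            m.weight.data[...] = 1.0 / (kh * kw * c)
            if m.bias is not None:
                m.bias.data[...] = 0.0
    block.eval()


def run_block(block, x_hwc):
    out = block(Tensor(x_hwc.transpose(2, 0, 1)[None].astype(np.float32)))
    return out.data[0].transpose(1, 2, 0)


# -- GRblock ------------------------------------------------------------------

def test_grblock_zero_params_zero_output(rng):
    blk = GRBlock(3, 8, 4, rng)
    zero_params(blk)
    out = run_block(blk, rng.normal(0, 1, (8, 8, 3)))
    assert np.all(out == 0.0)


@pytest.mark.parametrize("hw", [(8, 8), (12, 20), (256, 256)])
def test_grblock_halves_spatial_dims(rng, hw):
    blk = GRBlock(3, 4, 2, rng)
    blk.eval()
    out = run_block(blk, rng.normal(0, 1, (*hw, 3)).astype(np.float32))
    assert out.shape == (hw[0] // 2, hw[1] // 2, 4)
    assert (out >= 0).all()  # final ReLU


def test_grblock_rejects_odd_dims_and_wrong_channels(rng):
    blk = GRBlock(3, 4, 2, rng)
    with pytest.raises(ValueError, match="even"):
        blk(Tensor(np.zeros((1, 3, 7, 8), dtype=np.float32)))
    with pytest.raises(ValueError, match="channels"):
        blk(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))


def test_grblock_matches_hand_composition_with_averaging_kernels(rng):
    """With every conv an averaging kernel, the block must equal the naive
    loop composition of its definition (three-branch concat, then the two
    cross-residual sums)."""
    blk = GRBlock(1, 2, 2, rng)
    set_averaging(blk)
    x = np.ones((4, 4, 1))
    got = run_block(blk, x)

    s = BN_SCALE
    b1 = conv_ref(maxpool_ref(x), avg_weights(2, 1, 3, 3)) * s
    down = conv_ref(x, avg_weights(2, 1, 1, 1), stride=2) * s
    b2 = conv_ref(down, avg_weights(2, 2, 1, 3)) * s
    b3 = conv_ref(down, avg_weights(2, 2, 3, 1)) * s
    h = np.concatenate([b1, b2, b3], axis=-1)
    m = np.maximum(conv_ref(h, avg_weights(2, 6, 3, 3)) * s
                   + conv_ref(h, avg_weights(2, 6, 1, 1)) * s, 0.0)
    want = np.maximum(conv_ref(m, avg_weights(2, 2, 3, 3)) * s
                      + conv_ref(h, avg_weights(2, 6, 1, 1)) * s, 0.0)
    np.testing.assert_allclose(got, want, atol=1e-5)


# -- WGRblock -----------------------------------------------------------------

def test_wgrblock_zero_params_zero_output(rng):
    blk = WGRBlock(4, 8, 4, rng)
    zero_params(blk)
    out = run_block(blk, rng.normal(0, 1, (8, 8, 4)))
    assert np.all(out == 0.0)


def test_wgrblock_concat_width_is_six_branches(rng):
    blk = WGRBlock(4, 8, 5, rng)
    assert blk.fuse_a.conv.weight.shape[1] == 6 * 5
    assert blk.fuse_res.conv.weight.shape[1] == 6 * 5


@pytest.mark.parametrize("hw", [(8, 8), (6, 10)])
def test_wgrblock_halves_and_is_nonnegative(rng, hw):
    blk = WGRBlock(3, 6, 4, rng)
    blk.eval()
    out = run_block(blk, rng.normal(0, 1, (*hw, 3)))
    assert out.shape == (hw[0] // 2, hw[1] // 2, 6)
    assert (out >= 0).all()


def test_wgrblock_matches_hand_composition_with_averaging_kernels(rng):
    blk = WGRBlock(1, 2, 2, rng)
    set_averaging(blk)
    x = np.ones((4, 4, 1))
    got = run_block(blk, x)

    s = BN_SCALE
    down = conv_ref(x, avg_weights(2, 1, 1, 1), stride=2) * s  # any 1x1 s2 branch
    s1 = down
    s2 = conv_ref(down, avg_weights(2, 2, 3, 3)) * s
    g = np.concatenate([
        down,
        conv_ref(maxpool_ref(x), avg_weights(2, 1, 1, 1)) * s,
        conv_ref(s1, avg_weights(2, 2, 1, 3)) * s,
        conv_ref(s1, avg_weights(2, 2, 3, 1)) * s,
        conv_ref(s2, avg_weights(2, 2, 1, 3)) * s,
        conv_ref(s2, avg_weights(2, 2, 3, 1)) * s,
    ], axis=-1)
    inner = conv_ref(g, avg_weights(2, 12, 3, 3)) * s
    want = np.maximum(conv_ref(inner, avg_weights(2, 2, 3, 3)) * s
                      + conv_ref(g, avg_weights(2, 12, 1, 1)) * s, 0.0)
    np.testing.assert_allclose(got, want, atol=1e-5)


# -- outlook attention --------------------------------------------------------

def outlook_uniform_ref(x, wv, k):
    """Loop oracle for outlook attention with uniform attention weights:
    K x K in-bounds window means of the projected values, scattered back
    over overlapping windows and normalized by the overlap count."""
    h, w, d = x.shape
    v = x.astype(np.float64) @ wv
    p = k // 2
    out = np.zeros_like(v)
    cnt = np.zeros((h, w, 1))
    for i in range(h):
        for j in range(w):
            win = v[max(0, i - p):i + p + 1, max(0, j - p):j + p + 1]
            m = win.sum(axis=(0, 1)) / (win.shape[0] * win.shape[1])
            for di in range(-p, p + 1):
                for dj in range(-p, p + 1):
                    q, r = i + di, j + dj
                    if 0 <= q < h and 0 <= r < w:
                        out[q, r] += m
                        cnt[q, r] += 1
    return out / cnt


def test_outlook_uniform_equals_neighborhood_average_oracle(rng):
    d, heads, k = 8, 2, 3
    att = OutlookAttention(d, heads, k, rng)
    att.attn.weight.data[...] = 0.0
    att.attn.bias.data[...] = 0.0       # uniform softmax
    att.proj.weight.data[...] = np.eye(d)
    att.proj.bias.data[...] = 0.0
    x = rng.normal(0, 1, (5, 6, d)).astype(np.float32)
    got = att(Tensor(x[None])).data[0]
    want = outlook_uniform_ref(x, att.v.weight.data.astype(np.float64), k)
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_outlook_constant_grid_maps_to_constant_grid(rng):
    d = 8
    att = OutlookAttention(d, 2, 3, rng)
    att.v.weight.data[...] = np.eye(d)
    att.proj.weight.data[...] = np.eye(d)
    att.proj.bias.data[...] = 0.0
    const = rng.normal(0, 1, d).astype(np.float32)
    x = np.broadcast_to(const, (4, 4, d)).copy()
    out = att(Tensor(x[None])).data[0]
    np.testing.assert_allclose(out, x, atol=1e-5)


def test_attention_rows_sum_to_one(rng):
    att = OutlookAttention(8, 2, 3, rng)
    w = att.attention_weights(Tensor(rng.normal(0, 1, (1, 4, 4, 8))))
    np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)
    sa = SelfAttention(8, 2, rng)
    w = sa.attention_weights(Tensor(rng.normal(0, 1, (1, 7, 8))))
    np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)


def test_outlook_rejects_indivisible_heads(rng):
    with pytest.raises(ValueError, match="divisible"):
        OutlookAttention(10, 4, 3, rng)
    with pytest.raises(ValueError, match="divisible"):
        SelfAttention(10, 4, rng)


# -- residual layers ----------------------------------------------------------

def _zero_residual_outputs(layer):
    attn = layer.mhoa if hasattr(layer, "mhoa") else layer.mhsa
    for lin in (attn.proj, layer.mlp.fc2):
        lin.weight.data[...] = 0.0
        lin.bias.data[...] = 0.0


@pytest.mark.parametrize("kind", ["outlooker", "transformer"])
def test_zeroed_residual_branches_give_exact_identity(rng, kind):
    if kind == "outlooker":
        layer = OutlookerLayer(8, 2, 3, 16, rng)
        x = rng.normal(0, 1, (1, 4, 4, 8)).astype(np.float32)
    else:
        layer = TransformerLayer(8, 2, 16, rng)
        x = rng.normal(0, 1, (1, 6, 8)).astype(np.float32)
    _zero_residual_outputs(layer)
    out = layer(Tensor(x))
    assert np.array_equal(out.data, x)


def test_outlooker_layer_equals_stepwise_composition(rng):
    layer = OutlookerLayer(8, 2, 3, 16, rng)
    x = Tensor(rng.normal(0, 1, (1, 4, 4, 8)).astype(np.float32))
    got = layer(x)
    h = layer.mhoa(layer.ln1(x)) + x
    want = layer.mlp(layer.ln2(h)) + h
    np.testing.assert_array_equal(got.data, want.data)


def test_transformer_two_token_hand_computation(rng):
    """D=2, one head, two tokens: the attention output must equal the
    hand-written scaled-dot-product formula."""
    sa = SelfAttention(2, 1, rng)
    wq, wk, wv = (np.array([[1.0, 0.0], [0.0, 1.0]]),
                  np.array([[0.0, 1.0], [1.0, 0.0]]),
                  np.array([[2.0, 0.0], [0.0, 0.5]]))
    for lin, w in ((sa.q, wq), (sa.k, wk), (sa.v, wv)):
        lin.weight.data[...] = w
        lin.bias.data[...] = 0.0
    sa.proj.weight.data[...] = np.eye(2)
    sa.proj.bias.data[...] = 0.0
    x = np.array([[0.5, -1.0], [1.5, 0.25]], dtype=np.float32)
    got = sa(Tensor(x[None])).data[0]

    q, k, v = x @ wq, x @ wk, x @ wv
    logits = q @ k.T / np.sqrt(2.0)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    attn = e / e.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(got, attn @ v, atol=1e-5)


# -- OTblock ------------------------------------------------------------------

def _small_ot(rng, outlook_depth=4, transformer_depth=12):
    return OTBlock(cin=6, grid=(4, 4), dim=8, heads=2, k=3,
                   outlook_depth=outlook_depth, transformer_depth=transformer_depth,
                   outlook_mlp_hidden=12, transformer_mlp_hidden=12,
                   patch_step=2, rng=rng)


def test_otblock_layer_depth_bookkeeping(rng):
    ot = _small_ot(rng)
    assert len(ot.outlookers) == 4
    assert len(ot.transformers) == 12


def test_otblock_preserves_spatial_shape(rng):
    ot = _small_ot(rng, 1, 2)
    x = rng.normal(0, 1, (2, 6, 4, 4)).astype(np.float32)
    assert ot(Tensor(x)).shape == (2, 6, 4, 4)


def test_otblock_rejects_indivisible_grid(rng):
    with pytest.raises(ValueError, match="patch step"):
        OTBlock(cin=6, grid=(3, 4), dim=8, heads=2, k=3, outlook_depth=1,
                transformer_depth=1, outlook_mlp_hidden=8,
                transformer_mlp_hidden=8, patch_step=2, rng=rng)


def test_otblock_projection_only_passthrough(rng):
    """Zeroing every residual-branch output and the positional embedding
    reduces the block to embed -> patch projection -> bilinear re-expansion
    -> output projection."""
    ot = _small_ot(rng, 1, 2)
    for layer in ot.outlookers + ot.transformers:
        _zero_residual_outputs(layer)
    ot.pos.data[...] = 0.0
    x = rng.normal(0, 1, (1, 6, 4, 4)).astype(np.float32)
    got = ot(Tensor(x)).data[0]

    from grotunet.nn.tensor import _bilinear_matrix
    tok = x[0].transpose(1, 2, 0) @ ot.embed.weight.data + ot.embed.bias.data
    s, d = 2, 8
    patches = tok.reshape(2, s, 2, s, d).transpose(0, 2, 1, 3, 4).reshape(4, s * s * d)
    g = patches @ ot.patch_proj.weight.data + ot.patch_proj.bias.data
    grid = g.reshape(2, 2, d)
    a = _bilinear_matrix(4, 2)
    upped = np.einsum("ph,hwd->pwd", a, grid)
    upped = np.einsum("qw,pwd->pqd", a, upped)
    want = (upped @ ot.out_proj.weight.data + ot.out_proj.bias.data).transpose(2, 0, 1)
    np.testing.assert_allclose(got, want.astype(np.float32), atol=1e-5)
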