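"""Network assembly: skips, decoder, variants, accounting, checkpoints."""

import numpy as np
import pytest

import grotunet.nn as nn
from grotunet.config import ModelConfig
from grotunet.model import (GrotUNet, MultiScaleDecoder, RSkip, build_variant,
                            count_flops, count_parameters, load_checkpoint,
                            save_checkpoint)
from grotunet.nn import Tensor

from conftest import tiny_config, zero_params


def fmap(rng, c, h, w, n=1):
    return Tensor(rng.normal(0, 1, (n, c, h, w)).astype(np.float32))


# -- R-Skip -------------------------------------------------------------------

def test_rskip_passes_deepest_level_through_bit_identical(rng):
    rs = RSkip(4, 6, 8, (5, 7), rng)
    f1, f2, f3 = fmap(rng, 4, 16, 16), fmap(rng, 6, 8, 8), fmap(rng, 8, 4, 4)
    s1, s2, s3 = rs(f1, f2, f3)
    assert s3 is f3
    assert s2.shape == (1, 7, 8, 8) and s1.shape == (1, 5, 16, 16)


def test_rskip_zero_convs_give_zero_skips(rng):
    rs = RSkip(4, 6, 8, (5, 7), rng)
    zero_params(rs)
    s1, s2, _ = rs(fmap(rng, 4, 16, 16), fmap(rng, 6, 8, 8), fmap(rng, 8, 4, 4))
    assert np.all(s1.data == 0) and np.all(s2.data == 0)


def test_rskip_prefusion_channel_arithmetic(rng):
    rs = RSkip(4, 6, 8, (5, 7), rng)
    assert rs.fuse2.conv.weight.shape[1] == 6 + 8
    assert rs.fuse1.conv.weight.shape[1] == 4 + 6 + 7


def test_rskip_rejects_broken_resolution_chain(rng):
    rs = RSkip(4, 6, 8, (5, 7), rng)
    with pytest.raises(ValueError, match="resolution chain"):
        rs(fmap(rng, 4, 16, 16), fmap(rng, 6, 8, 8), fmap(rng, 8, 3, 3))


# -- decoder ------------------------------------------------------------------

def _decoder(rng, use_mutiup=True):
    return MultiScaleDecoder(c4=8, skip_channels=(3, 4, 5), widths=(6, 6, 4, 4),
                             lateral=2, use_mutiup=use_mutiup, rng=rng)


def test_decoder_shape_chain_doubles_each_step(rng):
    dec = _decoder(rng)
    skips = (fmap(rng, 3, 128, 128), fmap(rng, 4, 64, 64), fmap(rng, 5, 32, 32))
    y4, y3, y2, y1, y0 = dec(fmap(rng, 8, 16, 16), skips)
    assert [t.shape[2] for t in (y4, y3, y2, y1, y0)] == [16, 32, 64, 128, 256]


def test_decoder_zero_weights_zero_output(rng):
    dec = _decoder(rng)
    zero_params(dec)
    skips = (fmap(rng, 3, 32, 32), fmap(rng, 4, 16, 16), fmap(rng, 5, 8, 8))
    *_, y0 = dec(fmap(rng, 8, 4, 4), skips)
    assert np.all(y0.data == 0)


def test_decoder_rejects_resolution_mismatch(rng):
    dec = _decoder(rng)
    skips = (fmap(rng, 3, 32, 32), fmap(rng, 4, 16, 16), fmap(rng, 5, 16, 16))
    with pytest.raises(ValueError, match="mismatch"):
        dec(fmap(rng, 8, 4, 4), skips)


def test_decoder_with_zero_skips_equals_backbone_chain(rng):
    """Zeroing the skip inputs must reduce each fusion conv to the plain
    upsample-and-convolve chain restricted to its backbone channels."""
    dec = _decoder(rng)
    dec.eval()
    y4 = fmap(rng, 8, 4, 4)
    zskips = (fmap(rng, 3, 32, 32) * 0.0, fmap(rng, 4, 16, 16) * 0.0,
              fmap(rng, 5, 8, 8) * 0.0)
    *_, y0 = dec(y4, zskips)

    def convbn(mod, x, keep):
        w = mod.conv.weight.data[:, :keep]
        y = nn.conv2d(x, Tensor(w), None, (1, 1), mod.conv.padding)
        y = (y - Tensor(mod.bn.running_mean.data.reshape(1, -1, 1, 1))) \
            * Tensor((mod.bn.running_var.data.reshape(1, -1, 1, 1) + mod.bn.eps) ** -0.5)
        y = y * Tensor(mod.bn.gamma.data.reshape(1, -1, 1, 1)) \
            + Tensor(mod.bn.beta.data.reshape(1, -1, 1, 1))
        return nn.relu(y)

    up = nn.upsample_bilinear
    y3 = convbn(dec.conv3, up(y4, 2), 8)
    lat2 = dec.lat4_2(y4)
    y2 = convbn(dec.conv2, nn.concat([up(y3, 2), up(lat2, 4)], axis=1), 6 + 2)
    y1 = convbn(dec.conv1, nn.concat(
        [up(y2, 2), up(dec.lat3_1(y3), 4), up(dec.lat4_1(y4), 8)], axis=1), 6 + 4)
    want = convbn(dec.conv0, up(y1, 2), 4)
    np.testing.assert_allclose(y0.data, want.data, atol=1e-5)


def test_bilinear_upx2_matches_closed_form():
    """Half-pixel-center bilinear x2 of [[0,1],[2,3]] computed from the
    interpolation formula directly."""
    x = np.array([[0.0, 1.0], [2.0, 3.0]], dtype=np.float32)
    got = nn.upsample_bilinear(Tensor(x[None, None]), 2).data[0, 0]

    def interp1(vals, i):
        src = np.clip((i + 0.5) / 2 - 0.5, 0, len(vals) - 1)
        lo = int(np.floor(src))
        hi = min(lo + 1, len(vals) - 1)
        t = src - lo
        return vals[lo] * (1 - t) + vals[hi] * t

    want = np.empty((4, 4))
    for i in range(4):
        rows = [interp1(x[:, j], i) for j in range(2)]
        for j in range(4):
            want[i, j] = interp1(np.array(rows), j)
    np.testing.assert_allclose(got, want, atol=1e-6)


# -- full model ---------------------------------------------------------------

@pytest.mark.parametrize("size", [256, 128])
def test_forward_output_matches_input_resolution(rng, size):
    cfg = tiny_config(input_size=(size, size))
    model = GrotUNet(cfg, rng=np.random.default_rng(0)).eval()
    out = model(fmap(rng, 3, size, size))
    assert out.shape == (1, cfg.embedding_dim, size, size)


def test_forward_rejects_indivisible_input(rng):
    cfg = tiny_config()
    model = GrotUNet(cfg, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="divisible by 32"):
        model(fmap(rng, 3, 48, 48))


def test_inference_is_deterministic(rng):
    model = GrotUNet(tiny_config(), rng=np.random.default_rng(0)).eval()
    x = fmap(rng, 3, 32, 32)
    with nn.no_grad():
        a = model(x).data
        b = model(x).data
    assert np.array_equal(a, b)


def test_gradient_reaches_every_parameter(rng):
    # 64x64 input so the transformer sees >1 token (with a single token the
    # softmax is constant and q/k correctly receive zero gradient)
    model = GrotUNet(tiny_config(input_size=(64, 64)), rng=np.random.default_rng(0))
    out = model(fmap(rng, 3, 64, 64, n=2))
    (out ** 2.0).sum().backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.abs(p.grad).sum() > 0]
    assert dead == []


# -- variants and accounting --------------------------------------------------

def test_build_variant_flag_table():
    assert build_variant("V").use_otblock and build_variant("V").use_rskip \
        and build_variant("V").use_mutiup
    i = build_variant("I")
    assert (i.use_otblock, i.use_rskip, i.use_mutiup) == (False, True, True)
    ii = build_variant("II")
    assert (ii.use_otblock, ii.use_rskip, ii.use_mutiup) == (True, False, False)
    iii = build_variant("III")
    assert (iii.use_otblock, iii.use_rskip, iii.use_mutiup) == (True, True, False)
    iv = build_variant("IV")
    assert (iv.use_otblock, iv.use_rskip, iv.use_mutiup) == (True, False, True)
    with pytest.raises(ValueError, match="unknown configuration"):
        build_variant("VI")


def test_single_conv_parameter_closed_form(rng):
    conv = nn.Conv2d(4, 8, 3, bias=True, rng=rng)
    assert sum(p.size for p in [conv.weight, conv.bias]) == 3 * 3 * 4 * 8 + 8


def test_ablation_never_increases_parameter_count():
    base = tiny_config()
    full = count_parameters(build_variant("V", base))
    for cid in ("I", "II", "III", "IV"):
        assert count_parameters(build_variant(cid, base)) <= full


def test_flop_accounting_closed_forms():
    # 1x1 conv contributes H*W*Cin*Cout MACs; doubling H and W quadruples
    # every convolutional term
    cfg = tiny_config(use_otblock=False)
    base = count_flops(cfg, (32, 32))
    assert count_flops(cfg, (64, 64)) == pytest.approx(4 * base, rel=1e-6)
    with_head = count_flops(cfg, (32, 32))
    bigger_head = count_flops(tiny_config(use_otblock=False, embedding_dim=8), (32, 32))
    assert bigger_head - with_head == 32 * 32 * cfg.decoder_widths[3] * 4


# -- checkpoints --------------------------------------------------------------

def test_checkpoint_round_trip_is_exact(rng, tmp_path):
    model = GrotUNet(tiny_config(), rng=np.random.default_rng(3)).eval()
    x = fmap(rng, 3, 32, 32)
    with nn.no_grad():
        before = model(x).data
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path).eval()
    for (na, pa), (nb, pb) in zip(sorted(model.named_parameters()),
                                  sorted(restored.named_parameters())):
        assert na == nb and np.array_equal(pa.data, pb.data)
    with nn.no_grad():
        after = restored(x).data
    assert np.array_equal(before, after)
    assert restored.cfg == model.cfg


def test_checkpoint_config_mismatch_rejected(rng, tmp_path):
    model = GrotUNet(build_variant("I", tiny_config()), rng=np.random.default_rng(3))
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    with pytest.raises(ValueError, match="does not match"):
        load_checkpoint(path, expect_cfg=build_variant("V", tiny_config()))
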