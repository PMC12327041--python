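"""Full network assembly: encoder stack, reconstructed skip connections,
multi-scale upsampling-fusion decoder, embedding head, ablation variants,
parameter/MAC accounting and checkpoint I/O.

The network maps an RGB image to a per-pixel embedding map at the same
resolution.  Instances are later recovered from the embeddings by
clustering (see :mod:`grotunet.cluster`).

Ablation variants (flag combinations of :class:`~grotunet.config.ModelConfig`):

====  ========  =======  ========
id    OTblock   R-Skip   Muti-UP
====  ========  =======  ========
I     off       on       on
II    on        off      off
III   on        on       off
IV    on        off      on
V     on        on       on
====  ========  =======  ========
"""

from __future__ import annotations

import json

import numpy as np

from . import nn
from .blocks import GRBlock, OTBlock, WGRBlock
from .config import ModelConfig
from .nn import Tensor

CHECKPOINT_VERSION = 1

VARIANTS = {
    "I": dict(use_otblock=False, use_rskip=True, use_mutiup=True),
    "II": dict(use_otblock=True, use_rskip=False, use_mutiup=False),
    "III": dict(use_otblock=True, use_rskip=True, use_mutiup=False),
    "IV": dict(use_otblock=True, use_rskip=False, use_mutiup=True),
    "V": dict(use_otblock=True, use_rskip=True, use_mutiup=True),
}


def build_variant(config_id: str, base: ModelConfig | None = None) -> ModelConfig:
    """Return a copy of `base` with the ablation flags of the named variant."""
    if config_id not in VARIANTS:
        raise ValueError(f"unknown configuration {config_id!r}; expected one of {list(VARIANTS)}")
    base = base or ModelConfig()
    d = base.to_dict()
    d.update(VARIANTS[config_id])
    return ModelConfig.from_dict(d)


def _check_chain(maps, what: str) -> None:
    for a, b in zip(maps[:-1], maps[1:]):
        if a.shape[2] != 2 * b.shape[2] or a.shape[3] != 2 * b.shape[3]:
            raise ValueError(
                f"{what}: broken resolution chain {a.shape} vs {b.shape} "
                "(each level must be exactly 2x the next)")


class RSkip(nn.Module):
    """Reconstructed skip connections.

    S3 passes the deepest skip through unchanged; S2 and S1 aggregate the
    current stage with bilinearly upsampled higher-level maps through a
    single 1x1 convolution each (cross-channel fusion, no spatial mixing).
    """

    def __init__(self, c1: int, c2: int, c3: int, widths: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        s1w, s2w = widths
        self.fuse2 = nn.ConvBN(c2 + c3, s2w, 1, rng=rng)
        self.fuse1 = nn.ConvBN(c1 + c2 + s2w, s1w, 1, rng=rng)

    def forward(self, f1: Tensor, f2: Tensor, f3: Tensor):
        _check_chain([f1, f2, f3], "rskip")
        s3 = f3
        s2 = self.fuse2(nn.concat([f2, nn.upsample_bilinear(s3, 2)], axis=1))
        s1 = self.fuse1(nn.concat([
            f1, nn.upsample_bilinear(f2, 2), nn.upsample_bilinear(s2, 2)], axis=1))
        return s1, s2, s3


class MultiScaleDecoder(nn.Module):
    """Decoder with optional multi-scale upsampling fusion.

    With fusion on, the two deepest decoder states are reduced by 1x1
    convolutions and re-injected (bilinearly upsampled x4/x8) into every
    shallower decoding step alongside the skip of matching resolution.
    """

    def __init__(self, c4: int, skip_channels: tuple[int, int, int],
                 widths: tuple[int, int, int, int], lateral: int,
                 use_mutiup: bool, rng: np.random.Generator):
        super().__init__()
        s1c, s2c, s3c = skip_channels
        d3, d2, d1, d0 = widths
        self.use_mutiup = use_mutiup
        self.conv3 = nn.ConvBN(c4 + s3c, d3, 3, relu=True, rng=rng)
        if use_mutiup:
            self.lat4_2 = nn.ConvBN(c4, lateral, 1, rng=rng)
            self.lat4_1 = nn.ConvBN(c4, lateral, 1, rng=rng)
            self.lat3_1 = nn.ConvBN(d3, lateral, 1, rng=rng)
            self.conv2 = nn.ConvBN(d3 + lateral + s2c, d2, 3, relu=True, rng=rng)
            self.conv1 = nn.ConvBN(d2 + 2 * lateral + s1c, d1, 3, relu=True, rng=rng)
        else:
            self.conv2 = nn.ConvBN(d3 + s2c, d2, 3, relu=True, rng=rng)
            self.conv1 = nn.ConvBN(d2 + s1c, d1, 3, relu=True, rng=rng)
        self.conv0 = nn.ConvBN(d1, d0, 3, relu=True, rng=rng)

    def forward(self, y4: Tensor, skips):
        s1, s2, s3 = skips
        if y4.shape[2] * 2 != s3.shape[2] or y4.shape[3] * 2 != s3.shape[3]:
            raise ValueError(f"decoder/skip resolution mismatch: y4 {y4.shape} vs S3 {s3.shape}")
        up = nn.upsample_bilinear
        y3 = self.conv3(nn.concat([up(y4, 2), s3], axis=1))
        if self.use_mutiup:
            y2 = self.conv2(nn.concat([up(y3, 2), up(self.lat4_2(y4), 4), s2], axis=1))
            y1 = self.conv1(nn.concat([
                up(y2, 2), up(self.lat3_1(y3), 4), up(self.lat4_1(y4), 8), s1], axis=1))
        else:
            y2 = self.conv2(nn.concat([up(y3, 2), s2], axis=1))
            y1 = self.conv1(nn.concat([up(y2, 2), s1], axis=1))
        y0 = self.conv0(up(y1, 2))
        return y4, y3, y2, y1, y0


class GrotUNet(nn.Module):
    """Encoder-decoder network emitting per-pixel instance embeddings.

    Encoder: one shallow GR stage then three WGR stages (each halves the
    resolution), with optional outlooker/transformer refinement of the top
    stage.  Decoder: reconstructed skips + multi-scale upsampling fusion
    (both optional per the ablation flags).  Head: a single 1x1 convolution
    to ``embedding_dim`` channels, no activation.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.stage_widths
        self.stage1 = GRBlock(cfg.in_channels, c1, cfg.gr_branch_width, rng)
        self.stage2 = WGRBlock(c1, c2, cfg.wgr_branch_widths[0], rng)
        self.stage3 = WGRBlock(c2, c3, cfg.wgr_branch_widths[1], rng)
        self.stage4 = WGRBlock(c3, c4, cfg.wgr_branch_widths[2], rng)
        h, w = cfg.input_size
        if cfg.use_otblock:
            self.ot = OTBlock(
                c4, (h // 16, w // 16), cfg.token_dim, cfg.heads,
                cfg.outlook_kernel, cfg.outlook_depth, cfg.transformer_depth,
                cfg.outlook_mlp_hidden, cfg.transformer_mlp_hidden,
                cfg.patch_step, rng)
        else:
            self.ot = None
        if cfg.use_rskip:
            self.rskip = RSkip(c1, c2, c3, cfg.skip_widths, rng)
            skip_channels = (cfg.skip_widths[0], cfg.skip_widths[1], c3)
        else:
            self.rskip = None
            skip_channels = (c1, c2, c3)
        widths = cfg.decoder_widths if (cfg.use_rskip or cfg.use_mutiup) \
            else cfg.plain_decoder_widths
        self.decoder = MultiScaleDecoder(c4, skip_channels, widths,
                                         cfg.lateral_width, cfg.use_mutiup, rng)
        self.head = nn.Conv2d(widths[3], cfg.embedding_dim, 1, bias=True, rng=rng)

    def _check_input(self, x: Tensor) -> None:
        n, c, h, w = x.shape
        div = self.cfg.divisor
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims must be divisible by {div}, got {h}x{w}")
        if (h, w) != self.cfg.input_size and self.ot is not None:
            raise ValueError(
                f"model was built for input size {self.cfg.input_size}, got {(h, w)} "
                "(the positional embedding is size-bound)")

    def forward(self, x: Tensor) -> Tensor:
        self._check_input(x)
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        y4 = self.ot(f4) if self.ot is not None else f4
        skips = self.rskip(f1, f2, f3) if self.rskip is not None else (f1, f2, f3)
        _, _, _, _, y0 = self.decoder(y4, skips)
        return self.head(y0)

    def embed_image(self, image: np.ndarray) -> np.ndarray:
        """Inference convenience: [H,W,3] float image -> [H,W,E] embedding."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                x = Tensor(np.asarray(image, dtype=np.float32).transpose(2, 0, 1)[None])
                emb = self.forward(x)
        finally:
            self.train(was_training)
        return emb.data[0].transpose(1, 2, 0)


def count_parameters(cfg: ModelConfig) -> int:
    """Number of trainable scalars of the assembled model (convs, norms,
    attention projections, positional embedding, MLPs, head)."""
    return GrotUNet(cfg).num_parameters()


def count_flops(cfg: ModelConfig, input_shape: tuple[int, int] | None = None) -> float:
    """Multiply-accumulate count of one forward pass, in MACs.

    Convention: one MAC per scalar multiply-add in convolutions, linear
    projections and attention matrix products; normalization layers,
    activations, pooling and bilinear resampling are not counted.
    """
    h, w = input_shape or cfg.input_size
    c1, c2, c3, c4 = cfg.stage_widths
    total = 0.0

    def conv(kh, kw, cin, cout, ho, wo):
        return kh * kw * cin * cout * ho * wo

    # encoder stage 1 (GR)
    b = cfg.gr_branch_width
    h1, w1 = h // 2, w // 2
    total += conv(3, 3, cfg.in_channels, b, h1, w1)
    total += 2 * (conv(1, 1, cfg.in_channels, b, h1, w1))
    total += conv(1, 3, b, b, h1, w1) + conv(3, 1, b, b, h1, w1)
    hch = 3 * b
    total += conv(3, 3, hch, c1, h1, w1) + conv(1, 1, hch, c1, h1, w1)
    total += conv(3, 3, c1, c1, h1, w1) + conv(1, 1, hch, c1, h1, w1)
    # WGR stages
    hs, ws, cin = h1, w1, c1
    for cout, b in zip((c2, c3, c4), cfg.wgr_branch_widths):
        ho, wo = hs // 2, ws // 2
        total += 3 * conv(1, 1, cin, b, ho, wo)      # three stride-2 1x1 branches
        total += conv(1, 1, cin, b, ho, wo)          # 1x1 after max pool
        total += conv(3, 3, b, b, ho, wo)            # s2 conv
        total += 2 * (conv(1, 3, b, b, ho, wo) + conv(3, 1, b, b, ho, wo))
        g = 6 * b
        total += conv(3, 3, g, cout, ho, wo) + conv(3, 3, cout, cout, ho, wo)
        total += conv(1, 1, g, cout, ho, wo)
        hs, ws, cin = ho, wo, cout
    # OT block
    if cfg.use_otblock:
        gh, gw = h // 16, w // 16
        n_grid = gh * gw
        d, heads, k = cfg.token_dim, cfg.heads, cfg.outlook_kernel
        total += n_grid * c4 * d  # embed
        k4 = k**4
        for _ in range(cfg.outlook_depth):
            total += n_grid * d * d                    # v
            total += n_grid * d * heads * k4           # attention logits
            total += n_grid * k4 * d                   # attn @ v
            total += n_grid * d * d                    # proj
            total += 2 * n_grid * d * cfg.outlook_mlp_hidden
        s = cfg.patch_step
        t = n_grid // (s * s)
        total += t * (s * s * d) * d                   # patch projection
        for _ in range(cfg.transformer_depth):
            total += 4 * t * d * d                     # q,k,v,proj
            total += 2 * t * t * d                     # logits + weighted sum
            total += 2 * t * d * cfg.transformer_mlp_hidden
        total += n_grid * d * c4                       # out projection
    # skips
    h3, w3 = h // 8, w // 8
    h2, w2 = h // 4, w // 4
    if cfg.use_rskip:
        s1w, s2w = cfg.skip_widths
        total += conv(1, 1, c2 + c3, s2w, h3, w3)
        total += conv(1, 1, c1 + c2 + s2w, s1w, h2, w2)
        s1c, s2c = s1w, s2w
    else:
        s1c, s2c = c1, c2
    # decoder
    d3, d2, d1, d0 = cfg.decoder_widths if (cfg.use_rskip or cfg.use_mutiup) \
        else cfg.plain_decoder_widths
    lat = cfg.lateral_width
    total += conv(3, 3, c4 + c3, d3, h3, w3)
    if cfg.use_mutiup:
        h4, w4 = h // 16, w // 16
        total += 2 * conv(1, 1, c4, lat, h4, w4) + conv(1, 1, d3, lat, h3, w3)
        total += conv(3, 3, d3 + lat + s2c, d2, h2, w2)
        total += conv(3, 3, d2 + 2 * lat + s1c, d1, h1, w1)
    else:
        total += conv(3, 3, d3 + s2c, d2, h2, w2)
        total += conv(3, 3, d2 + s1c, d1, h1, w1)
    total += conv(3, 3, d1, d0, h, w)
    total += conv(1, 1, d0, cfg.embedding_dim, h, w)  # head
    return float(total)


def save_checkpoint(model: GrotUNet, path) -> None:
    """Serialize parameters, buffers and the ModelConfig to an npz archive."""
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": model.cfg.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path, expect_cfg: ModelConfig | None = None) -> GrotUNet:
    """Rebuild a model from an archive written by :func:`save_checkpoint`.

    If `expect_cfg` is given, the stored configuration must match exactly.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = ModelConfig.from_dict(meta["config"])
        if expect_cfg is not None and cfg != expect_cfg:
            raise ValueError("checkpoint configuration does not match the requested model")
        model = GrotUNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
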