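"""Configuration records for the model, loss, clustering and training.

The default ``ModelConfig`` is the frozen reference channel plan.  The
architecture's publication reports only total parameter budgets, not channel
widths, so the plan below was calibrated once against those budgets
(104.45 M for the full model, 19.14 M without the attention block, 103.87 M
with plain skips/decoder) and is treated as fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    ``stage_widths`` are the encoder stage output channels C1..C4 (the input
    image is halved once per stage, so C4 lives at 1/16 resolution).
    ``use_otblock`` / ``use_rskip`` / ``use_mutiup`` are the ablation flags:
    all three on is the full model (configuration V).
    """

    input_size: tuple[int, int] = (256, 256)
    in_channels: int = 3
    embedding_dim: int = 8
    # encoder
    stage_widths: tuple[int, int, int, int] = (64, 160, 320, 640)
    gr_branch_width: int = 32
    wgr_branch_widths: tuple[int, int, int] = (40, 80, 182)
    # attention refinement (applied to the stage-4 output)
    token_dim: int = 728
    heads: int = 8
    outlook_kernel: int = 3
    outlook_depth: int = 4
    transformer_depth: int = 12
    outlook_mlp_hidden: int = 2187
    transformer_mlp_hidden: int = 2162
    patch_step: int = 2
    # skips / decoder
    skip_widths: tuple[int, int] = (82, 160)       # S1, S2 output channels
    decoder_widths: tuple[int, int, int, int] = (320, 160, 80, 40)  # D3..D0
    lateral_width: int = 76                        # 1x1 reductions feeding Muti-UP
    plain_decoder_widths: tuple[int, int, int, int] = (308, 160, 81, 40)
    # ablation flags
    use_otblock: bool = True
    use_rskip: bool = True
    use_mutiup: bool = True

    def __post_init__(self):
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.token_dim % self.heads:
            raise ValueError("token_dim must be divisible by heads")
        if self.outlook_kernel % 2 == 0:
            raise ValueError("outlook kernel size must be odd")
        if any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")

    @property
    def divisor(self) -> int:
        """Input spatial sizes must be divisible by this."""
        return 16 * self.patch_step

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("input_size", "stage_widths", "wgr_branch_widths",
                    "skip_widths", "decoder_widths", "plain_decoder_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def reduced_config(scale: int = 4, input_size: tuple[int, int] = (64, 64),
                   outlook_depth: int = 1, transformer_depth: int = 2) -> ModelConfig:
    """A desk-scale variant: widths divided by `scale`, shallow attention."""
    base = ModelConfig()
    td = max(16, base.token_dim // scale)
    heads = 4
    td -= td % heads
    return ModelConfig(
        input_size=input_size,
        stage_widths=tuple(max(8, w // scale) for w in base.stage_widths),
        gr_branch_width=max(4, base.gr_branch_width // scale),
        wgr_branch_widths=tuple(max(4, w // scale) for w in base.wgr_branch_widths),
        token_dim=td,
        heads=heads,
        outlook_depth=outlook_depth,
        transformer_depth=transformer_depth,
        outlook_mlp_hidden=max(16, base.outlook_mlp_hidden // scale),
        transformer_mlp_hidden=max(16, base.transformer_mlp_hidden // scale),
        skip_widths=tuple(max(4, w // scale) for w in base.skip_widths),
        decoder_widths=tuple(max(4, w // scale) for w in base.decoder_widths),
        lateral_width=max(4, base.lateral_width // scale),
        plain_decoder_widths=tuple(max(4, w // scale) for w in base.plain_decoder_widths),
    )


@dataclass
class LossConfig:
    """Margins and weights of the discriminative embedding loss.

    ``delta_v`` is the pull margin (pixels within this distance of their
    instance mean contribute nothing), ``delta_d`` the push margin (means
    further than 2*delta_d apart contribute nothing).
    """

    delta_v: float = 0.5
    delta_d: float = 1.5
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.001
    norm: str = "l2"  # 'l1' or 'l2'
    background_as_instance: bool = True

    def __post_init__(self):
        if self.delta_v <= 0 or self.delta_d <= 0:
            raise ValueError("margins must be positive")
        if self.norm not in ("l1", "l2"):
            raise ValueError("norm must be 'l1' or 'l2'")


@dataclass
class ClusterConfig:
    """Mean-shift decoding of embedding maps into instance labels."""

    bandwidth: float = 0.5            # = delta_v by default
    assign_radius: float = 1.0        # = 2 * delta_v
    merge_radius: float = 2.0         # = delta_v + delta_d. Fragment modes of
                                      # one instance lie within ~2*delta_v of
                                      # each other while distinct instance
                                      # modes are >= 2*delta_d - delta_v apart,
                                      # so any threshold in (1.0, 2.5) separates
                                      # the two cases; the default is mid-band.
    min_instance_pixels: int = 16
    background_rule: str = "border_majority"  # or 'largest_cluster'
    seed_stride: int = 4              # mean-shift seeds on every k-th pixel
    fit_stride: int = 2               # mean-shift density from every k-th pixel

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.assign_radius < self.bandwidth:
            raise ValueError("assign_radius must be >= bandwidth")
        if self.min_instance_pixels < 1:
            raise ValueError("min_instance_pixels must be >= 1")
        if self.background_rule not in ("border_majority", "largest_cluster"):
            raise ValueError("unknown background_rule")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published setup)."""

    lr: float = 1e-3
    weight_decay: float = 0.05
    lr_decay_factor: float = 0.1
    lr_patience: int = 10
    batch_size: int = 16
    epochs: int = 200
    val_fraction: float = 0.15
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    augment: bool = True
    crop_size: tuple[int, int] | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
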