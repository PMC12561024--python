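"""UNeXt-style tokenized-MLP encoder-decoder for thin-curve segmentation.

The network is a convolutional encoder (three conv-BN-ReLU-maxpool stages,
1 -> 16 -> 32 -> 128 channels), two overlapping patch embeddings (stride-2
3x3 convolutions to 160 and 256 channels) each followed by a shifted-MLP
token block, and a convolutional decoder with bilinear 2x upsampling and
additive skip connections (256 -> 160 -> 128 -> 32 -> 16 -> 16), closed by
a 1x1 convolution producing a single logit map at input resolution.

The shifted-MLP block mixes tokens without attention: channels are split
into five groups that are spatially translated by -2..+2 pixels before a
per-pixel linear layer; a depthwise 3x3 convolution and GELU sit between
the two linear layers, with a channel LayerNorm and a residual connection
around the whole block.  Axis of the shift alternates (rows before fc1,
columns before fc2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor, add, relu


@dataclass(frozen=True)
class UNeXtConfig:
    in_channels: int = 1
    conv_channels: tuple[int, int, int] = (16, 32, 128)
    embed_dims: tuple[int, int] = (160, 256)
    conv_kernel: int = 3
    mlp_hidden_ratio: float = 1.0
    out_channels: int = 1
    input_size: tuple[int, int] = (192, 192)

    def __post_init__(self):
        if len(self.conv_channels) != 3:
            raise ValueError("conv_channels must have 3 entries")
        if len(self.embed_dims) != 2:
            raise ValueError("embed_dims must have 2 entries")
        if any(d <= 0 for d in (*self.conv_channels, *self.embed_dims,
                                self.in_channels, self.out_channels)):
            raise ValueError("all channel dims must be positive")


@dataclass
class LayerBudget:
    """Per-layer parameter counts for the enumerated named layers."""

    rows: list[tuple[str, str, int]] = field(default_factory=list)
    model_total: int = 0

    @property
    def enumerated_total(self) -> int:
        return sum(r[2] for r in self.rows)

    def as_dict(self) -> dict[str, int]:
        return {name: count for name, _, count in self.rows}

    def format_table(self) -> str:
        lines = [f"{'Layer':<22}{'Type':<16}{'Number of Parameters':>22}"]
        for name, kind, count in self.rows:
            lines.append(f"{name:<22}{kind:<16}{count:>22,}")
        lines.append(f"{'':<38}Total: {self.enumerated_total:,} parameters")
        lines.append(f"{'':<38}(full model incl. norms/depthwise: "
                     f"{self.model_total:,})")
        return "\n".join(lines)


class EncoderStage(nn.Module):
    def __init__(self, cin, cout, k, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, rng, stride=1, padding=k // 2)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x):
        return relu(F.maxpool2x2(self.bn(self.conv(x))))


class ShiftedMLPBlock(nn.Module):
    """Residual tokenized-MLP block with axial spatial shifts."""

    def __init__(self, dim, rng, hidden_ratio=1.0):
        super().__init__()
        hidden = int(round(dim * hidden_ratio))
        self.norm = nn.LayerNormChannels(dim)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.dwconv = nn.DWConv3x3(hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def __call__(self, x):
        h = self.norm(x)
        h = F.group_spatial_shift(h, axis=2)
        h = self.fc1(h)
        h = F.gelu(self.dwconv(h))
        h = F.group_spatial_shift(h, axis=3)
        h = self.fc2(h)
        return add(x, h)


class UNeXt(nn.Module):
    def __init__(self, cfg: UNeXtConfig, rng):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3 = cfg.conv_channels
        d1, d2 = cfg.embed_dims
        k = cfg.conv_kernel
        self.encoder1 = EncoderStage(cfg.in_channels, c1, k, rng)
        self.encoder2 = EncoderStage(c1, c2, k, rng)
        self.encoder3 = EncoderStage(c2, c3, k, rng)
        self.patch_embed3 = nn.Conv2d(c3, d1, k, rng, stride=2, padding=k // 2)
        self.pe_norm3 = nn.LayerNormChannels(d1)
        self.block1 = ShiftedMLPBlock(d1, rng, cfg.mlp_hidden_ratio)
        self.stage_norm3 = nn.LayerNormChannels(d1)
        self.patch_embed4 = nn.Conv2d(d1, d2, k, rng, stride=2, padding=k // 2)
        self.pe_norm4 = nn.LayerNormChannels(d2)
        self.block2 = ShiftedMLPBlock(d2, rng, cfg.mlp_hidden_ratio)
        self.stage_norm4 = nn.LayerNormChannels(d2)
        self.decoder1 = nn.Conv2d(d2, d1, k, rng, padding=k // 2)
        self.dbn1 = nn.BatchNorm2d(d1)
        self.decoder2 = nn.Conv2d(d1, c3, k, rng, padding=k // 2)
        self.dbn2 = nn.BatchNorm2d(c3)
        self.decoder3 = nn.Conv2d(c3, c2, k, rng, padding=k // 2)
        self.dbn3 = nn.BatchNorm2d(c2)
        self.decoder4 = nn.Conv2d(c2, c1, k, rng, padding=k // 2)
        self.dbn4 = nn.BatchNorm2d(c1)
        self.decoder5 = nn.Conv2d(c1, c1, k, rng, padding=k // 2)
        self.final = nn.Conv2d(c1, cfg.out_channels, 1, rng, padding=0)

    def __call__(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial dims must be /32-divisible, got {h}x{w}")
        t1 = self.encoder1(x)                       # c1 @ /2
        t2 = self.encoder2(t1)                      # c2 @ /4
        t3 = self.encoder3(t2)                      # c3 @ /8
        x4 = self.pe_norm3(self.patch_embed3(t3))   # d1 @ /16
        t4 = self.stage_norm3(self.block1(x4))
        x5 = self.pe_norm4(self.patch_embed4(t4))   # d2 @ /32
        x5 = self.stage_norm4(self.block2(x5))
        d = add(relu(F.upsample2x_bilinear(self.dbn1(self.decoder1(x5)))), t4)
        d = add(relu(F.upsample2x_bilinear(self.dbn2(self.decoder2(d)))), t3)
        d = add(relu(F.upsample2x_bilinear(self.dbn3(self.decoder3(d)))), t2)
        d = add(relu(F.upsample2x_bilinear(self.dbn4(self.decoder4(d)))), t1)
        d = relu(F.upsample2x_bilinear(self.decoder5(d)))
        return self.final(d)                        # logits, out_channels @ /1

    def predict_proba(self, x):
        """Sigmoid probability map, no graph recorded."""
        with nn.no_grad():
            was_training = self.training
            self.eval()
            out = F._sigmoid_np(self(x).data)
            self.train(was_training)
        return out


def build_model(cfg: UNeXtConfig | None = None, seed: int = 0) -> UNeXt:
    cfg = cfg or UNeXtConfig()
    rng = np.random.default_rng(seed)
    return UNeXt(cfg, rng)


def _count(*tensors) -> int:
    return sum(int(t.data.size) for t in tensors)


def parameter_budget(model: UNeXt) -> LayerBudget:
    """Parameter counts for the enumerated named layers of the architecture.

    The enumeration covers the convolutional, batch-norm and token-fc layers
    of the published layout; LayerNorms and the depthwise convolutions inside
    the token blocks (and the decoder batch-norms) exist in the model but are
    reported only through ``model_total``.
    """
    m = model
    rows = [
        ("Encoder1_Conv2D", "Conv2d", _count(m.encoder1.conv.weight, m.encoder1.conv.bias)),
        ("Encoder1_BatchNorm", "BatchNorm2d", _count(m.encoder1.bn.gamma, m.encoder1.bn.beta)),
        ("Encoder2_Conv2D", "Conv2d", _count(m.encoder2.conv.weight, m.encoder2.conv.bias)),
        ("Encoder2_BatchNorm", "BatchNorm2d", _count(m.encoder2.bn.gamma, m.encoder2.bn.beta)),
        ("Encoder3_Conv2D", "Conv2d", _count(m.encoder3.conv.weight, m.encoder3.conv.bias)),
        ("Encoder3_BatchNorm", "BatchNorm2d", _count(m.encoder3.bn.gamma, m.encoder3.bn.beta)),
        ("PatchEmbed3_Conv2D", "Conv2d", _count(m.patch_embed3.weight, m.patch_embed3.bias)),
        ("PatchEmbed4_Conv2D", "Conv2d", _count(m.patch_embed4.weight, m.patch_embed4.bias)),
        ("ShiftMLP1_fc1", "Linear", _count(m.block1.fc1.weight, m.block1.fc1.bias)),
        ("ShiftMLP1_fc2", "Linear", _count(m.block1.fc2.weight, m.block1.fc2.bias)),
        ("ShiftMLP2_fc1", "Linear", _count(m.block2.fc1.weight, m.block2.fc1.bias)),
        ("ShiftMLP2_fc2", "Linear", _count(m.block2.fc2.weight, m.block2.fc2.bias)),
        ("Decoder1_Conv2D", "Conv2d", _count(m.decoder1.weight, m.decoder1.bias)),
        ("Decoder2_Conv2D", "Conv2d", _count(m.decoder2.weight, m.decoder2.bias)),
        ("Decoder3_Conv2D", "Conv2d", _count(m.decoder3.weight, m.decoder3.bias)),
        ("Decoder4_Conv2D", "Conv2d", _count(m.decoder4.weight, m.decoder4.bias)),
        ("Decoder5_Conv2D", "Conv2d", _count(m.decoder5.weight, m.decoder5.bias)),
        ("Final_1x1_Conv", "Conv2d (1x1)", _count(m.final.weight, m.final.bias)),
    ]
    return LayerBudget(rows=rows, model_total=model.num_parameters())


def save_checkpoint(path, model: UNeXt):
    """Single-file checkpoint with the architecture config embedded."""
    import json
    state = model.state_dict()
    cfg = model.cfg
    meta = json.dumps({
        "in_channels": cfg.in_channels,
        "conv_channels": list(cfg.conv_channels),
        "embed_dims": list(cfg.embed_dims),
        "conv_kernel": cfg.conv_kernel,
        "mlp_hidden_ratio": cfg.mlp_hidden_ratio,
        "out_channels": cfg.out_channels,
        "input_size": list(cfg.input_size),
    })
    np.savez(path, __config__=np.array(meta), **state)


def load_checkpoint(path) -> UNeXt:
    import json
    with np.load(path) as data:
        meta = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg = UNeXtConfig(
        in_channels=meta["in_channels"],
        conv_channels=tuple(meta["conv_channels"]),
        embed_dims=tuple(meta["embed_dims"]),
        conv_kernel=meta["conv_kernel"],
        mlp_hidden_ratio=meta["mlp_hidden_ratio"],
        out_channels=meta["out_channels"],
        input_size=tuple(meta["input_size"]),
    )
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
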