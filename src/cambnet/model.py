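"""CAMBNet: cross-attention multi-branch CNN for 64x64 tumor patches.

The network has a shared stem and three light branches:

* **SFEpath** (shallow feature extraction): 1x1 expansion to 128, 3x3
  depthwise, squeeze-and-excitation, 1x1 reduction back to 16, plus a
  residual connection from the stem output;
* **LTTpath1** (locate-the-tumor 1): a 1x1 -> depthwise 3x3 -> 1x1
  bottleneck (16 -> 8 -> 16);
* **LTTpath2**: a 1x1 reduction to 4 followed by alternating asymmetric
  1x3 / 3x1 convolutions (4 -> 8 -> 8 -> 8 -> 16), Inception-style
  factorisation that cuts parameters relative to square kernels.

The two LTT branches exchange attention: channel weights computed from one
branch gate the other, and spatial weights computed from the second gate
the first ("cross" wiring; both directions are available behind a config
switch).  Both attention sub-modules are single-path (average-pooled
descriptors only).  The gated branches are added, concatenated with the
SFEpath output (LTT sum first, SFE second) and passed to the deep feature
extraction module (DFEM): maxpool, 1x1 expansion to 128, stride-2 depthwise
(no residual here), SE, 1x1 to 64, maxpool, global average pooling,
dropout, and a linear 2-way classifier.

Every stage output is recorded under the tag of the corresponding row of
the architecture table (``EXPECTED_STAGE_INPUTS``) so shape conformance can
be checked mechanically and activations/gradients can be read for
explainability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass(frozen=True)
class CambnetConfig:
    """Architecture hyperparameters; the defaults realise the printed table."""

    input_side: int = 64
    in_channels: int = 3
    stem_channels: int = 16
    sfe_expansion_channels: int = 128
    ltt1_bottleneck_channels: int = 8
    ltt2_channel_plan: tuple[int, ...] = (4, 8, 8, 8, 16)
    branch_out_channels: int = 16
    dfem_expansion_channels: int = 128
    dfem_out_channels: int = 64
    n_classes: int = 2
    se_reduction_ratio: int = 16
    dropout_rate: float = 0.5
    attention_kernel_size: int = 7
    # "ltt1_channel" = channel attention from LTTpath1 gates LTTpath2 and
    # spatial attention from LTTpath2 gates LTTpath1; "ltt2_channel" swaps.
    cross_wiring: str = "ltt1_channel"
    attention_dual_path: bool = False  # ablation: avg+max descriptors

    def __post_init__(self):
        if self.ltt2_channel_plan[-1] != self.branch_out_channels:
            raise ValueError(
                "LTTpath2 channel plan must end at branch_out_channels "
                f"({self.ltt2_channel_plan[-1]} != {self.branch_out_channels})"
            )
        if self.branch_out_channels != self.stem_channels:
            raise ValueError(
                "branch_out_channels must equal stem_channels for the "
                "SFEpath residual connection and additive LTT fusion"
            )
        if self.cross_wiring not in ("ltt1_channel", "ltt2_channel"):
            raise ValueError(f"unknown cross_wiring {self.cross_wiring!r}")
        if self.input_side % 8:
            raise ValueError("input_side must be divisible by 8 (two maxpools "
                             "and one stride-2 stage)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


#: expected (H, W, C) input dimensions of every stage under the default
#: config, matching the published per-stage table row by row.
EXPECTED_STAGE_INPUTS: dict[str, tuple[int, int, int]] = {
    "Pre_layer": (64, 64, 3),
    "Conv1_1": (64, 64, 16),
    "Dwconv1_2": (64, 64, 128),
    "SEB1_3": (64, 64, 128),
    "Conv1_4": (64, 64, 128),
    "Conv2_1": (64, 64, 16),
    "Dwconv2_2": (64, 64, 8),
    "Conv2_3": (64, 64, 8),
    "Cross_Attention": (64, 64, 16),
    "Conv3_1": (64, 64, 16),
    "Conv3_2": (64, 64, 4),
    "Conv3_3": (64, 64, 8),
    "Conv3_4": (64, 64, 8),
    "Conv3_5": (64, 64, 8),
    "Maxpool4_1": (64, 64, 32),
    "Conv4_2": (32, 32, 32),
    "Dwconv4_3": (32, 32, 128),
    "SEB4_4": (16, 16, 128),
    "Conv4_5": (16, 16, 128),
    "Maxpool4_6": (16, 16, 64),
    "Fc4_7": (8, 8, 64),
}


class StageShapeError(ValueError):
    """Raised when a configuration produces an inconsistent stage."""


class CAMBNet(L.Module):
    """The model; ``forward`` returns logits and fills ``self.stages``."""

    def __init__(self, config: CambnetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        cs, ce = c.stem_channels, c.sfe_expansion_channels
        ratio = c.se_reduction_ratio

        self.stem = L.ConvBNReLU(c.in_channels, cs, 3, rng)

        # SFEpath
        self.conv1_1 = L.ConvBNReLU(cs, ce, 1, rng)
        self.dwconv1_2 = L.DwConvBNReLU(ce, 3, rng)
        self.seb1_3 = L.SEBlock(ce, ratio, rng)
        self.conv1_4 = L.Conv2d(ce, cs, 1, rng)
        self.bn1_4 = L.BatchNorm2d(cs)

        # LTTpath1
        cb = c.ltt1_bottleneck_channels
        self.conv2_1 = L.ConvBNReLU(cs, cb, 1, rng)
        self.dwconv2_2 = L.DwConvBNReLU(cb, 3, rng)
        self.conv2_3 = L.ConvBNReLU(cb, c.branch_out_channels, 1, rng)

        # LTTpath2: 1x1 then alternating 1x3 / 3x1
        plan = c.ltt2_channel_plan
        self.conv3_1 = L.ConvBNReLU(cs, plan[0], 1, rng)
        self.ltt2_stages = []
        in_ch = plan[0]
        for i, out_ch in enumerate(plan[1:]):
            ksize = (1, 3) if i % 2 == 0 else (3, 1)
            self.ltt2_stages.append(L.ConvBNReLU(in_ch, out_ch, ksize, rng))
            in_ch = out_ch

        # cross attention between the LTT branches
        self.channel_att = L.ChannelAttention(
            c.branch_out_channels, ratio, rng, dual_path=c.attention_dual_path
        )
        self.spatial_att = L.SpatialAttention(
            c.attention_kernel_size, rng, dual_path=c.attention_dual_path
        )

        # DFEM
        fused_ch = 2 * c.branch_out_channels
        self.conv4_2 = L.ConvBNReLU(fused_ch, c.dfem_expansion_channels, 1, rng)
        self.dwconv4_3 = L.DwConvBNReLU(c.dfem_expansion_channels, 3, rng, stride=2)
        self.seb4_4 = L.SEBlock(c.dfem_expansion_channels, ratio, rng)
        self.conv4_5 = L.ConvBNReLU(c.dfem_expansion_channels, c.dfem_out_channels,
                                    1, rng)
        self.dropout = L.Dropout(c.dropout_rate, rng)
        self.fc4_7 = L.Linear(c.dfem_out_channels, c.n_classes, rng)

        self.stages: dict[str, Tensor] = {}

    # -- branch forwards ---------------------------------------------------
    def stem_forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise StageShapeError(
                f"Pre_layer expects (N,{self.config.in_channels},H,W), got {x.shape}"
            )
        if x.shape[2] != self.config.input_side or x.shape[3] != self.config.input_side:
            raise StageShapeError(
                f"Pre_layer expects side {self.config.input_side}, got "
                f"{x.shape[2]}x{x.shape[3]}"
            )
        out = self.stem(x)
        self.stages["Pre_layer"] = out
        return out

    def sfepath_forward(self, stem_out: Tensor) -> Tensor:
        h = self.conv1_1(stem_out)
        self.stages["Conv1_1"] = h
        h = self.dwconv1_2(h)
        self.stages["Dwconv1_2"] = h
        h = self.seb1_3(h)
        self.stages["SEB1_3"] = h
        h = self.bn1_4(self.conv1_4(h))
        self.stages["Conv1_4"] = h
        out = T.relu(h + stem_out)  # residual connection from the stem
        self.stages["SFEpath"] = out
        return out

    def lttpath1_forward(self, stem_out: Tensor) -> Tensor:
        h = self.conv2_1(stem_out)
        self.stages["Conv2_1"] = h
        h = self.dwconv2_2(h)
        self.stages["Dwconv2_2"] = h
        h = self.conv2_3(h)
        self.stages["Conv2_3"] = h
        self.stages["LTTpath1"] = h
        return h

    def lttpath2_forward(self, stem_out: Tensor) -> Tensor:
        h = self.conv3_1(stem_out)
        self.stages["Conv3_1"] = h
        for i, stage in enumerate(self.ltt2_stages):
            h = stage(h)
            self.stages[f"Conv3_{i + 2}"] = h
        self.stages["LTTpath2"] = h
        return h

    def cross_attention(self, feat_a: Tensor, feat_b: Tensor
                        ) -> tuple[Tensor, Tensor]:
        """Channel gate from ``feat_a`` modulates ``feat_b``; spatial gate
        from ``feat_b`` modulates ``feat_a``."""
        if feat_a.shape != feat_b.shape:
            raise StageShapeError(
                f"cross attention shape mismatch: {feat_a.shape} vs {feat_b.shape}"
            )
        cw = self.channel_att(feat_a)
        sw = self.spatial_att(feat_b)
        self.stages["channel_weights"] = cw
        self.stages["spatial_weights"] = sw
        return feat_a * sw, feat_b * cw

    def fuse_branches(self, sfe_out: Tensor, att_a: Tensor, att_b: Tensor) -> Tensor:
        """(att_a + att_b) concatenated with sfe_out; LTT sum first."""
        if not (sfe_out.shape == att_a.shape == att_b.shape):
            raise StageShapeError("fuse_branches requires equal branch shapes")
        fused = T.concat([att_a + att_b, sfe_out], axis=1)
        self.stages["Fuse"] = fused
        return fused

    def dfem_forward(self, fused: Tensor) -> Tensor:
        self.stages["Maxpool4_1"] = fused  # tag = stage input, table convention
        h = T.maxpool2d(fused, 2)
        h = self.conv4_2(h)
        self.stages["Conv4_2"] = h
        h = self.dwconv4_3(h)
        self.stages["Dwconv4_3"] = h
        h = self.seb4_4(h)
        self.stages["SEB4_4"] = h
        h = self.conv4_5(h)
        self.stages["Conv4_5"] = h
        h = T.maxpool2d(h, 2)
        self.stages["Maxpool4_6"] = h
        feat = T.mean(h, axis=(2, 3))  # global average pooling to (N, 64)
        self.stages["GAP"] = feat
        logits = self.fc4_7(self.dropout(feat))
        self.stages["Fc4_7"] = logits
        return logits

    def __call__(self, x) -> Tensor:
        """Forward a batch (N, C, side, side) -> logits (N, n_classes)."""
        x = T.as_tensor(x)
        self.stages = {}
        stem_out = self.stem_forward(x)
        sfe = self.sfepath_forward(stem_out)
        ltt1 = self.lttpath1_forward(stem_out)
        ltt2 = self.lttpath2_forward(stem_out)
        # cross_attention(a, b) returns (a * spatial(b), b * channel(a))
        if self.config.cross_wiring == "ltt1_channel":
            att_l1, att_l2 = self.cross_attention(ltt1, ltt2)
        else:
            att_l2, att_l1 = self.cross_attention(ltt2, ltt1)
        self.stages["Cross_Attention_LTT1"] = att_l1
        self.stages["Cross_Attention_LTT2"] = att_l2
        fused = self.fuse_branches(sfe, att_l1, att_l2)
        return self.dfem_forward(fused)

    # -- introspection -----------------------------------------------------
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def stage_input_shapes(self, batch: int = 1) -> dict[str, tuple[int, int, int]]:
        """Realised (H, W, C) input dims per architecture-table row.

        Runs one inference forward on zeros and reads each tagged stage's
        recorded input (= previous stage output, per the table convention).
        """
        c = self.config
        was_training = self.training
        self.eval()
        with T.no_grad():
            self(np.zeros((batch, c.in_channels, c.input_side, c.input_side),
                          dtype=np.float32))
        if was_training:
            self.train()

        def hwc(t: Tensor) -> tuple[int, int, int]:
            _, ch, h, w = t.shape
            return (h, w, ch)

        s = self.stages
        realized = {
            "Pre_layer": (c.input_side, c.input_side, c.in_channels),
            "Conv1_1": hwc(s["Pre_layer"]),
            "Dwconv1_2": hwc(s["Conv1_1"]),
            "SEB1_3": hwc(s["Dwconv1_2"]),
            "Conv1_4": hwc(s["SEB1_3"]),
            "Conv2_1": hwc(s["Pre_layer"]),
            "Dwconv2_2": hwc(s["Conv2_1"]),
            "Conv2_3": hwc(s["Dwconv2_2"]),
            "Cross_Attention": hwc(s["Conv2_3"]),
            "Conv3_1": hwc(s["Pre_layer"]),
            "Conv3_2": hwc(s["Conv3_1"]),
            "Conv3_3": hwc(s["Conv3_2"]),
            "Conv3_4": hwc(s["Conv3_3"]),
            "Conv3_5": hwc(s["Conv3_4"]),
            "Maxpool4_1": hwc(s["Fuse"]),
            "Conv4_2": tuple(np.array(hwc(s["Fuse"])) // [2, 2, 1]),
            "Dwconv4_3": hwc(s["Conv4_2"]),
            "SEB4_4": hwc(s["Dwconv4_3"]),
            "Conv4_5": hwc(s["SEB4_4"]),
            "Maxpool4_6": hwc(s["Conv4_5"]),
            "Fc4_7": hwc(s["Maxpool4_6"]),
        }
        return {k: tuple(int(x) for x in v) for k, v in realized.items()}

    def summary_table(self) -> str:
        """Realised vs expected per-stage input dims, for eyeball diffing."""
        realized = self.stage_input_shapes()
        lines = [f"{'stage':<16}{'realized':<16}{'expected':<16}match"]
        for tag, exp in EXPECTED_STAGE_INPUTS.items():
            got = realized.get(tag)
            ok = "yes" if got == exp else "NO"
            fmt = lambda t: "x".join(map(str, t)) if t else "-"
            lines.append(f"{tag:<16}{fmt(got):<16}{fmt(exp):<16}{ok}")
        lines.append(f"trainable parameters: {self.parameter_count()}")
        return "\n".join(lines)

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        cfg = asdict(self.config)
        cfg["ltt2_channel_plan"] = list(cfg["ltt2_channel_plan"])
        np.savez(path, __config__=json.dumps(cfg), **self.state_dict())

    @classmethod
    def load(cls, path) -> "CAMBNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg["ltt2_channel_plan"] = tuple(cfg["ltt2_channel_plan"])
            model = cls(CambnetConfig(**cfg), np.random.default_rng(0))
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        model.eval()
        return model


def build_cambnet(config: CambnetConfig | None = None,
                  seed: int | np.random.Generator = 0) -> CAMBNet:
    """Construct a seeded CAMBNet (weights Kaiming-initialised, zero bias)."""
    config = config or CambnetConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return CAMBNet(config, rng)


def predict_proba(model: CAMBNet, patches: np.ndarray,
                  batch_size: int = 1) -> np.ndarray:
    """Class probabilities for patches given as (N, side, side, C) HWC."""
    from .nn.tensor import softmax

    model.eval()
    x = np.ascontiguousarray(np.transpose(patches, (0, 3, 1, 2)), dtype=np.float32)
    outs = []
    with T.no_grad():
        for i in range(0, len(x), batch_size):
            outs.append(model(x[i : i + batch_size]).data)
    return softmax(np.concatenate(outs, axis=0))


__all__ = [
    "CambnetConfig",
    "CAMBNet",
    "EXPECTED_STAGE_INPUTS",
    "StageShapeError",
    "build_cambnet",
    "predict_proba",
]
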