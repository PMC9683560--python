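"""Declarative network specifications.

A :class:`ModelSpec` is a compact, fully-resolved description of one of the
three network variants:

* ``csp_unet``       — shared encoder + segmentation decoder (branch II);
* ``branch1_only``   — shared encoder + grading classification head (branch I);
* ``mtnet``          — shared encoder + both branches (hard parameter sharing).

The same spec is consumed by two independent clients: the network builder
(:mod:`fundusmt.models`), which instantiates layers, and the complexity
accountant (:mod:`fundusmt.complexity`), which counts parameters and MACs
from the spec alone without building anything.  ``blocks()`` enumerates the
architecture as an ordered list of typed block descriptions, grouped into the
three parameter groups (``shared``, ``decoder``, ``head``).

Topology (downsampling factor 16): a two-conv stem (stride 1 then stride 2)
is followed by three encoder stages of BottleneckCSP + stride-2 conv.  The
decoder has four modules, each containing exactly one ASPP and one bilinear
upsample block; the three shallower modules first concatenate the matching
encoder CSP output (the skip), while the deepest module applies ASPP directly
to the encoder output, which is the only feature available at that
resolution.  The classification head downsamples once more, stacks conv
blocks, then global-average-pools into a fully connected 5-class layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence, Union

import yaml

ASPP_RATES = (6, 12, 18)
N_GRADES = 5


@dataclass(frozen=True)
class ConvBlockSpec:
    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    dilation: int = 1
    bn: bool = True      # conv has no bias when followed by batch norm
    kind: str = "conv_block"

    def __post_init__(self) -> None:
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")


@dataclass(frozen=True)
class BottleneckCSPSpec:
    in_channels: int
    out_channels: int
    repeats: int = 1
    kind: str = "bottleneck_csp"

    def __post_init__(self) -> None:
        if self.out_channels % 2:
            raise ValueError(f"CSP out channels must be even, got {self.out_channels}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ASPPSpec:
    in_channels: int
    out_channels: int
    branch_channels: int
    dilation_rates: tuple[int, ...] = ASPP_RATES
    kind: str = "aspp"

    def __post_init__(self) -> None:
        rates = tuple(self.dilation_rates)
        if any(r <= 0 for r in rates):
            raise ValueError(f"dilation rates must be positive, got {rates}")
        if len(set(rates)) > 1 and list(rates) != sorted(rates):
            raise ValueError(f"dilation rates must be increasing, got {rates}")


@dataclass(frozen=True)
class UpsampleBlockSpec:
    in_channels: int
    out_channels: int
    kind: str = "upsample_block"


@dataclass(frozen=True)
class ConcatSpec:
    sources: tuple[str, str]
    out_channels: int
    kind: str = "concat"


@dataclass(frozen=True)
class FCHeadSpec:
    in_features: int
    out_features: int = N_GRADES
    kind: str = "fc_head"


BlockSpec = Union[ConvBlockSpec, BottleneckCSPSpec, ASPPSpec,
                  UpsampleBlockSpec, ConcatSpec, FCHeadSpec]


@dataclass(frozen=True)
class Block:
    """One named block in the architecture.

    ``scale`` is the downsampling factor of the block's *output* feature map
    relative to the network input (1 = full resolution).
    """
    group: str          # shared | decoder | head
    name: str
    spec: BlockSpec
    scale: int


@dataclass
class ModelSpec:
    """Fully resolved description of a network variant."""

    name: str                                   # csp_unet | mtnet | branch1_only
    widths: tuple[int, int, int, int]           # stem/encoder stage channels
    repeats: tuple[int, int, int]               # bottlenecks per CSP stage
    aspp_branch: tuple[int, int, int, int]      # ASPP branch width, deep -> shallow
    aspp_out: tuple[int, int, int, int]         # ASPP output channels
    up_out: tuple[int, int, int, int]           # upsample-block output channels
    head_channels: tuple[int, ...]              # classification-head conv widths
    n_classes: int = N_GRADES

    VALID_NAMES = ("csp_unet", "mtnet", "branch1_only", "branch2_only")

    def __post_init__(self) -> None:
        if self.name not in self.VALID_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        self.widths = tuple(int(w) for w in self.widths)
        self.repeats = tuple(int(r) for r in self.repeats)
        self.aspp_branch = tuple(int(c) for c in self.aspp_branch)
        self.aspp_out = tuple(int(c) for c in self.aspp_out)
        self.up_out = tuple(int(c) for c in self.up_out)
        self.head_channels = tuple(int(c) for c in self.head_channels)
        if len(self.widths) != 4 or len(self.repeats) != 3:
            raise ValueError("expected 4 stage widths and 3 repeat counts")

    # ------------------------------------------------------------------
    @property
    def has_decoder(self) -> bool:
        return self.name in ("csp_unet", "mtnet", "branch2_only")

    @property
    def has_head(self) -> bool:
        return self.name in ("mtnet", "branch1_only")

    @property
    def downsample_factor(self) -> int:
        return 16

    def blocks(self) -> list[Block]:
        """Ordered block list consumed by the builder and the accountant."""
        w0, w1, w2, w3 = self.widths
        r1, r2, r3 = self.repeats
        out: list[Block] = [
            Block("shared", "stem.conv1", ConvBlockSpec(3, w0, 3, 1), 1),
            Block("shared", "stem.conv2", ConvBlockSpec(w0, w0, 3, 2), 2),
            Block("shared", "enc1.csp", BottleneckCSPSpec(w0, w0, r1), 2),
            Block("shared", "enc1.down", ConvBlockSpec(w0, w1, 3, 2), 4),
            Block("shared", "enc2.csp", BottleneckCSPSpec(w1, w1, r2), 4),
            Block("shared", "enc2.down", ConvBlockSpec(w1, w2, 3, 2), 8),
            Block("shared", "enc3.csp", BottleneckCSPSpec(w2, w2, r3), 8),
            Block("shared", "enc3.down", ConvBlockSpec(w2, w3, 3, 2), 16),
        ]
        if self.has_decoder:
            b3, b2, b1, b0 = self.aspp_branch
            a3, a2, a1, a0 = self.aspp_out
            u3, u2, u1, u0 = self.up_out
            out += [
                Block("decoder", "dec1.aspp", ASPPSpec(w3, a3, b3), 16),
                Block("decoder", "dec1.up", UpsampleBlockSpec(a3, u3), 8),
                Block("decoder", "dec2.concat",
                      ConcatSpec(("dec1.up", "enc3.csp"), u3 + w2), 8),
                Block("decoder", "dec2.aspp", ASPPSpec(u3 + w2, a2, b2), 8),
                Block("decoder", "dec2.up", UpsampleBlockSpec(a2, u2), 4),
                Block("decoder", "dec3.concat",
                      ConcatSpec(("dec2.up", "enc2.csp"), u2 + w1), 4),
                Block("decoder", "dec3.aspp", ASPPSpec(u2 + w1, a1, b1), 4),
                Block("decoder", "dec3.up", UpsampleBlockSpec(a1, u1), 2),
                Block("decoder", "dec4.concat",
                      ConcatSpec(("dec3.up", "enc1.csp"), u1 + w0), 2),
                Block("decoder", "dec4.aspp", ASPPSpec(u1 + w0, a0, b0), 2),
                Block("decoder", "dec4.up", UpsampleBlockSpec(a0, u0), 1),
                Block("decoder", "dec.final",
                      ConvBlockSpec(u0, 1, 3, 1, bn=False), 1),
            ]
        if self.has_head:
            cs = self.head_channels
            out.append(Block("head", "head.conv1",
                             ConvBlockSpec(w3, cs[0], 3, 2), 32))
            for i in range(1, len(cs)):
                out.append(Block("head", f"head.conv{i + 1}",
                                 ConvBlockSpec(cs[i - 1], cs[i], 3, 1), 32))
            out.append(Block("head", "head.fc",
                             FCHeadSpec(cs[-1], self.n_classes), 32))
        return out

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_list"] = [
            {"group": b.group, "name": b.name, "kind": b.spec.kind,
             "scale": b.scale, **{k: v for k, v in dataclasses.asdict(b.spec).items()
                                  if k != "kind"}}
            for b in self.blocks()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plainify(self.to_dict()), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)
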