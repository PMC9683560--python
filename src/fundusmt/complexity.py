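"""First-principles parameter and MAC accounting over a :class:`ModelSpec`.

Counting conventions (the usual profiler ones):

* conv layer: ``k*k*Cin*Cout`` weights, plus ``Cout`` bias scalars when the
  conv carries a bias, plus ``2*Cout`` batch-norm scalars when a batch norm
  follows (convs followed by BN carry no bias);
* fully connected: ``Nin*Nout + Nout``;
* MACs: ``k*k*Cin*Cout*Hout*Wout`` per conv, ``Nin*Nout`` per FC; batch
  norm, activations, bilinear upsampling, pooling and softmax are zero-MAC;
* "GFLOPs" is reported as giga-MACs (1 reported FLOP = 1 multiply-accumulate)
  unless ``flops_per_mac=2`` is requested.

All arithmetic is exact integer arithmetic; division by 1e6/1e9 happens only
at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .specs import (
    ASPPSpec,
    Block,
    BlockSpec,
    BottleneckCSPSpec,
    ConcatSpec,
    ConvBlockSpec,
    FCHeadSpec,
    ModelSpec,
    UpsampleBlockSpec,
)

__all__ = ["ComplexityReport", "count_params", "count_macs", "profile",
           "sharing_savings"]


@dataclass(frozen=True)
class LayerCount:
    """Exact parameter/MAC tally of one primitive layer."""
    name: str
    params: int
    macs: int


def _conv_params(cin: int, cout: int, k: int, bn: bool) -> int:
    p = k * k * cin * cout
    if bn:
        p += 2 * cout          # BN scale + shift; conv bias folded away
    else:
        p += cout              # plain conv bias
    return p


def _conv_macs(cin: int, cout: int, k: int, scale: int, h: int, w: int) -> int:
    return k * k * cin * cout * (h // scale) * (w // scale)


def _expand(block: Block, h: int, w: int) -> Iterator[LayerCount]:
    """Primitive layer counts of one block at input size (h, w).

    The expansion mirrors layer-for-layer what :mod:`fundusmt.models`
    instantiates; the test suite asserts exact agreement against a
    brute-force enumeration of the instantiated weight arrays.
    """
    s = block.spec
    sc = block.scale
    nm = block.name
    if isinstance(s, ConvBlockSpec):
        yield LayerCount(nm, _conv_params(s.in_channels, s.out_channels, s.kernel, s.bn),
                         _conv_macs(s.in_channels, s.out_channels, s.kernel, sc, h, w))
    elif isinstance(s, BottleneckCSPSpec):
        hid = s.out_channels // 2
        yield LayerCount(f"{nm}.cv1", _conv_params(s.in_channels, hid, 1, True),
                         _conv_macs(s.in_channels, hid, 1, sc, h, w))
        for i in range(s.repeats):
            yield LayerCount(f"{nm}.m{i}.cv1", _conv_params(hid, hid, 1, True),
                             _conv_macs(hid, hid, 1, sc, h, w))
            yield LayerCount(f"{nm}.m{i}.cv2", _conv_params(hid, hid, 3, True),
                             _conv_macs(hid, hid, 3, sc, h, w))
        yield LayerCount(f"{nm}.cv2", _conv_params(s.in_channels, hid, 1, False),
                         _conv_macs(s.in_channels, hid, 1, sc, h, w))
        yield LayerCount(f"{nm}.bn", 2 * (2 * hid), 0)
        yield LayerCount(f"{nm}.cv4", _conv_params(2 * hid, s.out_channels, 1, True),
                         _conv_macs(2 * hid, s.out_channels, 1, sc, h, w))
    elif isinstance(s, ASPPSpec):
        b = s.branch_channels
        yield LayerCount(f"{nm}.branch1", _conv_params(s.in_channels, b, 1, True),
                         _conv_macs(s.in_channels, b, 1, sc, h, w))
        for r in s.dilation_rates:
            yield LayerCount(f"{nm}.rate{r}", _conv_params(s.in_channels, b, 3, True),
                             _conv_macs(s.in_channels, b, 3, sc, h, w))
        cin_p = (1 + len(s.dilation_rates)) * b
        yield LayerCount(f"{nm}.project", _conv_params(cin_p, s.out_channels, 1, True),
                         _conv_macs(cin_p, s.out_channels, 1, sc, h, w))
    elif isinstance(s, UpsampleBlockSpec):
        # bilinear interpolation itself is parameter- and MAC-free
        yield LayerCount(f"{nm}.conv", _conv_params(s.in_channels, s.out_channels, 3, True),
                         _conv_macs(s.in_channels, s.out_channels, 3, sc, h, w))
    elif isinstance(s, FCHeadSpec):
        yield LayerCount(nm, s.in_features * s.out_features + s.out_features,
                         s.in_features * s.out_features)
    elif isinstance(s, ConcatSpec):
        return
    else:  # pragma: no cover - exhaustive over BlockSpec
        raise TypeError(f"unknown block spec {type(s).__name__}")


@dataclass
class ComplexityReport:
    """Exact totals plus per-block breakdown for one model at one input size.

    ``params_millions`` and ``gflops`` are the printed-table conventions
    (totals / 1e6 and / 1e9, rounded to 1 decimal).
    """
    model: str
    input_hw: tuple[int, int]
    total_params: int
    total_macs: int
    per_block: list[LayerCount]
    by_group: dict[str, tuple[int, int]]
    flops_per_mac: int = 1

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 1)

    @property
    def gflops(self) -> float:
        return round(self.flops_per_mac * self.total_macs / 1e9, 1)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "input_hw": list(self.input_hw),
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "params_millions": self.params_millions,
            "gflops": self.gflops,
            "by_group": {g: {"params": p, "macs": m}
                         for g, (p, m) in self.by_group.items()},
            "per_block": [{"name": c.name, "params": c.params, "macs": c.macs}
                          for c in self.per_block],
        }

    def to_text(self) -> str:
        lines = [f"model: {self.model}  input: {self.input_hw[0]}x{self.input_hw[1]}",
                 f"{'layer':<28}{'params':>14}{'MACs':>18}"]
        for c in self.per_block:
            lines.append(f"{c.name:<28}{c.params:>14,}{c.macs:>18,}")
        for g, (p, m) in self.by_group.items():
            lines.append(f"{'[' + g + ']':<28}{p:>14,}{m:>18,}")
        lines.append(f"{'TOTAL':<28}{self.total_params:>14,}{self.total_macs:>18,}")
        lines.append(f"=> {self.params_millions} M parameters, "
                     f"{self.gflops} GFLOPs")
        return "\n".join(lines)


def profile(spec: ModelSpec, input_hw: tuple[int, int] = (512, 512), *,
            flops_per_mac: int = 1) -> ComplexityReport:
    """Count parameters and MACs of ``spec`` at ``input_hw`` from scratch."""
    h, w = input_hw
    if h % spec.downsample_factor or w % spec.downsample_factor:
        raise ValueError(
            f"input size {h}x{w} not divisible by {spec.downsample_factor}")
    per_block: list[LayerCount] = []
    by_group: dict[str, list[int]] = {}
    for block in spec.blocks():
        for cnt in _expand(block, h, w):
            per_block.append(cnt)
            acc = by_group.setdefault(block.group, [0, 0])
            acc[0] += cnt.params
            acc[1] += cnt.macs
    total_p = sum(c.params for c in per_block)
    total_m = sum(c.macs for c in per_block)
    return ComplexityReport(
        model=spec.name, input_hw=(h, w),
        total_params=total_p, total_macs=total_m,
        per_block=per_block,
        by_group={g: (p, m) for g, (p, m) in by_group.items()},
        flops_per_mac=flops_per_mac,
    )


def count_params(spec: ModelSpec) -> ComplexityReport:
    """Parameter count (input-size independent; reported at 512x512)."""
    return profile(spec, (512, 512))


def count_macs(spec: ModelSpec, input_hw: tuple[int, int],
               *, flops_per_mac: int = 1) -> ComplexityReport:
    return profile(spec, input_hw, flops_per_mac=flops_per_mac)


def sharing_savings(report1: ComplexityReport, report2: ComplexityReport,
                    report_joint: ComplexityReport) -> tuple[float, float]:
    """Percentage savings of the joint model versus running both singles.

    Returns ``(param_saving_pct, flop_saving_pct)`` where each is
    ``100 * (x1 + x2 - x_joint) / (x1 + x2)`` computed on the printed-table
    values (millions / GFLOPs at 1 decimal), matching how the savings are
    quoted alongside those tables.
    """
    sizes = {report1.input_hw, report2.input_hw, report_joint.input_hw}
    if len(sizes) != 1:
        raise ValueError(f"reports computed at different input sizes: {sizes}")
    p1, p2, pj = (r.params_millions for r in (report1, report2, report_joint))
    f1, f2, fj = (r.gflops for r in (report1, report2, report_joint))
    if p1 + p2 == 0 or f1 + f2 == 0:
        raise ZeroDivisionError("single-task totals are zero")
    return (100.0 * (p1 + p2 - pj) / (p1 + p2),
            100.0 * (f1 + f2 - fj) / (f1 + f2))
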