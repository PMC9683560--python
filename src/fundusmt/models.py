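"""Network builders and runnable models.

Three variants share one encoder layout (the hard-shared backbone):

* :func:`build_csp_unet` — vessel-segmentation network: encoder + decoder
  with per-module ASPP (rates 6/12/18) and bilinear upsampling, ending in a
  1-channel conv + sigmoid probability map;
* :func:`build_branch1` — grading-diagnosis network: encoder + conv head +
  global average pooling + 5-class FC + softmax;
* :func:`build_mtnet` — both branches on the single shared encoder.

``CALIBRATED`` is the default channel schedule.  Stage widths and repeat
counts were fixed by calibrating the complexity accountant against the
published budget tables: 15.1 M parameters / 46.0 GFLOPs at 512x512 for the
segmentation network, 18.8 M / 24.9 G for the grading-only network, and
24.8 M / 48.5 G for the joint network (per-group: encoder 9.1 M / 22.4 G,
decoder 6.0 M / 23.6 G, head 9.7 M / 2.5 G).  ``TINY`` is a narrow variant
for CPU-scale training and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor
from .specs import ModelSpec, N_GRADES

__all__ = [
    "CALIBRATED", "TINY", "GradePrediction",
    "build_csp_unet", "build_mtnet", "build_branch1", "build_model",
    "MTNet",
]

# Channel schedule calibrated against the printed complexity budgets.
CALIBRATED: dict = {
    "widths": (48, 160, 512, 1370),
    "repeats": (1, 1, 2),
    "aspp_branch": (64, 118, 24, 12),
    "aspp_out": (512, 160, 64, 16),
    "up_out": (160, 96, 32, 8),
    "head_channels": (192, 384, 1924),
}

# Narrow schedule for desk-scale training experiments and the test suite.
TINY: dict = {
    "widths": (4, 8, 16, 32),
    "repeats": (1, 1, 1),
    "aspp_branch": (8, 8, 8, 8),
    "aspp_out": (32, 16, 16, 16),
    "up_out": (16, 16, 8, 8),
    "head_channels": (16, 16),
}


def _make_spec(name: str, schedule: Optional[dict]) -> ModelSpec:
    sched = dict(CALIBRATED if schedule is None else schedule)
    return ModelSpec(name=name, **sched)


def build_csp_unet(schedule: Optional[dict] = None) -> ModelSpec:
    return _make_spec("csp_unet", schedule)


def build_mtnet(schedule: Optional[dict] = None) -> ModelSpec:
    return _make_spec("mtnet", schedule)


def build_branch1(schedule: Optional[dict] = None) -> ModelSpec:
    return _make_spec("branch1_only", schedule)


@dataclass
class GradePrediction:
    """Softmax class probabilities over the 5 retinopathy grades."""
    probs: np.ndarray         # shape (5,), sums to 1
    grade: int                # argmax

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "GradePrediction":
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape != (N_GRADES,):
            raise ValueError(f"expected {N_GRADES} probabilities, got {probs.shape}")
        if not np.isclose(probs.sum(), 1.0, atol=1e-5):
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")
        return cls(probs=probs, grade=int(np.argmax(probs)))


class SharedEncoder(nn.Module):
    """Stem + three CSP/downsample stages; the hard-shared backbone."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator) -> None:
        super().__init__()
        w0, w1, w2, w3 = spec.widths
        r1, r2, r3 = spec.repeats
        self.stem1 = nn.ConvBlock(rng, 3, w0, stride=1)
        self.stem2 = nn.ConvBlock(rng, w0, w0, stride=2)
        self.csp1 = nn.BottleneckCSP(rng, w0, w0, r1)
        self.down1 = nn.ConvBlock(rng, w0, w1, stride=2)
        self.csp2 = nn.BottleneckCSP(rng, w1, w1, r2)
        self.down2 = nn.ConvBlock(rng, w1, w2, stride=2)
        self.csp3 = nn.BottleneckCSP(rng, w2, w2, r3)
        self.down3 = nn.ConvBlock(rng, w2, w3, stride=2)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Returns (skip at H/2, skip at H/4, skip at H/8, bottleneck at H/16)."""
        g1 = self.csp1(self.stem2(self.stem1(x)))
        g2 = self.csp2(self.down1(g1))
        g3 = self.csp3(self.down2(g2))
        f3 = self.down3(g3)
        return g1, g2, g3, f3


class Decoder(nn.Module):
    """Branch II: four (concat/ASPP/upsample) modules + 1-channel sigmoid conv."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator) -> None:
        super().__init__()
        w0, w1, w2, w3 = spec.widths
        b3, b2, b1, b0 = spec.aspp_branch
        a3, a2, a1, a0 = spec.aspp_out
        u3, u2, u1, u0 = spec.up_out
        self.aspp1 = nn.ASPP(rng, w3, a3, b3)
        self.up1 = nn.UpsampleBlock(rng, a3, u3)
        self.aspp2 = nn.ASPP(rng, u3 + w2, a2, b2)
        self.up2 = nn.UpsampleBlock(rng, a2, u2)
        self.aspp3 = nn.ASPP(rng, u2 + w1, a1, b1)
        self.up3 = nn.UpsampleBlock(rng, a1, u1)
        self.aspp4 = nn.ASPP(rng, u1 + w0, a0, b0)
        self.up4 = nn.UpsampleBlock(rng, a0, u0)
        self.final = nn.Conv2d(rng, u0, 1, k=3, bias=True)

    def forward(self, g1: Tensor, g2: Tensor, g3: Tensor, f3: Tensor) -> Tensor:
        d = self.up1(self.aspp1(f3))
        d = self.up2(self.aspp2(nn.concat_channels([d, g3])))
        d = self.up3(self.aspp3(nn.concat_channels([d, g2])))
        d = self.up4(self.aspp4(nn.concat_channels([d, g1])))
        return nn.sigmoid(self.final(d))


class ClsHead(nn.Module):
    """Branch I: stride-2 conv, conv stack, global average pool, FC, softmax."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator) -> None:
        super().__init__()
        w3 = spec.widths[3]
        cs = spec.head_channels
        self.conv1 = nn.ConvBlock(rng, w3, cs[0], stride=2)
        self.convs = [nn.ConvBlock(rng, cs[i - 1], cs[i]) for i in range(1, len(cs))]
        self.fc = nn.Linear(rng, cs[-1], spec.n_classes)

    def forward(self, f3: Tensor) -> Tensor:
        h = self.conv1(f3)
        for c in self.convs:
            h = c(h)
        return nn.softmax(self.fc(nn.global_avg_pool(h)), axis=-1)


class MTNet(nn.Module):
    """Runnable model for any of the three spec variants.

    One forward pass on a fundus image batch yields, depending on the
    variant, a vessel probability map (branch II), 5-grade probabilities
    (branch I), or both from the single shared encoder pass.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.seed = seed
        self.encoder = SharedEncoder(spec, rng)
        self.decoder = Decoder(spec, rng) if spec.has_decoder else None
        self.head = ClsHead(spec, rng) if spec.has_head else None

    # ``spec`` / ``seed`` are plain attrs; exclude them from Module traversal
    def named_parameters(self, prefix: str = ""):
        for attr in ("encoder", "decoder", "head"):
            mod = getattr(self, attr)
            if mod is not None:
                yield from mod.named_parameters(f"{prefix}{attr}.")

    def _named_bn(self, prefix: str = ""):
        for attr in ("encoder", "decoder", "head"):
            mod = getattr(self, attr)
            if mod is not None:
                yield from mod._named_bn(f"{prefix}{attr}.")

    def modules(self):
        yield self
        for attr in ("encoder", "decoder", "head"):
            mod = getattr(self, attr)
            if mod is not None:
                yield from mod.modules()

    def forward(self, x: Tensor,
                branches: Optional[tuple[str, ...]] = None) -> dict[str, Tensor]:
        """One shared encoder pass feeding the requested branches.

        ``branches`` defaults to every branch the variant has; pass
        ``("grade",)`` or ``("seg",)`` to skip the other branch's compute.
        """
        self._check_input(x.data)
        g1, g2, g3, f3 = self.encoder(x)
        out: dict[str, Tensor] = {}
        if self.decoder is not None and (branches is None or "seg" in branches):
            out["seg"] = self.decoder(g1, g2, g3, f3)
        if self.head is not None and (branches is None or "grade" in branches):
            out["grade_probs"] = self.head(f3)
        return out

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        f = self.spec.downsample_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"input size {x.shape[2]}x{x.shape[3]} not divisible by {f}")

    # -- parameter groups ----------------------------------------------
    def parameter_groups(self) -> dict[str, dict[str, nn.Parameter]]:
        """Disjoint named-parameter groups: shared / branch1 / branch2."""
        groups: dict[str, dict[str, nn.Parameter]] = {
            "shared": dict(self.encoder.named_parameters("encoder."))}
        if self.head is not None:
            groups["branch1"] = dict(self.head.named_parameters("head."))
        if self.decoder is not None:
            groups["branch2"] = dict(self.decoder.named_parameters("decoder."))
        return groups

    # -- inference helpers ---------------------------------------------
    def predict_proba_map(self, images: np.ndarray) -> np.ndarray:
        """Vessel probability maps, (N, H, W), eval mode."""
        if self.decoder is None:
            raise ValueError("model has no segmentation branch")
        mode = self._training
        self.eval()
        out = self.forward(Tensor(np.asarray(images, dtype=np.float32)),
                           branches=("seg",))
        self.train(mode)
        return out["seg"].data[:, 0]

    def predict_grades(self, images: np.ndarray) -> list[GradePrediction]:
        if self.head is None:
            raise ValueError("model has no grading branch")
        mode = self._training
        self.eval()
        out = self.forward(Tensor(np.asarray(images, dtype=np.float32)),
                           branches=("grade",))
        self.train(mode)
        return [GradePrediction.from_probs(p) for p in out["grade_probs"].data]


def build_model(spec: ModelSpec, seed: int = 0) -> MTNet:
    """Instantiate a runnable network from a declarative spec."""
    return MTNet(spec, seed=seed)
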