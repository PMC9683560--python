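"""Loss functions constraining the two branches.

Segmentation (branch II) uses per-pixel binary cross-entropy on the sigmoid
probability map plus soft Dice loss, summed: L = L_ce + L_dice.  With deep
supervision over n outputs the vessel loss generalises to
L_vessel = sum_k lambda_k (L_ce^k + L_dice^k); the default is a single
supervised output with unit weight, which reduces to the plain sum.

Grading (branch I) uses categorical cross-entropy over the 5 softmax
probabilities: -log p_label.  The joint multi-task loss is the plain sum
L = L_dr + L_vessel.

Probabilities are clipped to [1e-7, 1 - 1e-7] before logarithms; the clip
also zeroes the gradient there.  All losses accept either raw numpy arrays
or autodiff :class:`~fundusmt.nn.Tensor` inputs and return a scalar Tensor
(use ``float(...)`` / ``.item()`` for the value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .nn import Tensor
from .specs import N_GRADES

__all__ = [
    "EPS", "SegLossBreakdown", "VesselLossConfig", "JointLossBreakdown",
    "seg_ce", "dice_loss", "seg_loss", "dr_ce", "joint_loss",
]

EPS = 1e-7

ArrayLike = Union[np.ndarray, Tensor]


def _as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_shapes(p: Tensor, y: Tensor) -> None:
    if p.data.shape != y.data.shape:
        raise ValueError(f"shape mismatch: prediction {p.data.shape} "
                         f"vs target {y.data.shape}")


@dataclass(frozen=True)
class VesselLossConfig:
    """Weights of the (possibly deep-supervised) vessel loss.

    ``n`` supervised outputs with positive weights ``lambdas``; the default
    single output with unit weight reproduces L_ce + L_dice exactly.
    """
    n: int = 1
    lambdas: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.lambdas) != self.n:
            raise ValueError(f"{len(self.lambdas)} weights for n={self.n} outputs")
        if any(l <= 0 for l in self.lambdas):
            raise ValueError("all loss weights must be positive")


@dataclass(frozen=True)
class SegLossBreakdown:
    """Cross-entropy and Dice components of one segmentation loss value.

    ``total == ce + dice`` exactly; ``loss`` carries the differentiable
    scalar when the inputs were autodiff tensors.
    """
    ce: float
    dice: float
    total: float
    loss: Optional[Tensor] = None


@dataclass(frozen=True)
class JointLossBreakdown:
    """Grading + vessel components of the multi-task loss (total = sum)."""
    dr_ce: float
    vessel: float
    total: float


def seg_ce(p: ArrayLike, y: ArrayLike) -> Tensor:
    """Mean per-pixel binary cross-entropy of probability map vs {0,1} mask."""
    p, y = _as_tensor(p), _as_tensor(y)
    _check_shapes(p, y)
    pd, yd = p.data, y.data
    if not np.isfinite(pd).all():
        raise ValueError("non-finite probabilities")
    pc = np.clip(pd, EPS, 1.0 - EPS)
    n = pd.size
    val = -np.sum(yd * np.log(pc) + (1.0 - yd) * np.log1p(-pc)) / n

    if not (p.requires_grad or p._parents):
        return Tensor(np.float64(val))

    inside = (pd > EPS) & (pd < 1.0 - EPS)

    def backward(gy: np.ndarray) -> None:
        g = (-yd / pc + (1.0 - yd) / (1.0 - pc)) / n
        p.accumulate(gy * np.where(inside, g, 0.0))

    return Tensor(np.float64(val), parents=[p], backward=backward)


def dice_loss(p: ArrayLike, y: ArrayLike, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*y)+s) / (sum(p)+sum(y)+s), in [0, 1)."""
    p, y = _as_tensor(p), _as_tensor(y)
    _check_shapes(p, y)
    pd, yd = p.data, y.data
    inter = float(np.sum(pd * yd))
    denom = float(np.sum(pd) + np.sum(yd)) + smooth
    val = 1.0 - (2.0 * inter + smooth) / denom

    if not (p.requires_grad or p._parents):
        return Tensor(np.float64(val))

    def backward(gy: np.ndarray) -> None:
        num = 2.0 * inter + smooth
        g = -(2.0 * yd * denom - num) / (denom * denom)
        p.accumulate(gy * g)

    return Tensor(np.float64(val), parents=[p], backward=backward)


def seg_loss(p: Union[ArrayLike, Sequence[ArrayLike]],
             y: Union[ArrayLike, Sequence[ArrayLike]],
             cfg: VesselLossConfig = VesselLossConfig(),
             smooth: float = 1.0) -> SegLossBreakdown:
    """Weighted vessel loss over one or more supervised outputs.

    Pass single (p, y) arrays for the default n=1 case, or equal-length
    sequences of per-output pairs matching ``cfg.n``.
    """
    if isinstance(p, (list, tuple)) != isinstance(y, (list, tuple)):
        raise ValueError("p and y must both be single maps or both sequences")
    ps = list(p) if isinstance(p, (list, tuple)) else [p]
    ys = list(y) if isinstance(y, (list, tuple)) else [y]
    if len(ps) != cfg.n or len(ys) != cfg.n:
        raise ValueError(f"config expects {cfg.n} outputs, got {len(ps)}")

    total_t: Optional[Tensor] = None
    ce_val = 0.0
    dice_val = 0.0
    from .nn import add, scale
    for lam, pk, yk in zip(cfg.lambdas, ps, ys):
        ce_k = seg_ce(pk, yk)
        dice_k = dice_loss(pk, yk, smooth=smooth)
        ce_val += lam * ce_k.item()
        dice_val += lam * dice_k.item()
        term = scale(add(ce_k, dice_k), lam)
        total_t = term if total_t is None else add(total_t, term)
    return SegLossBreakdown(ce=ce_val, dice=dice_val, total=ce_val + dice_val,
                            loss=total_t)


def dr_ce(probs: ArrayLike, label: Union[int, Sequence[int]]) -> Tensor:
    """Categorical cross-entropy -log p_label over the 5 grades.

    ``probs`` is a 5-vector (single image) or an (N, 5) batch with a label
    per row; the batch value is the mean.
    """
    p = _as_tensor(probs)
    pd = p.data
    single = pd.ndim == 1
    pb = pd[None, :] if single else pd
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    if pb.ndim != 2 or pb.shape[1] != N_GRADES:
        raise ValueError(f"expected {N_GRADES} class probabilities, got {pb.shape}")
    if labels.shape[0] != pb.shape[0]:
        raise ValueError("one label per probability row required")
    if labels.min() < 0 or labels.max() >= N_GRADES:
        raise ValueError(f"label outside 0..{N_GRADES - 1}: {labels}")
    sums = pb.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError(f"probabilities must sum to 1 (got {sums})")
    n = pb.shape[0]
    rows = np.arange(n)
    pc = np.clip(pb[rows, labels], EPS, 1.0)
    val = float(-np.log(pc).mean())

    if not (p.requires_grad or p._parents):
        return Tensor(np.float64(val))

    def backward(gy: np.ndarray) -> None:
        g = np.zeros_like(pb)
        inside = pb[rows, labels] > EPS
        g[rows, labels] = np.where(inside, -1.0 / pc, 0.0) / n
        p.accumulate(gy * (g[0] if single else g))

    return Tensor(np.float64(val), parents=[p], backward=backward)


def joint_loss(dr: float, vessel: float) -> JointLossBreakdown:
    """Multi-task total: grading cross-entropy plus vessel loss."""
    dr = float(dr)
    vessel = float(vessel)
    if not (np.isfinite(dr) and np.isfinite(vessel)):
        raise ValueError("loss terms must be finite")
    return JointLossBreakdown(dr_ce=dr, vessel=vessel, total=dr + vessel)
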