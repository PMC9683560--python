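"""Optimizer schedule and the staged multi-task training protocol.

The protocol has four stages, all with Adam (lr 1e-3 cosine-annealed to
2e-7, batch size 4, 60 epochs by default) and best-loss checkpointing:

1. branch I (grading) is trained on retinopathy data; the shared encoder
   updates too;
2. branch II (segmentation) is trained on vessel data, shared encoder
   updating, branch I untouched;
3. joint training: each optimization step draws one retinopathy batch and
   one vessel batch in strict alternation (retinopathy first), computes both
   losses and backpropagates their sum once;
4. fine-tune: the shared encoder is frozen (asserted bitwise), both branches
   train, and the three parameter groups are merged into one checkpoint.

Checkpoint selection keeps the epoch with minimum monitored loss (ties go to
the earliest epoch).  By default the monitored loss is computed on a
held-out monitoring split the caller provides; passing the test split
reproduces the published procedure verbatim (which leaks test data into
model selection — hence not the default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Optional, Union

import numpy as np
import yaml

from .losses import VesselLossConfig, dr_ce, joint_loss, seg_loss
from .metrics import binarize, confusion, grading_accuracy, segmentation_metrics
from .models import MTNet, build_model
from .nn import Adam, Parameter, Tensor, add
from .specs import ModelSpec

__all__ = [
    "TrainConfig", "SegData", "GradeData", "Checkpoint", "StepLog",
    "cosine_lr", "select_best", "train_stage1", "train_stage2",
    "train_stage3_joint", "finetune_and_merge", "run_full_protocol",
    "evaluate_segmentation", "evaluate_grading",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, schedule and stage settings."""
    lr_max: float = 1e-3
    lr_min: float = 2e-7
    epochs: int = 60
    batch_size: int = 4
    optimizer: str = "adam"
    schedule: str = "cosine_annealing"
    stage: Union[int, str] = 1
    seed: int = 0
    loss_weights: VesselLossConfig = field(default_factory=VesselLossConfig)
    monitor_on_test: bool = False

    def __post_init__(self) -> None:
        if self.lr_min >= self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in (
            "lr_max", "lr_min", "epochs", "batch_size", "optimizer",
            "schedule", "stage", "seed", "monitor_on_test")}
        d["loss_weights"] = {"n": self.loss_weights.n,
                             "lambdas": list(self.loss_weights.lambdas)}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text)
        lw = d.pop("loss_weights", None)
        cfg = cls(**d) if lw is None else cls(
            **d, loss_weights=VesselLossConfig(lw["n"], tuple(lw["lambdas"])))
        return cfg


@dataclass
class SegData:
    """Vessel-segmentation data: (N, 3, H, W) images + (N, H, W) masks."""
    images: np.ndarray
    masks: np.ndarray

    def __post_init__(self) -> None:
        if len(self.images) != len(self.masks) or len(self.images) == 0:
            raise ValueError("images and masks must be equal-length and non-empty")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class GradeData:
    """Grading data: (N, 3, H, W) images + (N,) integer grades."""
    images: np.ndarray
    grades: np.ndarray

    def __post_init__(self) -> None:
        if len(self.images) != len(self.grades) or len(self.images) == 0:
            raise ValueError("images and grades must be equal-length and non-empty")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class StepLog:
    step: int
    stage: str
    lr: float
    dr_ce: float
    vessel: float
    total: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def _group_of(name: str) -> str:
    """Map a state-dict key to its hard-sharing parameter group."""
    if name.startswith("encoder."):
        return "shared"
    if name.startswith("head."):
        return "branch1"
    if name.startswith("decoder."):
        return "branch2"
    raise ValueError(f"cannot assign parameter {name!r} to a group")


@dataclass
class Checkpoint:
    """Per-group model state (weights and batch-norm statistics) plus
    provenance.  Group keys: shared / branch1 / branch2."""
    weights: dict[str, dict[str, np.ndarray]]
    spec: ModelSpec
    stage: Union[int, str]
    best_monitored_loss: float
    seed: int

    def flat_weights(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for group, params in self.weights.items():
            for name, arr in params.items():
                if name in out:
                    raise ValueError(f"parameter {name} in two groups")
                out[name] = arr
        return out

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        meta = {"spec": self.spec.to_dict() | {"block_list": None},
                "stage": self.stage,
                "best_monitored_loss": self.best_monitored_loss,
                "seed": self.seed,
                "groups": {g: list(ws) for g, ws in self.weights.items()}}
        arrays = {f"{g}::{n}": a for g, ws in self.weights.items()
                  for n, a in ws.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Checkpoint":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            weights: dict[str, dict[str, np.ndarray]] = {
                g: {} for g in meta["groups"]}
            for key in z.files:
                if key == "__meta__":
                    continue
                g, n = key.split("::", 1)
                weights[g][n] = z[key]
        spec_d = {k: v for k, v in meta["spec"].items() if k != "block_list"}
        return cls(weights=weights, spec=ModelSpec.from_dict(spec_d),
                   stage=meta["stage"],
                   best_monitored_loss=meta["best_monitored_loss"],
                   seed=meta["seed"])

    def load_into(self, model: MTNet) -> None:
        model.load_state_dict(self.flat_weights())


def cosine_lr(t: float, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate at schedule fraction ``t`` in [0, 1]."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"schedule fraction must be in [0,1], got {t}")
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (1.0 + math.cos(math.pi * t))


def select_best(history: list[tuple[int, float, dict[str, np.ndarray]]]
                ) -> tuple[int, float, dict[str, np.ndarray]]:
    """Minimum monitored loss; ties broken by the earliest epoch."""
    if not history:
        raise ValueError("empty training history")
    best = history[0]
    for entry in history[1:]:
        if entry[1] < best[1]:
            best = entry
    return best


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

# stable per-stage RNG stream ids (string hashing is not reproducible)
_STAGE_STREAM = {"1": 1, "2": 2, "3": 3, "finetune": 4}


def _epoch_fraction(epoch: int, epochs: int) -> float:
    return 0.0 if epochs == 1 else epoch / (epochs - 1)


def _batches(n: int, batch_size: int, rng: np.random.Generator
             ) -> Iterator[np.ndarray]:
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _cycle_batches(n: int, n_batches: int, batch_size: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """n_batches index batches; the dataset cycles (reshuffled) if smaller."""
    out: list[np.ndarray] = []
    while len(out) < n_batches:
        out.extend(_batches(n, batch_size, rng))
    return out[:n_batches]


def _dr_loss_tensor(model: MTNet, images: np.ndarray, grades: np.ndarray) -> Tensor:
    out = model(Tensor(images), branches=("grade",))
    return dr_ce(out["grade_probs"], grades)

def _seg_loss_tensor(model: MTNet, images: np.ndarray, masks: np.ndarray,
                     cfg: TrainConfig) -> Tensor:
    out = model(Tensor(images), branches=("seg",))
    bk = seg_loss(out["seg"], masks[:, None, :, :].astype(np.float64),
                  cfg.loss_weights)
    return bk.loss


def _monitor_loss(model: MTNet, data, loss_kind: str, cfg: TrainConfig,
                  chunk: int = 8) -> float:
    """Monitored loss over a dataset, evaluated in chunks (bounded memory)."""
    mode = model.training
    model.eval()
    total, n = 0.0, len(data)
    for i in range(0, n, chunk):
        k = min(chunk, n - i)
        if loss_kind == "dr":
            v = float(_dr_loss_tensor(model, data.images[i:i + k],
                                      data.grades[i:i + k]))
        else:
            v = float(_seg_loss_tensor(model, data.images[i:i + k],
                                       data.masks[i:i + k], cfg))
        total += v * k
    model.train(mode)
    return total / n


def _train_single_branch(model: MTNet, data, cfg: TrainConfig, *,
                         loss_kind: str, stage: Union[int, str],
                         groups: tuple[str, ...],
                         monitor_data=None,
                         log: Optional[list[StepLog]] = None) -> Checkpoint:
    if len(data) == 0:
        raise ValueError("empty training data")
    monitor = monitor_data if monitor_data is not None else data
    pgroups = model.parameter_groups()
    params: dict[str, Parameter] = {}
    for g in groups:
        params.update(pgroups[g])
    opt = Adam(params, lr=cfg.lr_max)
    model.train(True)
    best_loss = math.inf
    best_state: Optional[dict[str, np.ndarray]] = None
    step = 0
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(_epoch_fraction(epoch, cfg.epochs), cfg)
        rng = np.random.default_rng((cfg.seed, _STAGE_STREAM.get(str(stage), 9), epoch))
        for idx in _batches(len(data), cfg.batch_size, rng):
            opt.zero_grad()
            if loss_kind == "dr":
                loss = _dr_loss_tensor(model, data.images[idx], data.grades[idx])
                dr_val, seg_val = float(loss), 0.0
            else:
                loss = _seg_loss_tensor(model, data.images[idx],
                                        data.masks[idx], cfg)
                dr_val, seg_val = 0.0, float(loss)
            loss.backward()
            opt.step()
            step += 1
            if log is not None:
                log.append(StepLog(step, str(stage), opt.lr, dr_val, seg_val,
                                   dr_val + seg_val))
        # best-checkpoint rule: strictly smaller monitored loss wins, so
        # ties keep the earliest epoch
        mon = _monitor_loss(model, monitor, loss_kind, cfg)
        if mon < best_loss:
            best_loss = mon
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return _make_checkpoint(model, stage, best_loss, cfg.seed)


def _make_checkpoint(model: MTNet, stage, best_loss: float, seed: int) -> Checkpoint:
    weights: dict[str, dict[str, np.ndarray]] = {}
    for name, arr in model.state_dict().items():
        weights.setdefault(_group_of(name), {})[name] = arr
    return Checkpoint(weights=weights, spec=model.spec, stage=stage,
                      best_monitored_loss=best_loss, seed=seed)


# ---------------------------------------------------------------------------
# the four stages
# ---------------------------------------------------------------------------

def train_stage1(model: MTNet, dr_data: GradeData, cfg: TrainConfig,
                 monitor_data: Optional[GradeData] = None,
                 log: Optional[list[StepLog]] = None) -> Checkpoint:
    """Stage 1: grading branch + shared encoder on retinopathy data."""
    if model.head is None:
        raise ValueError("model has no grading branch")
    return _train_single_branch(model, dr_data, cfg, loss_kind="dr",
                                stage=1, groups=("shared", "branch1"),
                                monitor_data=monitor_data, log=log)


def train_stage2(model: MTNet, vessel_data: SegData, cfg: TrainConfig,
                 monitor_data: Optional[SegData] = None,
                 log: Optional[list[StepLog]] = None) -> Checkpoint:
    """Stage 2: segmentation branch + shared encoder on vessel data."""
    if model.decoder is None:
        raise ValueError("model has no segmentation branch")
    return _train_single_branch(model, vessel_data, cfg, loss_kind="seg",
                                stage=2, groups=("shared", "branch2"),
                                monitor_data=monitor_data, log=log)


def train_stage3_joint(model: MTNet, dr_data: GradeData, vessel_data: SegData,
                       cfg: TrainConfig,
                       monitor: Optional[tuple[GradeData, SegData]] = None,
                       log: Optional[list[StepLog]] = None,
                       freeze_shared: bool = False,
                       stage: Union[int, str] = 3) -> Checkpoint:
    """Stage 3: joint training with strict DR-then-vessel batch alternation.

    Each optimization step computes the grading loss on one retinopathy
    batch and the vessel loss on one vessel batch, backpropagates their sum
    once, and updates every unfrozen group.
    """
    if len(dr_data) == 0 or len(vessel_data) == 0:
        raise ValueError("both datasets must be non-empty")
    if model.head is None or model.decoder is None:
        raise ValueError("joint training needs both branches")
    pgroups = model.parameter_groups()
    params: dict[str, Parameter] = {}
    for g, ps in pgroups.items():
        if freeze_shared and g == "shared":
            continue
        params.update(ps)
    shared_before = ({n: p.data.copy() for n, p in pgroups["shared"].items()}
                     if freeze_shared else None)
    opt = Adam(params, lr=cfg.lr_max)
    model.train(True)
    n_batches = max(math.ceil(len(dr_data) / cfg.batch_size),
                    math.ceil(len(vessel_data) / cfg.batch_size))
    best_loss = math.inf
    best_state: Optional[dict[str, np.ndarray]] = None
    step = 0
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(_epoch_fraction(epoch, cfg.epochs), cfg)
        rng_d = np.random.default_rng((cfg.seed, 30, epoch))
        rng_v = np.random.default_rng((cfg.seed, 31, epoch))
        dr_batches = _cycle_batches(len(dr_data), n_batches, cfg.batch_size, rng_d)
        v_batches = _cycle_batches(len(vessel_data), n_batches, cfg.batch_size, rng_v)
        for bi in range(n_batches):
            opt.zero_grad()
            # strict alternation: retinopathy batch first, vessel batch second
            dr_loss = _dr_loss_tensor(model, dr_data.images[dr_batches[bi]],
                                      dr_data.grades[dr_batches[bi]])
            v_loss = _seg_loss_tensor(model, vessel_data.images[v_batches[bi]],
                                      vessel_data.masks[v_batches[bi]], cfg)
            total = add(dr_loss, v_loss)
            total.backward()
            opt.step()
            step += 1
            if log is not None:
                bk = joint_loss(float(dr_loss), float(v_loss))
                log.append(StepLog(step, str(stage), opt.lr, bk.dr_ce,
                                   bk.vessel, bk.total))
        mon_dr, mon_seg = monitor if monitor is not None else (dr_data, vessel_data)
        mon = (_monitor_loss(model, mon_dr, "dr", cfg)
               + _monitor_loss(model, mon_seg, "seg", cfg))
        if mon < best_loss:
            best_loss = mon
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    if freeze_shared:
        # batch-norm statistics may drift in training mode; the freeze
        # contract is on trainable parameters
        for n, p in model.parameter_groups()["shared"].items():
            if not np.array_equal(p.data, shared_before[n]):
                raise AssertionError(f"frozen shared parameter {n} changed")
    return _make_checkpoint(model, stage, best_loss, cfg.seed)


def finetune_and_merge(joint_ckpt: Checkpoint, dr_data: GradeData,
                       vessel_data: SegData, cfg: TrainConfig,
                       monitor: Optional[tuple[GradeData, SegData]] = None,
                       log: Optional[list[StepLog]] = None) -> Checkpoint:
    """Stage 4: freeze the shared encoder from the joint checkpoint, train
    both branches, and merge all three parameter groups."""
    for g in ("shared", "branch1", "branch2"):
        if g not in joint_ckpt.weights:
            raise ValueError(f"checkpoint missing parameter group {g!r}")
    model = build_model(joint_ckpt.spec, seed=joint_ckpt.seed)
    joint_ckpt.load_into(model)
    ckpt = train_stage3_joint(model, dr_data, vessel_data, cfg,
                              monitor=monitor, log=log, freeze_shared=True,
                              stage="finetune")
    for n, arr in joint_ckpt.weights["shared"].items():
        if "running_" in n:
            continue
        if not np.array_equal(ckpt.weights["shared"][n], arr):
            raise AssertionError(f"shared weights drifted during fine-tune: {n}")
    return ckpt


def run_full_protocol(spec: ModelSpec, dr_data: GradeData, vessel_data: SegData,
                      cfg: TrainConfig,
                      monitor: Optional[tuple[GradeData, SegData]] = None,
                      log: Optional[list[StepLog]] = None
                      ) -> tuple[Checkpoint, MTNet]:
    """Stages 1-4 end to end on a randomly initialized joint model."""
    model = build_model(spec, seed=cfg.seed)
    mon_dr, mon_seg = monitor if monitor is not None else (None, None)
    train_stage1(model, dr_data, replace(cfg, stage=1), mon_dr, log)
    train_stage2(model, vessel_data, replace(cfg, stage=2), mon_seg, log)
    ckpt3 = train_stage3_joint(model, dr_data, vessel_data,
                               replace(cfg, stage=3), monitor, log)
    final = finetune_and_merge(ckpt3, dr_data, vessel_data,
                               replace(cfg, stage="finetune"), monitor, log)
    final.load_into(model)
    return final, model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_segmentation(model: MTNet, data: SegData, *,
                          threshold: float = 0.5):
    """Pooled segmentation metrics of binarized probability maps."""
    probs = model.predict_proba_map(data.images)
    counts = None
    for p, m in zip(probs, data.masks):
        c = confusion(binarize(p, threshold), m)
        counts = c if counts is None else counts + c
    return segmentation_metrics(counts)


def evaluate_grading(model: MTNet, data: GradeData) -> float:
    preds = [gp.grade for gp in model.predict_grades(data.images)]
    return grading_accuracy(preds, data.grades)
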