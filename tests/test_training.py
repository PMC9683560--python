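"""Schedule, checkpoint selection, and the staged protocol's contracts.

Training smoke tests run the tiny-width variant on 8 synthetic images at
64x64 so each stage takes seconds.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from fundusmt.losses import VesselLossConfig
from fundusmt.models import TINY, build_branch1, build_csp_unet, build_model, build_mtnet
from fundusmt.training import (Checkpoint, GradeData, SegData, StepLog,
                               TrainConfig, cosine_lr, finetune_and_merge,
                               select_best, train_stage1, train_stage2,
                               train_stage3_joint)

FAST = TrainConfig(epochs=1, batch_size=4, seed=0)


class TestCosineSchedule:
    def test_endpoints(self):
        cfg = TrainConfig()
        assert cosine_lr(0.0, cfg) == pytest.approx(1e-3)
        assert cosine_lr(1.0, cfg) == pytest.approx(2e-7)

    def test_midpoint_closed_form(self):
        assert cosine_lr(0.5, TrainConfig()) == pytest.approx(5.001e-4)

    def test_monotone_decreasing(self):
        cfg = TrainConfig()
        vals = [cosine_lr(t, cfg) for t in np.linspace(0, 1, 61)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(1.5, TrainConfig())


class TestSelectBest:
    def test_tie_keeps_earliest_epoch(self):
        hist = [(0, 3.0, {"a": 0}), (1, 2.0, {"a": 1}), (2, 2.0, {"a": 2}),
                (3, 4.0, {"a": 3})]
        assert select_best(hist)[0] == 1

    def test_monotone_decreasing_keeps_last(self):
        hist = [(i, 5.0 - i, {}) for i in range(4)]
        assert select_best(hist)[0] == 3

    def test_single_entry(self):
        assert select_best([(0, 1.0, {"w": 7})])[2] == {"w": 7}

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestTrainConfig:
    def test_yaml_round_trip(self):
        cfg = TrainConfig(epochs=5, seed=3,
                          loss_weights=VesselLossConfig(2, (1.0, 0.5)))
        back = TrainConfig.from_yaml(cfg.to_yaml())
        assert back == cfg

    def test_invalid_lr_ordering(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_max=1e-7, lr_min=1e-3)


class TestStage1(object):
    def test_one_epoch_decreases_training_loss(self, small_dr_data):
        model = build_model(build_mtnet(TINY), seed=0)
        from fundusmt.training import _dr_loss_tensor
        before = float(_dr_loss_tensor(model, small_dr_data.images,
                                       small_dr_data.grades))
        train_stage1(model, small_dr_data, replace(FAST, epochs=3))
        after = float(_dr_loss_tensor(model, small_dr_data.images,
                                      small_dr_data.grades))
        assert after < before

    def test_branch2_untouched(self, small_dr_data):
        model = build_model(build_mtnet(TINY), seed=0)
        b2_before = {n: p.data.copy()
                     for n, p in model.parameter_groups()["branch2"].items()}
        train_stage1(model, small_dr_data, FAST)
        for n, p in model.parameter_groups()["branch2"].items():
            np.testing.assert_array_equal(p.data, b2_before[n])

    def test_fixed_seed_bitwise_identical_runs(self, small_dr_data):
        logs = []
        states = []
        for _ in range(2):
            model = build_model(build_mtnet(TINY), seed=0)
            log: list[StepLog] = []
            train_stage1(model, small_dr_data, replace(FAST, epochs=2), log=log)
            logs.append([s.total for s in log])
            states.append(model.state_dict())
        assert logs[0] == logs[1]
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])

    def test_empty_data_rejected(self):
        model = build_model(build_mtnet(TINY), seed=0)
        with pytest.raises(ValueError):
            GradeData(np.zeros((0, 3, 64, 64), dtype=np.float32),
                      np.zeros(0, dtype=int))


class TestStage2:
    def test_decreases_loss_and_leaves_branch1(self, small_vessel_data):
        model = build_model(build_mtnet(TINY), seed=0)
        from fundusmt.training import _seg_loss_tensor
        cfg = replace(FAST, epochs=3)
        b1_before = {n: p.data.copy()
                     for n, p in model.parameter_groups()["branch1"].items()}
        before = float(_seg_loss_tensor(model, small_vessel_data.images,
                                        small_vessel_data.masks, cfg))
        train_stage2(model, small_vessel_data, cfg)
        after = float(_seg_loss_tensor(model, small_vessel_data.images,
                                       small_vessel_data.masks, cfg))
        assert after < before
        for n, p in model.parameter_groups()["branch1"].items():
            np.testing.assert_array_equal(p.data, b1_before[n])

    def test_single_task_model_trains_too(self, small_vessel_data):
        model = build_model(build_csp_unet(TINY), seed=1)
        ckpt = train_stage2(model, small_vessel_data, FAST)
        assert math.isfinite(ckpt.best_monitored_loss)
        assert set(ckpt.weights) == {"shared", "branch2"}


class TestStage3Joint:
    def test_logged_total_is_sum_of_parts(self, small_dr_data,
                                          small_vessel_data):
        model = build_model(build_mtnet(TINY), seed=0)
        log: list[StepLog] = []
        train_stage3_joint(model, small_dr_data, small_vessel_data, FAST,
                           log=log)
        assert len(log) > 0
        for entry in log:
            assert entry.total == pytest.approx(entry.dr_ce + entry.vessel)

    def test_all_groups_update(self, small_dr_data, small_vessel_data):
        model = build_model(build_mtnet(TINY), seed=0)
        before = model.state_dict()
        train_stage3_joint(model, small_dr_data, small_vessel_data, FAST)
        changed = {g: any(not np.array_equal(p.data, before[n])
                          for n, p in ps.items())
                   for g, ps in model.parameter_groups().items()}
        assert all(changed.values())

    def test_alternation_deterministic_given_seed(self, small_dr_data,
                                                  small_vessel_data):
        totals = []
        for _ in range(2):
            model = build_model(build_mtnet(TINY), seed=0)
            log: list[StepLog] = []
            train_stage3_joint(model, small_dr_data, small_vessel_data, FAST,
                               log=log)
            totals.append([(s.dr_ce, s.vessel) for s in log])
        assert totals[0] == totals[1]

    def test_requires_both_branches(self, small_dr_data, small_vessel_data):
        seg_only = build_model(build_csp_unet(TINY), seed=0)
        with pytest.raises(ValueError):
            train_stage3_joint(seg_only, small_dr_data, small_vessel_data, FAST)


class TestFinetuneAndMerge:
    def test_shared_frozen_and_merged_checkpoint_runs(self, small_dr_data,
                                                      small_vessel_data,
                                                      tmp_path):
        model = build_model(build_mtnet(TINY), seed=0)
        ck3 = train_stage3_joint(model, small_dr_data, small_vessel_data, FAST)
        final = finetune_and_merge(ck3, small_dr_data, small_vessel_data, FAST)
        # freeze contract: shared trainable parameters bitwise unchanged
        for n, arr in ck3.weights["shared"].items():
            if "running_" not in n:
                np.testing.assert_array_equal(final.weights["shared"][n], arr)
        assert set(final.weights) == {"shared", "branch1", "branch2"}
        # merged checkpoint round-trips through disk and runs forward
        p = tmp_path / "final.npz"
        final.save(p)
        restored = Checkpoint.load(p)
        m2 = build_model(restored.spec, seed=restored.seed)
        restored.load_into(m2)
        from fundusmt.nn import Tensor
        out = m2(Tensor(small_vessel_data.images[:1]))
        assert np.isfinite(out["seg"].data).all()
        for k, arr in final.flat_weights().items():
            np.testing.assert_array_equal(restored.flat_weights()[k], arr)

    def test_missing_group_rejected(self, small_dr_data, small_vessel_data):
        model = build_model(build_csp_unet(TINY), seed=0)
        ckpt = train_stage2(model, small_vessel_data, FAST)
        with pytest.raises(ValueError, match="branch1"):
            finetune_and_merge(ckpt, small_dr_data, small_vessel_data, FAST)


class TestHardSharingConservation:
    def test_distinct_storages_match_group_totals(self, small_dr_data,
                                                  small_vessel_data):
        model = build_model(build_mtnet(TINY), seed=0)
        train_stage3_joint(model, small_dr_data, small_vessel_data, FAST)
        groups = model.parameter_groups()
        storages = {id(p.data) for g in groups.values() for p in g.values()}
        n_params = sum(len(g) for g in groups.values())
        assert len(storages) == n_params
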