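"""Training loop: schedule constants, optimization sanity, determinism,
resume behavior, EWC bookkeeping."""

import numpy as np
import pytest

from nfuse.ewc import EWCState, accumulate
from nfuse.experiments import make_exposure_task
from nfuse.losses import LossWeights, MefSsimParams
from nfuse.network import FusionNet, NetConfig
from nfuse.trainer import (
    OptState,
    TaskSpec,
    TrainConfig,
    consolidate_task,
    lr_schedule,
    run_curriculum,
    train_task,
)

MEF = MefSsimParams()


def tiny_task(seed=1, n=4):
    return make_exposure_task(seed, n_train=n, n_eval=2, size=16)


def tiny_model(seed=3):
    return FusionNet(NetConfig(base_channels=4), seed=seed)


def cfg(**kw):
    kw.setdefault("master_seed", 5)
    kw.setdefault("patch", 16)
    kw.setdefault("initial_lr", 1e-3)
    return TrainConfig(**kw)


class TestSchedule:
    @pytest.mark.parametrize(
        "iteration,expected",
        [(0, 1e-4), (49_999, 1e-4), (50_000, 5e-5), (150_000, 1.25e-5)],
    )
    def test_halving_schedule(self, iteration, expected):
        assert lr_schedule(iteration, TrainConfig()) == pytest.approx(expected, rel=1e-12)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())


class TestTrainTask:
    def test_loss_decreases_smoothed(self):
        model = tiny_model()
        trace, _ = train_task(
            model, tiny_task(), EWCState(), cfg(), iterations=60, mef_params=MEF
        )
        losses = [r["loss"] for r in trace]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_zero_ewc_weight_matches_empty_state(self):
        task = tiny_task()
        state = accumulate(
            EWCState(),
            {k: np.ones_like(p.data) for k, p in tiny_model().params.items()},
            {k: p.data.copy() for k, p in tiny_model().params.items()},
        )
        weights = LossWeights(lambda1=0.5, lambda2=0.5, lambda3=0.0, supervised=True)
        task_zero = TaskSpec(
            name=task.name, data=task.data, supervised=True, weights=weights
        )
        m1, m2 = tiny_model(), tiny_model()
        train_task(m1, task_zero, state, cfg(), iterations=8, mef_params=MEF)
        train_task(m2, task_zero, EWCState(), cfg(), iterations=8, mef_params=MEF)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_determinism_across_runs(self):
        results = []
        for _ in range(2):
            m = tiny_model()
            train_task(m, tiny_task(), EWCState(), cfg(), iterations=10, mef_params=MEF)
            results.append({k: p.data.copy() for k, p in m.params.items()})
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_resume_reproduces_uninterrupted_run(self, tmp_path):
        task = tiny_task()
        straight = tiny_model()
        _, opt = train_task(straight, task, EWCState(), cfg(), iterations=14, mef_params=MEF)

        half = tiny_model()
        _, opt_h = train_task(half, task, EWCState(), cfg(), iterations=7, mef_params=MEF)
        ckpt = tmp_path / "mid.npz"
        half.save(ckpt, extra=opt_h.arrays())
        resumed, extra = FusionNet.load(ckpt)
        opt_r = OptState.from_arrays(extra)
        _, _ = train_task(
            resumed, task, EWCState(), cfg(),
            opt_state=opt_r, start_iteration=7, iterations=14, mef_params=MEF,
        )
        for k in straight.params:
            np.testing.assert_array_equal(straight.params[k].data, resumed.params[k].data)
        for k in straight.stats:
            np.testing.assert_array_equal(straight.stats[k], resumed.stats[k])

    def test_anchor_and_importance_never_mutated(self):
        model = tiny_model()
        anchor = {k: p.data.copy() + 0.05 for k, p in model.params.items()}
        omega = {k: np.full_like(p.data, 0.5) for k, p in model.params.items()}
        state = accumulate(EWCState(), omega, anchor)
        a_before = {k: v.copy() for k, v in state.anchor.items()}
        o_before = {k: v.copy() for k, v in state.importance.items()}
        train_task(model, tiny_task(), state, cfg(), iterations=6, mef_params=MEF)
        for k in a_before:
            np.testing.assert_array_equal(state.anchor[k], a_before[k])
            np.testing.assert_array_equal(state.importance[k], o_before[k])

    def test_held_out_evaluation_cadence(self):
        model = tiny_model()
        trace, _ = train_task(
            model, tiny_task(), EWCState(), cfg(eval_every=5), iterations=10,
            mef_params=MEF,
        )
        evals = [r for r in trace if "eval_mef_ssim" in r]
        assert [r["iteration"] for r in evals] == [4, 9]
        assert all(np.isfinite(r["eval_mef_ssim"]) for r in evals)

    def test_supervised_task_without_reference_rejected(self):
        data = [{"sources": np.random.default_rng(0).uniform(size=(2, 16, 16))}]
        with pytest.raises(ValueError, match="reference"):
            TaskSpec(name="multi_focus", data=data, supervised=True)

    def test_out_of_range_ewc_weight_warns(self):
        task = tiny_task()
        spec = TaskSpec(
            name=task.name,
            data=task.data,
            supervised=True,
            weights=LossWeights(0.5, 0.5, 9e4, supervised=True),
        )
        state = accumulate(
            EWCState(),
            {k: np.zeros_like(p.data) for k, p in tiny_model().params.items()},
            {k: p.data.copy() for k, p in tiny_model().params.items()},
        )
        with pytest.warns(UserWarning, match="EWC weight"):
            train_task(tiny_model(), spec, state, cfg(), iterations=1, mef_params=MEF)


class TestCurriculum:
    def test_single_task_equals_plain_training(self):
        task = tiny_task()
        m1, m2 = tiny_model(), tiny_model()
        report = run_curriculum(m1, [task], cfg(), iterations_per_task=8, mef_params=MEF)
        train_task(m2, task, EWCState(), cfg(), iterations=8, mef_params=MEF)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)
        assert report["final_ewc_state"].tasks_seen == 1

    def test_importance_accumulates_across_tasks(self):
        t1 = tiny_task(seed=1)
        t2_raw = tiny_task(seed=2)
        t2 = TaskSpec(name="multi_focus", data=t2_raw.data, supervised=True,
                      eval_data=t2_raw.eval_data)
        model = tiny_model()
        report = run_curriculum(
            model, [t1, t2], cfg(), iterations_per_task=6, mef_params=MEF
        )
        s1, s2 = report["ewc_states"]
        assert s1.tasks_seen == 1 and s2.tasks_seen == 2
        # omega from task 2 alone is the difference; it must be non-negative
        for k in s1.importance:
            diff = s2.importance[k] - s1.importance[k]
            assert (diff >= -1e-15).all()
        # the final anchor is the final parameter vector
        for k in model.params:
            np.testing.assert_array_equal(s2.anchor[k], model.params[k].data)

    def test_stage_reports_cover_all_tasks(self):
        t1 = tiny_task(seed=4)
        report = run_curriculum(tiny_model(), [t1], cfg(), iterations_per_task=4,
                                mef_params=MEF)
        stages = [s["stage"] for s in report["stages"]]
        assert stages == ["initial", "after_multi_exposure"]
        assert all("multi_exposure" in s["scores"] for s in report["stages"])

    def test_empty_curriculum_rejected(self):
        with pytest.raises(ValueError):
            run_curriculum(tiny_model(), [], cfg())


class TestConsolidate:
    def test_consolidation_anchors_current_parameters(self):
        model = tiny_model()
        task = tiny_task()
        state = consolidate_task(model, task, EWCState(), cfg(), MEF)
        assert state.tasks_seen == 1
        for k, p in model.params.items():
            np.testing.assert_array_equal(state.anchor[k], p.data)
            assert (state.importance[k] >= 0).all()
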