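"""Distillation loss, the skip-removal schedule, and skip clipping."""

import numpy as np
import pytest

from picocall.arch import build_network, chain_spec
from picocall.distill import (DistillConfig, kd_loss, remove_skip,
                              run_skip_removal, skip_removal_schedule)
from picocall.nn import ctc_loss
from picocall.training import TrainConfig, ctc_train, evaluate_chunks


def random_logprobs(rng, N, T, C=5):
    lp = rng.normal(size=(N, T, C))
    return lp - np.log(np.exp(lp).sum(axis=-1, keepdims=True))


class TestKDLoss:
    def test_identical_logits_reduce_to_weighted_ctc(self):
        rng = np.random.default_rng(0)
        lp = random_logprobs(rng, 2, 6)
        targets = [np.array([1, 2]), np.array([3])]
        cfg = DistillConfig(alpha=0.9, tau=2.0)
        ctc_val, _, _ = ctc_loss(lp, targets, want_grad=False)
        assert kd_loss(lp, lp, targets, cfg) == pytest.approx(0.1 * ctc_val)

    def test_alpha_zero_is_pure_ctc(self):
        rng = np.random.default_rng(1)
        s, t = random_logprobs(rng, 1, 5), random_logprobs(rng, 1, 5)
        targets = [np.array([2, 4])]
        cfg = DistillConfig(alpha=0.0, tau=2.0)
        ctc_val, _, _ = ctc_loss(s, targets, want_grad=False)
        assert kd_loss(s, t, targets, cfg) == pytest.approx(ctc_val)

    def test_two_frame_hand_computed_value(self):
        # KL of temperature-softened distributions computed from first
        # principles for two fixed 2-frame logit matrices at tau=2
        s = np.log(np.array([[[0.7, 0.1, 0.1, 0.05, 0.05],
                              [0.2, 0.5, 0.1, 0.1, 0.1]]]))
        t = np.log(np.array([[[0.5, 0.2, 0.1, 0.1, 0.1],
                              [0.1, 0.6, 0.1, 0.1, 0.1]]]))
        tau, alpha = 2.0, 0.9
        kl_sum = 0.0
        for f in range(2):
            ps = np.exp(s[0, f] / tau) / np.exp(s[0, f] / tau).sum()
            pt = np.exp(t[0, f] / tau) / np.exp(t[0, f] / tau).sum()
            kl_sum += float((pt * np.log(pt / ps)).sum())
        targets = [np.array([1])]
        cfg = DistillConfig(alpha=alpha, tau=tau)
        ctc_val, _, _ = ctc_loss(s, targets, want_grad=False)
        expected = alpha * tau ** 2 * kl_sum / 2 + (1 - alpha) * ctc_val
        assert kd_loss(s, t, targets, cfg) == pytest.approx(expected)

    def test_lower_bounded_by_weighted_ctc(self):
        rng = np.random.default_rng(2)
        cfg = DistillConfig(alpha=0.9, tau=2.0)
        for _ in range(10):
            s, t = random_logprobs(rng, 1, 5), random_logprobs(rng, 1, 5)
            targets = [np.array([1])]
            ctc_val, _, _ = ctc_loss(s, targets, want_grad=False)
            assert kd_loss(s, t, targets, cfg) >= (1 - cfg.alpha) * ctc_val - 1e-12

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            kd_loss(random_logprobs(rng, 1, 4), random_logprobs(rng, 1, 5),
                    [np.array([1])], DistillConfig())


class TestSchedule:
    def test_paper_stride_arithmetic(self):
        assert skip_removal_schedule(5, 1).completion_epoch == 5
        assert skip_removal_schedule(5, 3).completion_epoch == 15

    def test_single_block_stride_two(self):
        sched = skip_removal_schedule(1, 2)
        assert sched.events == [(2, 0)]

    def test_completion_epoch_exhaustive(self):
        for n_blocks in range(17):
            for stride in range(1, 9):
                sched = skip_removal_schedule(n_blocks, stride)
                assert sched.completion_epoch == n_blocks * stride
                assert [b for _, b in sched.events] == list(range(n_blocks))
                assert [e for e, _ in sched.events] == \
                    [stride * (i + 1) for i in range(n_blocks)]


def skip_student(seed=9):
    return build_network(chain_spec([16, 24, 24], kernel=9, skip=True,
                                    layers_per_block=2), seed=seed)


class TestRemoveSkip:
    def test_projection_parameters_dropped_exactly(self):
        net = build_network(chain_spec([8, 16], kernel=3, skip=True,
                                       layers_per_block=1), seed=0)
        # chain_spec puts a skip on block 1 whose channels change 8 -> 16
        res = net.residual_blocks()[0]
        proj_params = sum(p.value.size for p in res.proj.parameters())
        before = net.param_count()
        remove_skip(net, 0)
        assert before - net.param_count() == proj_params
        assert proj_params > 0

    def test_all_skips_removed_reports_zero(self):
        net = skip_student()
        n = net.active_skips()
        for i in range(n):
            remove_skip(net, i)
        assert net.active_skips() == 0
        with pytest.raises((IndexError, RuntimeError)):
            remove_skip(net, 0)

    def test_forward_finite_after_removal(self):
        net = skip_student()
        remove_skip(net, 0)
        out = net.forward(np.zeros((1, 60)))
        assert np.all(np.isfinite(out))

    def test_spec_accounting_follows_removal(self):
        from picocall.arch import param_count
        net = build_network(chain_spec([8, 16], kernel=3, skip=True), seed=0)
        before = param_count(net.spec)
        remove_skip(net, 0)
        assert param_count(net.spec) == net.param_count() < before


@pytest.fixture(scope="module")
def skip_teacher(tiny_task):
    teacher = build_network(chain_spec([16, 24, 24], kernel=9, skip=True,
                                       layers_per_block=2), seed=3)
    ctc_train(teacher, tiny_task["dataset"],
              TrainConfig(epochs=8, batch_size=32, seed=5))
    return teacher


class TestRunSkipRemoval:
    def test_stride_one_clears_skips_by_schedule(self, tiny_task, skip_teacher):
        student = skip_student()
        n_skips = student.active_skips()
        cfg = DistillConfig(skip_stride=1, total_epochs=n_skips + 2, seed=2)
        ds = tiny_task["dataset"].subset(np.arange(192))
        result = run_skip_removal(student, skip_teacher, ds, cfg, val_chunks=32)
        assert student.active_skips() == 0
        assert result.removal_epochs == list(range(1, n_skips + 1))
        assert len(result.accuracy_trajectory) == cfg.total_epochs

    def test_skip_free_student_is_plain_distillation(self, tiny_task,
                                                     skip_teacher):
        student = build_network(chain_spec([16, 24, 24], kernel=9), seed=1)
        cfg = DistillConfig(skip_stride=1, total_epochs=2, seed=2)
        ds = tiny_task["dataset"].subset(np.arange(96))
        result = run_skip_removal(student, skip_teacher, ds, cfg, val_chunks=16)
        assert result.removal_epochs == []
        assert student.active_skips() == 0

    def test_clipped_student_close_to_skip_bearing_twin(self, tiny_task,
                                                        skip_teacher):
        """Paired-seed run: clipping skips under distillation costs at most a
        couple of identity points versus keeping them."""
        ds = tiny_task["dataset"].subset(np.arange(256))
        epochs = 16  # removals at epochs 1-2, then a long recovery phase
        clipped = skip_student(seed=9)
        run_skip_removal(clipped, skip_teacher, ds,
                     DistillConfig(skip_stride=1, total_epochs=epochs, seed=2),
                     train_cfg=TrainConfig(epochs=epochs, batch_size=32,
                                           seed=2),
                     val_chunks=16)
        kept = skip_student(seed=9)
        ctc_train(kept, ds, TrainConfig(epochs=epochs, batch_size=32, seed=2),
                  teacher=skip_teacher,
                  distill_cfg=DistillConfig(skip_stride=1, seed=2))
        acc_clipped = evaluate_chunks(clipped, tiny_task["dataset"],
                                      max_chunks=96)["median_identity"]
        acc_kept = evaluate_chunks(kept, tiny_task["dataset"],
                                   max_chunks=96)["median_identity"]
        assert acc_clipped >= acc_kept - 2.0
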