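"""Stride-scheduled skip-connection removal under knowledge distillation.

Skip connections are hardware-unfriendly: they extend activation lifetimes
and, when channel counts differ, add projection parameters.  Rather than
training a skip-free network from scratch (which converges poorly), a
skip-bearing teacher guides a student while the student's skip connections
are removed one block at a time, every ``skip_stride`` epochs, in ascending
block order; training continues after the last removal so the student can
recover.  The distillation loss blends temperature-softened KL against the
teacher with the CTC term:

    loss = alpha * tau^2 * KL(soften(teacher) || soften(student))
         + (1 - alpha) * CTC(student, targets)

with alpha=0.9 and tau=2 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .arch import Network
from .io import SignalChunkSet
from .nn import ctc_loss
from .training import TrainConfig, _kd_grad, ctc_train, evaluate_chunks


@dataclass
class DistillConfig:
    alpha: float = 0.9
    tau: float = 2.0
    skip_stride: int = 1
    total_epochs: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.skip_stride < 1:
            raise ValueError("skip_stride must be >= 1")


@dataclass
class SkipSchedule:
    """Removal events: skip of ``block_index`` goes at ``epoch_index``."""
    events: List[Tuple[int, int]] = field(default_factory=list)
    n_blocks: int = 0

    @property
    def completion_epoch(self) -> int:
        return self.events[-1][0] if self.events else 0


def skip_removal_schedule(n_blocks: int, stride: int) -> SkipSchedule:
    """One removal every ``stride`` epochs, blocks in ascending order.

    Completion epoch is ``n_blocks * stride`` (5 blocks at stride 1 finish at
    epoch 5; at stride 3 at epoch 15).
    """
    if n_blocks < 0 or stride < 1:
        raise ValueError("need n_blocks >= 0 and stride >= 1")
    return SkipSchedule(events=[(stride * (i + 1), i) for i in range(n_blocks)],
                        n_blocks=n_blocks)


def kd_loss(student_logp: np.ndarray, teacher_logp: np.ndarray,
            targets, cfg: DistillConfig) -> float:
    """Distillation loss value for a batch of per-frame log-probabilities.

    The KL term is computed per frame between the temperature-softened class
    distributions (teacher as reference) and averaged over frames; it is zero
    iff the softened distributions agree frame-wise, so the loss is bounded
    below by ``(1 - alpha) * CTC``.
    """
    student_logp = np.asarray(student_logp, dtype=np.float64)
    teacher_logp = np.asarray(teacher_logp, dtype=np.float64)
    if student_logp.shape != teacher_logp.shape:
        raise ValueError("student and teacher outputs must share shape")
    _, kd_val = _kd_grad(student_logp, teacher_logp, cfg)
    ctc_val, _, _ = ctc_loss(student_logp, targets, want_grad=False)
    return kd_val + (1.0 - cfg.alpha) * ctc_val


def remove_skip(network: Network, block_index: int) -> Network:
    """Drop the skip connection (and any projection) of one residual block.

    The block index counts residual blocks only.  Removing a projection
    strictly decreases the live parameter count; removing an identity skip
    leaves it unchanged.  The network's spec is updated in step so size
    accounting stays consistent.
    """
    blocks = network.residual_blocks()
    if not 0 <= block_index < len(blocks):
        raise IndexError(f"no residual block {block_index}")
    blocks[block_index].remove_skip()
    # mirror into the spec: clear the skip flag of the matching spec block
    ri = -1
    for bspec, built in zip(network.spec.blocks, network.blocks):
        if built is blocks[block_index]:
            bspec.skip = False
            break
    return network


@dataclass
class SkipRemovalResult:
    student: Network
    accuracy_trajectory: List[float] = field(default_factory=list)
    removal_epochs: List[int] = field(default_factory=list)


def run_skip_removal(student: Network, teacher: Network,
                 dataset: SignalChunkSet, cfg: DistillConfig,
                 train_cfg: Optional[TrainConfig] = None,
                 val_dataset: Optional[SignalChunkSet] = None,
                 val_chunks: int = 64) -> SkipRemovalResult:
    """Distill ``teacher`` into ``student`` while clipping its skips.

    Follows :func:`skip_removal_schedule`: after epoch ``stride * i`` the
    i-th remaining residual block loses its skip; fine-tuning continues to
    ``cfg.total_epochs``.  Returns the skip-free student and its per-epoch
    validation identity.
    """
    if teacher.spec.decimation != student.spec.decimation:
        raise ValueError("teacher and student must share the frame rate")
    schedule = skip_removal_schedule(student.active_skips(), cfg.skip_stride)
    events = dict(schedule.events)
    train_cfg = train_cfg or TrainConfig(epochs=cfg.total_epochs, seed=cfg.seed)
    train_cfg.epochs = max(cfg.total_epochs, schedule.completion_epoch)
    val = val_dataset if val_dataset is not None else dataset
    result = SkipRemovalResult(student=student)

    def on_epoch(epoch: int, net: Network) -> None:
        if epoch in events:
            remove_skip(net, events[epoch])
            result.removal_epochs.append(epoch)
        acc = evaluate_chunks(net, val, max_chunks=val_chunks)
        result.accuracy_trajectory.append(acc["median_identity"])

    ctc_train(student, dataset, train_cfg, teacher=teacher, distill_cfg=cfg,
              epoch_callback=on_epoch)
    return result
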