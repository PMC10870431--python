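"""CTC training with optional knowledge distillation.

The optimizer is AdamW with the defaults used throughout the package:
learning rate 2e-3, second-moment coefficient 0.999 (first moment at the
conventional 0.9), weight decay 0.01, epsilon 1e-8, batch size 64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .arch import ALPHABET, Network
from .io import SignalChunkSet
from .nn import AdamW, ctc_loss
from .pipeline import greedy_decode
from .accuracy import read_identity


@dataclass
class TrainConfig:
    learning_rate: float = 2e-3
    beta: float = 0.999          # second-moment coefficient
    weight_decay: float = 0.01
    epsilon: float = 1e-8
    batch_size: int = 64
    epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "beta", "weight_decay", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


@dataclass
class TrainResult:
    network: Network
    losses: List[float] = field(default_factory=list)  # mean loss per epoch
    val_accuracy: List[float] = field(default_factory=list)


def _targets(dataset: SignalChunkSet, idx) -> List[np.ndarray]:
    # stored labels are 0..3; CTC classes reserve 0 for blank
    return [dataset.labels_for(int(i)).astype(np.int64) + 1 for i in idx]


def ctc_train(network: Network, dataset: SignalChunkSet, cfg: TrainConfig,
              teacher: Optional[Network] = None,
              distill_cfg=None,
              epoch_callback: Optional[Callable[[int, Network], None]] = None,
              ) -> TrainResult:
    """Minimize CTC loss (plus a distillation term when a teacher is given).

    ``epoch_callback(epoch, network)`` runs after each epoch — the
    skip-removal schedule hooks in here.  With ``epochs=0`` the network is
    returned untouched.
    """
    if teacher is not None and distill_cfg is None:
        from .distill import DistillConfig
        distill_cfg = DistillConfig()
    opt = AdamW(network.parameters(), lr=cfg.learning_rate,
                beta2=cfg.beta, eps=cfg.epsilon,
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    result = TrainResult(network=network)
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = dataset.signals[idx].astype(np.float64)
            targets = _targets(dataset, idx)
            logp = network.forward(x, train=True)
            loss, grad, _ = ctc_loss(logp, targets)
            if teacher is not None:
                t_logp = teacher.forward(x, train=False)
                kd_grad, kd_val = _kd_grad(logp, t_logp, distill_cfg)
                grad = (1.0 - distill_cfg.alpha) * grad + kd_grad
                loss = (1.0 - distill_cfg.alpha) * loss + kd_val
            opt.zero_grad()
            network.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        result.losses.append(float(np.mean(epoch_losses)))
        if epoch_callback is not None:
            epoch_callback(epoch + 1, network)
    return result


def _kd_grad(student_logp: np.ndarray, teacher_logp: np.ndarray, cfg):
    """Gradient and value of the temperature-softened KL term.

    KL(teacher || student) per frame with distributions softened at
    temperature tau, averaged over all frames, scaled by alpha * tau**2 (the
    standard correction keeping gradient magnitude comparable across
    temperatures).
    """
    tau, alpha = cfg.tau, cfg.alpha
    ps = _soften(student_logp, tau)
    pt = _soften(teacher_logp, tau)
    n_frames = student_logp.shape[0] * student_logp.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.where(pt > 0, pt * (np.log(pt) - np.log(ps)), 0.0)
    val = alpha * tau ** 2 * float(kl.sum() / n_frames)
    grad = alpha * tau * (ps - pt) / n_frames
    return grad, val


def _soften(logp: np.ndarray, tau: float) -> np.ndarray:
    z = logp / tau
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def evaluate_chunks(network: Network, dataset: SignalChunkSet,
                    max_chunks: Optional[int] = None,
                    batch_size: int = 64) -> dict:
    """Greedy-decode chunks and align against their ground-truth labels.

    Returns median/mean percent identity over the evaluated chunks; the
    desk-scale proxy for read accuracy used inside training loops.
    """
    n = len(dataset) if max_chunks is None else min(max_chunks, len(dataset))
    idents = []
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        logp = network.forward(dataset.signals[idx].astype(np.float64),
                               train=False)
        for row, i in enumerate(idx):
            truth = "".join(ALPHABET[b] for b in dataset.labels_for(int(i)))
            called, _ = greedy_decode(logp[row])
            if not truth:
                continue
            idents.append(read_identity(called, truth) if called else 0.0)
    return {"median_identity": float(np.median(idents)) if idents else 0.0,
            "mean_identity": float(np.mean(idents)) if idents else 0.0,
            "n": len(idents)}
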