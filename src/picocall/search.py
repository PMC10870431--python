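"""Quantization-aware differentiable architecture search.

The search space follows the full-scale layout of this package's networks:
``n_groups`` channel-size groups with ``repeats`` decision layers each.  A
decision layer chooses among grouped-conv candidates — every kernel-size
option crossed with every weight/activation bit-width pair — plus an identity
operator that effectively deletes the layer.  With 10 kernels, 4 bit-width
pairs and the identity over 5x4 = 20 layers the space holds 41^20 ~ 1.8e32
configurations.

The search trains a supernet: each decision layer computes the softmax-
weighted mixture of its candidates' outputs (quantization variants of one
kernel share the underlying convolution weights and differ only in their
fake-quantization wrappers).  Network weights and architecture logits are
updated alternately on disjoint halves of the search subset, minimizing

    CTC(mixture) + lambda_hw * expected_cost(logits)

where the expected cost is the softmax-weighted candidate cost, normalized
by the all-max configuration.  The discrete architecture is read off by
per-layer argmax (ties: lowest cost, then smallest kernel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .arch import (ALPHABET_SIZE, ArchitectureSpec, BlockSpec, KERNEL_OPTIONS,
                   LayerSpec, Network, QUANT_OPTIONS, QuantSpec, build_network)
from .io import SignalChunkSet
from .nn import (ActQuant, AdamW, BatchNorm1d, Conv1d, Identity, LogSoftmax,
                 Module, Param, ReLU, Residual, Sequential, ctc_loss,
                 unique_params)
from .training import TrainConfig


# ---------------------------------------------------------------------------
# Space and config
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    n_groups: int = 5
    repeats: int = 4
    kernel_options: Tuple[int, ...] = KERNEL_OPTIONS
    quant_options: Tuple[Tuple[int, int], ...] = QUANT_OPTIONS
    channel_options: Tuple[int, ...] = (16, 24, 32, 48, 64)
    include_identity: bool = True
    stem_kernel: int = 9
    stem_stride: int = 1

    def __post_init__(self):
        if len(self.channel_options) != self.n_groups:
            raise ValueError("need one channel size per group")

    @property
    def n_layers(self) -> int:
        return self.n_groups * self.repeats

    @property
    def n_candidates(self) -> int:
        return (len(self.kernel_options) * len(self.quant_options)
                + (1 if self.include_identity else 0))

    def candidates(self) -> List[Tuple]:
        """Per-layer candidate descriptors, identity (if any) last."""
        cands: List[Tuple] = [("conv", k, q) for k in self.kernel_options
                              for q in self.quant_options]
        if self.include_identity:
            cands.append(("identity",))
        return cands

    def group_of(self, layer: int) -> int:
        return layer // self.repeats


def search_space_size(space: SearchSpace) -> int:
    """Exact cardinality: (kernels x quants + identity) ** decision layers."""
    return space.n_candidates ** space.n_layers


@dataclass
class SearchConfig:
    lambda_hw: float = 0.6
    search_chunks: int = 30_000
    epochs: int = 5
    seed: int = 0
    train: TrainConfig = field(default_factory=lambda: TrainConfig(batch_size=16))
    arch_lr: float = 3e-3

    def __post_init__(self):
        if self.lambda_hw < 0:
            raise ValueError("lambda_hw must be >= 0")


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

@dataclass
class CostModel:
    """Per-candidate hardware cost (analytic BOPs or a measured table).

    ``matrix[l, c]`` is the cost of candidate ``c`` at decision layer ``l``;
    identity costs 0.  ``normalizer`` is the all-max configuration cost.
    """
    mode: str
    matrix: np.ndarray
    normalizer: float

    @classmethod
    def analytic_bops(cls, space: SearchSpace, ref_frames: int = 1000) -> "CostModel":
        """BOPs of each candidate on a reference frame count."""
        cands = space.candidates()
        matrix = np.zeros((space.n_layers, len(cands)))
        for l in range(space.n_layers):
            ch = space.channel_options[space.group_of(l)]
            for ci, cand in enumerate(cands):
                if cand[0] == "identity":
                    continue
                _, kernel, (wb, ab) = cand
                matrix[l, ci] = ref_frames * ch * ch * kernel * wb * ab
        return cls(mode="analytic_bops", matrix=matrix,
                   normalizer=_all_max(matrix))

    @classmethod
    def from_table(cls, space: SearchSpace,
                   table: Dict[Tuple, float]) -> "CostModel":
        """Costs keyed by (kind, kernel, channels, wbits, abits)."""
        cands = space.candidates()
        matrix = np.zeros((space.n_layers, len(cands)))
        for l in range(space.n_layers):
            ch = space.channel_options[space.group_of(l)]
            for ci, cand in enumerate(cands):
                if cand[0] == "identity":
                    continue
                _, kernel, (wb, ab) = cand
                matrix[l, ci] = float(table[("conv", kernel, ch, wb, ab)])
        if np.any(matrix < 0):
            raise ValueError("costs must be >= 0")
        return cls(mode="latency_table", matrix=matrix,
                   normalizer=_all_max(matrix))


def _all_max(matrix: np.ndarray) -> float:
    total = float(matrix.max(axis=1).sum())
    return total if total > 0 else 1.0


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def expected_cost(arch_logits: np.ndarray, cost_model: CostModel) -> float:
    """Softmax-weighted cost summed over layers, in all-max units."""
    p = _softmax(np.asarray(arch_logits, dtype=np.float64))
    return float((p * cost_model.matrix).sum() / cost_model.normalizer)


def expected_cost_grad(arch_logits: np.ndarray, cost_model: CostModel) -> np.ndarray:
    p = _softmax(np.asarray(arch_logits, dtype=np.float64))
    c = cost_model.matrix / cost_model.normalizer
    inner = (p * c).sum(axis=1, keepdims=True)
    return p * (c - inner)


# ---------------------------------------------------------------------------
# Supernet
# ---------------------------------------------------------------------------

class MixedLayer(Module):
    """Softmax mixture of candidate operations on a fixed channel width.

    Conv candidates of the same kernel share one weight tensor; each
    quantization variant wraps it with its own fake-quant widths, batch norm
    and activation quantizer.  ``probs`` must be assigned before ``forward``;
    ``backward`` additionally records ``dots[c] = <grad_out, out_c>``, the
    ingredient of the architecture-logit gradient.
    """

    def __init__(self, space: SearchSpace, channels: int,
                 rng: np.random.Generator, name: str):
        self.space = space
        self.channels = channels
        self.cands: List[Module] = []
        for kernel in space.kernel_options:
            shared = Conv1d(channels, channels, kernel, rng=rng,
                            name=f"{name}.k{kernel}")
            for (wb, ab) in space.quant_options:
                conv = Conv1d(channels, channels, kernel, wbits=wb,
                              weight=shared.w, bias_param=shared.b,
                              name=f"{name}.k{kernel}")
                self.cands.append(Sequential(
                    [conv, BatchNorm1d(channels, name=f"{name}.k{kernel}.bn"),
                     ReLU(), ActQuant(ab)]))
        if space.include_identity:
            self.cands.append(Identity())
        self.probs: Optional[np.ndarray] = None
        self.dots: Optional[np.ndarray] = None
        self._outs = None

    def parameters(self):
        for c in self.cands:
            yield from c.parameters()

    def forward(self, x, train=True):
        outs = [c.forward(x, train=train) for c in self.cands]
        self._outs = outs
        y = np.zeros_like(outs[0])
        for p, o in zip(self.probs, outs):
            if p > 0:
                y += p * o
        return y

    def backward(self, gy):
        self.dots = np.array([float((gy * o).sum()) for o in self._outs])
        gx = np.zeros_like(gy)
        for p, c in zip(self.probs, self.cands):
            gx += c.backward(p * gy)
        return gx


class Supernet:
    """Stem -> grouped decision layers (identity-skip per group) -> head."""

    def __init__(self, space: SearchSpace, seed: int = 0):
        self.space = space
        rng = np.random.default_rng(seed)
        ch0 = space.channel_options[0]
        self.stem = Sequential([
            Conv1d(1, ch0, space.stem_kernel, stride=space.stem_stride,
                   rng=rng, name="stem"),
            BatchNorm1d(ch0, name="stem.bn"), ReLU()])
        self.mixed: List[MixedLayer] = []
        self.trunk: List[Module] = [self.stem]
        prev = ch0
        for g in range(space.n_groups):
            ch = space.channel_options[g]
            if ch != prev:
                self.trunk.append(Sequential([
                    Conv1d(prev, ch, 1, rng=rng, name=f"transition{g}"),
                    BatchNorm1d(ch, name=f"transition{g}.bn"), ReLU()]))
            layers = [MixedLayer(space, ch, rng, f"group{g}.layer{r}")
                      for r in range(space.repeats)]
            self.mixed.extend(layers)
            self.trunk.append(Residual(Sequential(layers)))
            prev = ch
        self.head = Conv1d(prev, ALPHABET_SIZE, 1, rng=rng, name="head")
        self.log_softmax = LogSoftmax()

    def set_probs(self, probs: np.ndarray) -> None:
        for layer, p in zip(self.mixed, probs):
            layer.probs = p

    def forward(self, x, probs: np.ndarray, train: bool = True) -> np.ndarray:
        self.set_probs(probs)
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, None, :]
        for m in self.trunk:
            x = m.forward(x, train=train)
        x = self.head.forward(x, train=train)
        return np.transpose(self.log_softmax.forward(x, train=train), (0, 2, 1))

    def backward(self, grad_logprobs: np.ndarray) -> np.ndarray:
        gy = np.transpose(grad_logprobs, (0, 2, 1))
        gy = self.log_softmax.backward(gy)
        gy = self.head.backward(gy)
        for m in reversed(self.trunk):
            gy = m.backward(gy)
        return np.stack([l.dots for l in self.mixed])

    def parameters(self) -> List[Param]:
        out = []
        for m in self.trunk:
            out.extend(m.parameters())
        out.extend(self.head.parameters())
        return unique_params(out)

    @property
    def decimation(self) -> int:
        return self.space.stem_stride


@dataclass
class SupernetState:
    """Architecture logits plus the shared supernet weights."""
    space: SearchSpace
    arch_logits: np.ndarray
    supernet: Optional[Supernet] = None
    cost_model: Optional[CostModel] = None
    epoch: int = 0

    @classmethod
    def initial(cls, space: SearchSpace, seed: int = 0,
                cost_model: Optional[CostModel] = None) -> "SupernetState":
        return cls(space=space,
                   arch_logits=np.zeros((space.n_layers, space.n_candidates)),
                   supernet=Supernet(space, seed=seed), cost_model=cost_model)

    @property
    def probs(self) -> np.ndarray:
        return _softmax(self.arch_logits)


def supernet_loss(batch: Tuple[np.ndarray, Sequence[np.ndarray]],
                  state: SupernetState, cfg: SearchConfig) -> float:
    """CTC loss of the mixture forward pass + lambda_hw * expected cost."""
    x, targets = batch
    logp = state.supernet.forward(x, state.probs, train=True)
    loss, _, _ = ctc_loss(logp, targets, want_grad=False)
    hw = 0.0
    if state.cost_model is not None:
        hw = cfg.lambda_hw * expected_cost(state.arch_logits, state.cost_model)
    return loss + hw


# ---------------------------------------------------------------------------
# Search loop
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    state: SupernetState
    losses: List[float] = field(default_factory=list)
    logits_trajectory: List[np.ndarray] = field(default_factory=list)


def run_search(dataset: SignalChunkSet, space: SearchSpace, cfg: SearchConfig,
               cost_model: Optional[CostModel] = None) -> SearchResult:
    """Alternating bi-level optimization of weights and architecture logits.

    The search subset (up to ``cfg.search_chunks`` chunks, sampled without
    replacement) is split 50/50: network weights step on one half,
    architecture logits on the other.  Deterministic per seed up to
    floating-point reduction order.
    """
    rng = np.random.default_rng(cfg.seed)
    n = min(cfg.search_chunks, len(dataset))
    idx = rng.choice(len(dataset), size=n, replace=False)
    weight_set = dataset.subset(idx[: n // 2]) if n > 1 else dataset.subset(idx)
    arch_set = dataset.subset(idx[n // 2:]) if n > 1 else dataset.subset(idx)
    if cost_model is None:
        cost_model = CostModel.analytic_bops(space)
    state = SupernetState.initial(space, seed=cfg.seed, cost_model=cost_model)
    logit_param = Param(state.arch_logits, name="arch_logits")
    w_opt = AdamW(state.supernet.parameters(), lr=cfg.train.learning_rate,
                  beta2=cfg.train.beta, eps=cfg.train.epsilon,
                  weight_decay=cfg.train.weight_decay)
    a_opt = AdamW([logit_param], lr=cfg.arch_lr, weight_decay=0.0)
    result = SearchResult(state=state)
    bs = cfg.train.batch_size

    def batches(ds):
        order = rng.permutation(len(ds))
        for s0 in range(0, len(ds), bs):
            sel = order[s0:s0 + bs]
            yield (ds.signals[sel].astype(np.float64),
                   [ds.labels_for(int(i)).astype(np.int64) + 1 for i in sel])

    for epoch in range(cfg.epochs):
        epoch_losses = []
        for (xw, tw), (xa, ta) in zip(batches(weight_set), batches(arch_set)):
            # 1) weight step at fixed architecture distribution
            logp = state.supernet.forward(xw, state.probs, train=True)
            loss, grad, _ = ctc_loss(logp, tw)
            w_opt.zero_grad()
            state.supernet.backward(grad)
            w_opt.step()
            # 2) architecture step at fixed weights
            logp = state.supernet.forward(xa, state.probs, train=True)
            loss_a, grad_a, _ = ctc_loss(logp, ta)
            dots = state.supernet.backward(grad_a)
            p = state.probs
            ctc_logit_grad = p * (dots - (p * dots).sum(axis=1, keepdims=True))
            hw_grad = cfg.lambda_hw * expected_cost_grad(state.arch_logits,
                                                         cost_model)
            logit_param.grad[...] = ctc_logit_grad + hw_grad
            a_opt.step()
            logit_param.grad[...] = 0.0
            epoch_losses.append(
                loss_a + cfg.lambda_hw * expected_cost(state.arch_logits,
                                                       cost_model))
        state.epoch = epoch + 1
        result.losses.append(float(np.mean(epoch_losses)) if epoch_losses else
                             float("nan"))
        result.logits_trajectory.append(state.arch_logits.copy())
    return result


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def derive_architecture(state: SupernetState, space: SearchSpace,
                        cost_model: Optional[CostModel] = None,
                        ) -> ArchitectureSpec:
    """Per-layer argmax of the architecture logits -> discrete spec.

    Identity selections delete their layer.  Exact logit ties are broken by
    lowest candidate cost, then smallest kernel.  The derived network keeps
    the fixed stem, per-group channel transitions, an identity skip around
    each non-empty group, and the mandatory pointwise head.
    """
    cands = space.candidates()
    cost_model = cost_model or state.cost_model or CostModel.analytic_bops(space)
    choices = []
    for l in range(space.n_layers):
        logits = state.arch_logits[l]
        best = logits.max()
        tied = [c for c in range(len(cands)) if logits[c] == best]
        tied.sort(key=lambda c: (cost_model.matrix[l, c],
                                 cands[c][1] if cands[c][0] == "conv" else -1))
        choices.append(cands[tied[0]])

    blocks: List[BlockSpec] = []
    ch0 = space.channel_options[0]
    blocks.append(BlockSpec(layers=[LayerSpec(
        kind="conv", in_channels=1, out_channels=ch0,
        kernel=space.stem_kernel, stride=space.stem_stride)]))
    prev = ch0
    for g in range(space.n_groups):
        ch = space.channel_options[g]
        if ch != prev:
            blocks.append(BlockSpec(layers=[LayerSpec(
                kind="conv", in_channels=prev, out_channels=ch, kernel=1)]))
            prev = ch
        layers = []
        for r in range(space.repeats):
            cand = choices[g * space.repeats + r]
            if cand[0] == "identity":
                continue
            _, kernel, (wb, ab) = cand
            layers.append(LayerSpec(kind="conv", in_channels=ch,
                                    out_channels=ch, kernel=kernel,
                                    quant=QuantSpec(wb, ab)))
        if layers:
            blocks.append(BlockSpec(layers=layers, skip=True))
    spec = ArchitectureSpec(blocks=blocks)
    spec.validate()
    return spec
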