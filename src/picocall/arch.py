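"""Architecture specification, network construction, and cost accounting.

An :class:`ArchitectureSpec` is the discrete description of a convolutional
CTC basecaller: an ordered list of blocks (each a stack of grouped 1-D conv
layers, optionally wrapped by a skip connection) followed by a mandatory
pointwise head projecting to the 5-symbol alphabet (blank + A, C, G, T).
Every conv layer carries a :class:`QuantSpec` giving its weight/activation
bit-widths; 32 denotes full floating point.

Accounting conventions (documented in docs/methods.md):

* ``param_count`` sums conv weights ``(in/groups)*out*kernel``, biases, and
  batch-norm affine pairs; identity layers contribute nothing.
* ``model_size_bits`` charges every parameter of a layer at that layer's
  weight bit-width, so uniform re-quantization scales the size exactly
  (e.g. <16,16> vs fp32 is exactly 2x for any spec).  Numerically, biases and
  norm parameters are never quantized; only the accounting uses the width.
* ``bops`` charges ``MACs * wbits * abits`` per layer with
  ``MACs = frames * (in/groups) * out * kernel``; bias/norm ops are ignored.
* A skip projection (pointwise conv, present when block input and output
  channel counts differ) inherits the quantization of its block's final layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import yaml

from .nn import (ActQuant, BatchNorm1d, Conv1d, Identity, LogSoftmax, Module,
                 Param, ReLU, Residual, Sequential, unique_params)
from .nn.quant import ALLOWED_BITS

#: Kernel-size options for grouped 1-D convolutions in searched blocks.
KERNEL_OPTIONS = (3, 5, 7, 9, 25, 31, 55, 75, 115, 123)
#: Weight/activation bit-width pairs offered during architecture search.
QUANT_OPTIONS = ((8, 4), (8, 8), (16, 8), (16, 16))
ALPHABET = "ACGT"
ALPHABET_SIZE = 5  # blank + 4 bases


class SpecError(ValueError):
    """An architecture spec violates a structural invariant."""


@dataclass(frozen=True)
class QuantSpec:
    wbits: int = 32
    abits: int = 32

    def __post_init__(self):
        if self.wbits not in ALLOWED_BITS or self.abits not in ALLOWED_BITS:
            raise SpecError(f"bit-widths must be in {ALLOWED_BITS}: {self}")


FP32 = QuantSpec(32, 32)


@dataclass
class LayerSpec:
    kind: str = "conv"  # "conv" | "identity"
    in_channels: int = 1
    out_channels: int = 1
    kernel: int = 3
    groups: int = 1
    stride: int = 1
    quant: QuantSpec = FP32
    has_norm: bool = True
    has_activation: bool = True

    def validate(self, where: str = "layer", restrict_kernels: bool = True) -> None:
        if self.kind == "identity":
            if self.in_channels != self.out_channels:
                raise SpecError(f"{where}: identity layer must preserve channels")
            return
        if self.kind != "conv":
            raise SpecError(f"{where}: unknown layer kind {self.kind!r}")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise SpecError(f"{where}: kernel must be odd, got {self.kernel}")
        # kernel 1 = pointwise (transitions, projections, heads); others must
        # come from the searched option set
        if restrict_kernels and self.kernel != 1 and self.kernel not in KERNEL_OPTIONS:
            raise SpecError(
                f"{where}: kernel {self.kernel} not in {KERNEL_OPTIONS}")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise SpecError(f"{where}: groups={self.groups} must divide channels")
        if self.stride < 1:
            raise SpecError(f"{where}: stride must be >= 1")

    # -- accounting -------------------------------------------------------
    def n_weights(self) -> int:
        if self.kind == "identity":
            return 0
        return (self.in_channels // self.groups) * self.out_channels * self.kernel

    def n_params(self) -> int:
        if self.kind == "identity":
            return 0
        n = self.n_weights() + self.out_channels  # weights + bias
        if self.has_norm:
            n += 2 * self.out_channels
        return n

    def macs(self, frames_in: int) -> int:
        if self.kind == "identity":
            return 0
        frames_out = -(-frames_in // self.stride)
        return frames_out * self.n_weights()


@dataclass
class BlockSpec:
    layers: List[LayerSpec] = field(default_factory=list)
    skip: bool = False

    @property
    def in_channels(self) -> int:
        return self.layers[0].in_channels

    @property
    def out_channels(self) -> int:
        return self.layers[-1].out_channels

    def needs_projection(self) -> bool:
        return self.skip and self.in_channels != self.out_channels

    def projection_spec(self) -> Optional[LayerSpec]:
        """Pointwise channel-matching conv on the skip path, if needed."""
        if not self.needs_projection():
            return None
        q = self.layers[-1].quant if self.layers else FP32
        return LayerSpec(kind="conv", in_channels=self.in_channels,
                         out_channels=self.out_channels, kernel=1, groups=1,
                         stride=1, quant=q, has_norm=False, has_activation=False)


@dataclass
class ArchitectureSpec:
    blocks: List[BlockSpec] = field(default_factory=list)
    in_channels: int = 1
    alphabet_size: int = ALPHABET_SIZE
    head_quant: QuantSpec = FP32

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.alphabet_size != ALPHABET_SIZE:
            raise SpecError("alphabet must be blank + A,C,G,T (size 5)")
        ch = self.in_channels
        for bi, block in enumerate(self.blocks):
            if not block.layers:
                raise SpecError(f"block {bi} has no layers")
            for li, layer in enumerate(block.layers):
                where = f"block {bi} layer {li}"
                if layer.in_channels != ch:
                    raise SpecError(
                        f"{where}: expects {layer.in_channels} input channels, "
                        f"previous layer provides {ch}")
                layer.validate(where)
                ch = layer.out_channels
            if block.skip and any(l.stride != 1 for l in block.layers):
                raise SpecError(f"block {bi}: skip over strided layers unsupported")

    @property
    def out_channels(self) -> int:
        ch = self.in_channels
        for b in self.blocks:
            ch = b.out_channels if b.layers else ch
        return ch

    @property
    def decimation(self) -> int:
        d = 1
        for b in self.blocks:
            for l in b.layers:
                d *= l.stride
        return d

    def head_spec(self) -> LayerSpec:
        return LayerSpec(kind="conv", in_channels=self.out_channels,
                         out_channels=self.alphabet_size, kernel=1, groups=1,
                         quant=self.head_quant, has_norm=False,
                         has_activation=False)

    def n_skips(self) -> int:
        return sum(1 for b in self.blocks if b.skip)

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> Dict:
        return {
            "in_channels": self.in_channels,
            "alphabet_size": self.alphabet_size,
            "head_quant": list(astuple_quant(self.head_quant)),
            "blocks": [
                {"skip": b.skip,
                 "layers": [{**asdict(l), "quant": list(astuple_quant(l.quant))}
                            for l in b.layers]}
                for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "ArchitectureSpec":
        blocks = []
        for bd in d.get("blocks", []):
            layers = []
            for ld in bd.get("layers", []):
                ld = dict(ld)
                q = ld.pop("quant", [32, 32])
                layers.append(LayerSpec(quant=QuantSpec(*q), **ld))
            blocks.append(BlockSpec(layers=layers, skip=bool(bd.get("skip", False))))
        return cls(blocks=blocks,
                   in_channels=int(d.get("in_channels", 1)),
                   alphabet_size=int(d.get("alphabet_size", ALPHABET_SIZE)),
                   head_quant=QuantSpec(*d.get("head_quant", [32, 32])))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def astuple_quant(q: QuantSpec):
    return (q.wbits, q.abits)


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def _accounted_layers(spec: ArchitectureSpec):
    """Yield (name, LayerSpec) for every parameterized piece of the model."""
    for bi, block in enumerate(spec.blocks):
        for li, layer in enumerate(block.layers):
            yield f"block{bi}.layer{li}", layer
        proj = block.projection_spec()
        if proj is not None:
            yield f"block{bi}.skip_proj", proj
    yield "head", spec.head_spec()


def param_count(spec: ArchitectureSpec) -> int:
    """Total trainable parameters (conv weights + biases + norm affine)."""
    spec.validate()
    return sum(l.n_params() for _, l in _accounted_layers(spec))


def model_size_bits(spec: ArchitectureSpec) -> int:
    """Stored model size in bits: each layer's params at its weight width."""
    spec.validate()
    return sum(l.n_params() * l.quant.wbits for _, l in _accounted_layers(spec))


def layer_size_report(spec: ArchitectureSpec) -> List[Dict]:
    """Per-layer table of parameters, precisions, and stored bits."""
    spec.validate()
    rows = []
    for name, l in _accounted_layers(spec):
        rows.append({
            "layer": name,
            "kind": l.kind,
            "kernel": l.kernel if l.kind == "conv" else 0,
            "params": l.n_params(),
            "wbits": l.quant.wbits,
            "abits": l.quant.abits,
            "bits": l.n_params() * l.quant.wbits,
        })
    return rows


def bops(spec: ArchitectureSpec, input_length: int) -> int:
    """Bit operations for one forward pass over ``input_length`` samples."""
    spec.validate()
    total = 0
    frames = input_length
    for block in spec.blocks:
        frames_in_block = frames
        for layer in block.layers:
            total += layer.macs(frames) * layer.quant.wbits * layer.quant.abits
            if layer.kind == "conv":
                frames = -(-frames // layer.stride)
        proj = block.projection_spec()
        if proj is not None:
            total += proj.macs(frames_in_block) * proj.quant.wbits * proj.quant.abits
    head = spec.head_spec()
    total += head.macs(frames) * head.quant.wbits * head.quant.abits
    return total


def with_uniform_quant(spec: ArchitectureSpec, quant: QuantSpec) -> ArchitectureSpec:
    """Copy of ``spec`` with every layer (and the head) at one precision."""
    new = ArchitectureSpec.from_dict(spec.to_dict())
    for b in new.blocks:
        for l in b.layers:
            l.quant = quant
    new.head_quant = quant
    return new


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

class ConstructionError(ValueError):
    pass


class Network:
    """A built basecaller: callable stack of residual blocks plus head.

    ``forward`` maps raw signal batches ``(N, T)`` (or ``(N, C, T)``) to
    per-frame log-probabilities ``(N, T/decimation, 5)``.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        try:
            spec.validate()
        except SpecError as exc:
            raise ConstructionError(str(exc)) from exc
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.blocks: List[Module] = []
        for bi, block in enumerate(spec.blocks):
            body = Sequential([_build_layer(l, rng, f"block{bi}.layer{li}")
                               for li, l in enumerate(block.layers)])
            if block.skip:
                proj_spec = block.projection_spec()
                proj = None
                if proj_spec is not None:
                    proj = Conv1d(proj_spec.in_channels, proj_spec.out_channels,
                                  1, wbits=proj_spec.quant.wbits, rng=rng,
                                  name=f"block{bi}.skip_proj")
                self.blocks.append(Residual(body, proj))
            else:
                self.blocks.append(body)
        head = spec.head_spec()
        self.head = Conv1d(head.in_channels, head.out_channels, 1,
                           wbits=head.quant.wbits, rng=rng, name="head")
        self.log_softmax = LogSoftmax()

    # -- inference/training passes ---------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels")
        for block in self.blocks:
            x = block.forward(x, train=train)
        x = self.head.forward(x, train=train)
        x = self.log_softmax.forward(x, train=train)
        return np.transpose(x, (0, 2, 1))  # (N, T', C)

    def backward(self, grad_logprobs: np.ndarray) -> None:
        gy = np.transpose(grad_logprobs, (0, 2, 1))
        gy = self.log_softmax.backward(gy)
        gy = self.head.backward(gy)
        for block in reversed(self.blocks):
            gy = block.backward(gy)

    __call__ = forward

    # -- bookkeeping ------------------------------------------------------
    def parameters(self) -> List[Param]:
        out = []
        for block in self.blocks:
            out.extend(block.parameters())
        out.extend(self.head.parameters())
        return unique_params(out)

    def param_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def conv_weight_params(self) -> List[Param]:
        return [p for p in self.parameters() if p.prunable]

    def residual_blocks(self) -> List[Residual]:
        return [b for b in self.blocks if isinstance(b, Residual)]

    def active_skips(self) -> int:
        return sum(1 for b in self.residual_blocks() if b.active)


def _build_layer(l: LayerSpec, rng: np.random.Generator, name: str) -> Module:
    try:
        l.validate(name)
    except SpecError as exc:
        raise ConstructionError(str(exc)) from exc
    if l.kind == "identity":
        return Identity()
    mods: List[Module] = [Conv1d(l.in_channels, l.out_channels, l.kernel,
                                 stride=l.stride, groups=l.groups,
                                 wbits=l.quant.wbits, rng=rng, name=name)]
    if l.has_norm:
        mods.append(BatchNorm1d(l.out_channels, name=f"{name}.bn"))
    if l.has_activation:
        mods.append(ReLU())
    if l.quant.abits < 32:
        mods.append(ActQuant(l.quant.abits))
    return Sequential(mods)


def build_network(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Instantiate a trainable network from a validated spec."""
    return Network(spec, seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _iter_submodules(mod: Module):
    yield mod
    for attr in ("modules",):
        for sub in getattr(mod, attr, []):
            yield from _iter_submodules(sub)
    if isinstance(mod, Residual):
        yield from _iter_submodules(mod.body)
        if mod.proj is not None:
            yield from _iter_submodules(mod.proj)


def _network_modules(net: Network):
    for block in net.blocks:
        yield from _iter_submodules(block)
    yield from _iter_submodules(net.head)


def save_network(net: Network, path) -> None:
    """Checkpoint spec + parameters (+ masks, batch-norm statistics)."""
    import json
    arrays = {"__spec__": np.frombuffer(
        json.dumps(net.spec.to_dict()).encode(), dtype=np.uint8)}
    for i, p in enumerate(net.parameters()):
        arrays[f"p{i}"] = p.value
        if p.mask is not None:
            arrays[f"p{i}_mask"] = p.mask
    bn = [m for m in _network_modules(net) if isinstance(m, BatchNorm1d)]
    for i, m in enumerate(bn):
        arrays[f"bn{i}_mean"] = m.running_mean
        arrays[f"bn{i}_var"] = m.running_var
    np.savez(path, **arrays)


def load_network(path) -> Network:
    import json
    data = np.load(path)
    spec = ArchitectureSpec.from_dict(
        json.loads(bytes(data["__spec__"]).decode()))
    net = Network(spec)
    for i, p in enumerate(net.parameters()):
        p.value[...] = data[f"p{i}"]
        if f"p{i}_mask" in data:
            p.mask = data[f"p{i}_mask"]
    bn = [m for m in _network_modules(net) if isinstance(m, BatchNorm1d)]
    for i, m in enumerate(bn):
        m.running_mean[...] = data[f"bn{i}_mean"]
        m.running_var[...] = data[f"bn{i}_var"]
    return net


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------

def chain_spec(channels: List[int], kernel: int = 9, in_channels: int = 1,
               stride_first: int = 1, quant: QuantSpec = FP32,
               skip: bool = False, layers_per_block: int = 1) -> ArchitectureSpec:
    """A plain stack of conv blocks: one block per entry of ``channels``."""
    blocks = []
    ch = in_channels
    for bi, c in enumerate(channels):
        layers = []
        for li in range(layers_per_block):
            layers.append(LayerSpec(
                kind="conv", in_channels=ch, out_channels=c, kernel=kernel,
                stride=stride_first if (bi == 0 and li == 0) else 1,
                quant=quant))
            ch = c
        blocks.append(BlockSpec(layers=layers, skip=skip and bi > 0))
    return ArchitectureSpec(blocks=blocks, in_channels=in_channels)


def random_spec(rng: np.random.Generator, max_blocks: int = 4,
                max_layers: int = 3, channel_choices=(2, 4, 8, 16),
                kernels=KERNEL_OPTIONS[:4]) -> ArchitectureSpec:
    """Random valid spec; used for randomized accounting/shape checks."""
    blocks = []
    ch = 1
    for bi in range(int(rng.integers(1, max_blocks + 1))):
        layers = []
        out = int(rng.choice(channel_choices))
        for li in range(int(rng.integers(1, max_layers + 1))):
            if li > 0 and rng.random() < 0.2:
                layers.append(LayerSpec(kind="identity", in_channels=ch,
                                        out_channels=ch))
                continue
            groups = 1
            if rng.random() < 0.3:
                g = int(rng.choice([1, 2]))
                if ch % g == 0 and out % g == 0:
                    groups = g
            q = QuantSpec(*QUANT_OPTIONS[int(rng.integers(len(QUANT_OPTIONS)))]) \
                if rng.random() < 0.7 else FP32
            layers.append(LayerSpec(
                kind="conv", in_channels=ch, out_channels=out,
                kernel=int(rng.choice(kernels)), groups=groups,
                stride=1, quant=q, has_norm=bool(rng.random() < 0.8)))
            ch = out
        skip = bool(rng.random() < 0.4) and all(
            l.stride == 1 for l in layers)
        blocks.append(BlockSpec(layers=layers, skip=skip))
    return ArchitectureSpec(blocks=blocks)
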