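"""Synthetic nanopore squiggle generation.

The simulator emulates the statistical structure the basecalling task
assumes: a pore model assigns each k-mer an expected current level; a read's
signal visits the levels of consecutive k-mer windows, dwelling a random
number of samples on each (geometric by default — memoryless, ONT-like
variability; or deterministic), with additive Gaussian noise.  Signals are
then median/MAD-normalized and chunked exactly as the basecalling pipeline
does, and each chunk is labelled with the bases whose dwell interval it fully
contains, which is the supervision the CTC loss consumes.

It deliberately does not model pore physics (stray current, adapter stalls,
RNA) — see docs/methods.md for what this implies for the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import ALPHABET
from .io import SignalChunkSet
from .pipeline import ChunkingConfig, chunk_signal, normalize_signal

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Desk-scale default k-mer length (256 levels); real ONT pores blur ~6.
DEFAULT_K = 4


class EmptyDatasetError(ValueError):
    """No read produced a single usable chunk."""


@dataclass
class PoreModel:
    """Expected current level per k-mer, drawn i.i.d. N(0, level_spread)."""
    k: int
    level_array: np.ndarray  # 4**k levels, base-4 lexicographic k-mer order
    level_spread: float
    seed: int

    def __post_init__(self):
        self.level_array = np.asarray(self.level_array, dtype=np.float64)
        if not 1 <= self.k <= 8:
            raise ValueError(f"k must be in [1, 8], got {self.k}")
        if self.level_array.shape != (4 ** self.k,):
            raise ValueError("pore model needs exactly 4**k levels")

    @property
    def levels(self) -> Dict[str, float]:
        """k-mer string -> level mapping (built on demand)."""
        kmers = ("".join(t) for t in itertools.product(ALPHABET, repeat=self.k))
        return {kmer: float(v) for kmer, v in zip(kmers, self.level_array)}


@dataclass
class SimParams:
    dwell_mean: float = 5.0
    dwell_law: str = "geometric"  # "geometric" (min 1) or "fixed"
    noise_sd: float = 0.25
    read_length_law: Union[int, Tuple[str, int, int]] = ("uniform", 800, 1200)
    seed: int = 0

    def __post_init__(self):
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 sample per base")
        if self.dwell_law not in ("geometric", "fixed"):
            raise ValueError(f"unknown dwell law {self.dwell_law!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    signal: np.ndarray
    base_boundaries: np.ndarray  # per-k-mer-window start index into signal

    def validate(self) -> None:
        b = self.base_boundaries
        if len(b) and (np.any(np.diff(b) <= 0) or b[-1] >= len(self.signal)):
            raise ValueError("base boundaries must strictly increase within signal")


def make_pore_model(k: int, level_spread: float, seed: int) -> PoreModel:
    """Draw one level per k-mer i.i.d. from N(0, level_spread)."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    rng = np.random.default_rng(seed)
    levels = rng.normal(0.0, level_spread, size=4 ** k)
    return PoreModel(k=k, level_array=levels, level_spread=level_spread, seed=seed)


def generate_reference(length: int, gc_fraction: float, seed: int) -> str:
    """I.i.d. bases with P(G)+P(C) = gc_fraction, split evenly."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
         (1 - gc_fraction) / 2]
    idx = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


def encode_bases(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT character {exc}") from exc


def kmer_indices(sequence: str, k: int) -> np.ndarray:
    """Base-4 codes of the consecutive k-mer windows of ``sequence``."""
    enc = encode_bases(sequence)
    if len(enc) < k:
        raise ValueError(f"sequence shorter than k={k}")
    win = sliding_window_view(enc, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    return win @ powers


def _draw_dwells(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.dwell_law == "fixed":
        return np.full(n, max(1, int(round(params.dwell_mean))), dtype=np.int64)
    return rng.geometric(1.0 / params.dwell_mean, size=n).astype(np.int64)


def simulate_read(sequence: str, pore_model: PoreModel, params: SimParams,
                  read_id: str = "read", rng: Optional[np.random.Generator] = None,
                  ) -> SimulatedRead:
    """Emit the squiggle of one read.

    Each k-mer window contributes ``dwell`` consecutive samples at its pore
    level plus Gaussian noise; ``base_boundaries`` records where each window
    starts in the signal.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    codes = kmer_indices(sequence, pore_model.k)
    dwells = _draw_dwells(len(codes), params, rng)
    levels = pore_model.level_array[codes]
    signal = np.repeat(levels, dwells)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=len(signal))
    boundaries = np.concatenate(([0], np.cumsum(dwells)[:-1]))
    read = SimulatedRead(read_id=read_id, sequence=sequence, signal=signal,
                         base_boundaries=boundaries)
    read.validate()
    return read


def _read_length(law, rng: np.random.Generator) -> int:
    if isinstance(law, int):
        return law
    kind = law[0]
    if kind == "fixed":
        return int(law[1])
    if kind == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    raise ValueError(f"unknown read length law {law!r}")


def chunk_labels(read: SimulatedRead, start: int, end: int) -> np.ndarray:
    """Base indices (0..3) whose dwell interval lies inside [start, end).

    A base belongs to a chunk iff its boundary sample lies in the chunk and
    its dwell ends inside it; partially covered edge bases are dropped so the
    supervision at chunk edges is unambiguous.
    """
    b = read.base_boundaries
    ends = np.concatenate((b[1:], [len(read.signal)]))
    keep = (b >= start) & (ends <= end)
    enc = encode_bases(read.sequence)[:len(b)]  # first base of each window
    return enc[keep]


def simulate_dataset(n_reads: int, pore_model: PoreModel, params: SimParams,
                     chunking: ChunkingConfig, gc_fraction: float = 0.5,
                     seed: Optional[int] = None) -> SignalChunkSet:
    """Simulate, normalize, chunk and label a full training dataset.

    Reads whose signal is shorter than one chunk are dropped (padding is an
    inference-time device, not training supervision); if every read is
    dropped an :class:`EmptyDatasetError` is raised.
    """
    if n_reads < 1:
        raise EmptyDatasetError("n_reads must be >= 1")
    master = np.random.default_rng(params.seed if seed is None else seed)
    signals, labels, offsets, read_ids, intervals = [], [], [0], [], []
    for ri in range(n_reads):
        read_seed = int(master.integers(2 ** 31))
        rng = np.random.default_rng(read_seed)
        length = _read_length(params.read_length_law, rng)
        seq = generate_reference(length, gc_fraction, int(rng.integers(2 ** 31)))
        read = simulate_read(seq, pore_model, params,
                             read_id=f"read{ri:05d}", rng=rng)
        if len(read.signal) < chunking.chunk:
            continue
        norm = normalize_signal(read.signal)
        for (s, e) in chunk_signal(norm, chunking):
            lab = chunk_labels(read, s, e)
            if len(lab) == 0:
                continue
            signals.append(norm[s:e])
            labels.append(lab)
            offsets.append(offsets[-1] + len(lab))
            read_ids.append(read.read_id)
            intervals.append((s, e))
    if not signals:
        raise EmptyDatasetError(
            "no chunks produced; chunk size exceeds every simulated signal")
    return SignalChunkSet(
        signals=np.asarray(signals, dtype=np.float32),
        labels=np.concatenate(labels).astype(np.int8),
        offsets=np.asarray(offsets, dtype=np.int64),
        read_ids=list(read_ids),
        intervals=np.asarray(intervals, dtype=np.int64),
        metadata={
            "k": pore_model.k,
            "pore_seed": pore_model.seed,
            "level_spread": pore_model.level_spread,
            "chunk": chunking.chunk,
            "overlap": chunking.overlap,
            "dwell_mean": params.dwell_mean,
            "dwell_law": params.dwell_law,
            "noise_sd": params.noise_sd,
            "seed": params.seed if seed is None else seed,
            "normalization": "median/1.4826*MAD per read",
        })


def simulate_reads(n_reads: int, pore_model: PoreModel, params: SimParams,
                   gc_fraction: float = 0.5,
                   seed: Optional[int] = None) -> List[SimulatedRead]:
    """Raw (un-normalized, un-chunked) reads for pipeline-level evaluation."""
    master = np.random.default_rng(params.seed if seed is None else seed)
    out = []
    for ri in range(n_reads):
        rng = np.random.default_rng(int(master.integers(2 ** 31)))
        length = _read_length(params.read_length_law, rng)
        seq = generate_reference(length, gc_fraction, int(rng.integers(2 ** 31)))
        out.append(simulate_read(seq, pore_model, params,
                                 read_id=f"read{ri:05d}", rng=rng))
    return out
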