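"""End-to-end signal-to-sequence inference.

A raw squiggle is median/MAD-normalized, cut into fixed-size overlapping
chunks (4000 samples with 500 overlap by default), pushed through the
network, and the per-chunk frame matrices are stitched back in frame space —
each chunk keeps the frames covering its half of every overlap — before a
single CTC decode produces the read sequence.  Greedy (best-path) and prefix
beam-search decoders are provided; beam search is the default at inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .arch import ALPHABET

BLANK = 0
_BASES = np.array(list(ALPHABET))


@dataclass
class ChunkingConfig:
    chunk: int = 4000
    overlap: int = 500

    def __post_init__(self):
        if not 0 <= self.overlap < self.chunk:
            raise ValueError(f"need 0 <= overlap < chunk, got {self}")


@dataclass
class BasecallResult:
    read_id: str
    sequence: str
    qualities: np.ndarray  # Phred-scaled, one per base
    decode_method: str
    intervals: List[Tuple[int, int]] = field(default_factory=list)


def normalize_signal(raw: np.ndarray) -> np.ndarray:
    """Center by the median and scale by 1.4826*MAD (robust z-score).

    A zero MAD (constant stretches dominating the read) leaves the scale at 1
    and emits a warning rather than dividing by zero.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(raw)
    mad = np.median(np.abs(raw - med))
    scale = 1.4826 * mad
    if scale == 0.0:
        warnings.warn("signal MAD is zero; normalizing with unit scale")
        scale = 1.0
    return (raw - med) / scale


def chunk_signal(signal: np.ndarray, cfg: ChunkingConfig) -> List[Tuple[int, int]]:
    """Half-open sample intervals covering the signal.

    Starts advance by ``chunk - overlap``; the final window is anchored to end
    exactly at the signal end.  A signal shorter than one chunk yields a
    single short interval (the extraction step pads it).
    """
    n = len(signal)
    if n < 1:
        raise ValueError("cannot chunk an empty signal")
    intervals: List[Tuple[int, int]] = []
    pos = 0
    while True:
        end = pos + cfg.chunk
        if end >= n:
            intervals.append((max(0, n - cfg.chunk), n))
            break
        intervals.append((pos, end))
        pos += cfg.chunk - cfg.overlap
    return intervals


def extract_chunks(signal: np.ndarray, intervals: Sequence[Tuple[int, int]],
                   cfg: ChunkingConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Stack chunk windows into an (n, chunk) matrix, zero-padding short ones.

    Returns the matrix and the per-chunk count of valid (un-padded) samples.
    """
    out = np.zeros((len(intervals), cfg.chunk))
    valid = np.zeros(len(intervals), dtype=np.int64)
    for i, (s, e) in enumerate(intervals):
        seg = signal[s:e]
        out[i, :len(seg)] = seg
        valid[i] = len(seg)
    return out, valid


# ---------------------------------------------------------------------------
# CTC decoding
# ---------------------------------------------------------------------------

def _phred(p_err: np.ndarray) -> np.ndarray:
    p_err = np.clip(p_err, 1e-9, 1.0 - 1e-12)
    return np.minimum(np.round(-10.0 * np.log10(p_err)), 90).astype(np.int64)


def greedy_decode(log_probs: np.ndarray) -> Tuple[str, np.ndarray]:
    """Best-path decoding: frame argmax, collapse repeats, drop blanks.

    Per-base quality is the Phred-scaled posterior of the frame where each
    base run begins.
    """
    log_probs = np.asarray(log_probs)
    if log_probs.ndim != 2 or log_probs.shape[1] < 2:
        raise ValueError("log_probs must be (frames, classes)")
    path = np.argmax(log_probs, axis=1)
    probs = np.exp(log_probs[np.arange(len(path)), path])
    bases, quals = [], []
    prev = BLANK
    for t, c in enumerate(path):
        if c != BLANK and c != prev:
            bases.append(ALPHABET[c - 1])
            quals.append(probs[t])
        prev = c
    return "".join(bases), _phred(1.0 - np.asarray(quals, dtype=np.float64))


def beam_decode(log_probs: np.ndarray, width: int = 8) -> Tuple[str, np.ndarray]:
    """CTC prefix beam search.

    Tracks the most probable label prefixes, accumulating blank-ending and
    non-blank-ending probability mass separately so that paths collapsing to
    the same prefix are merged.  Returns the highest-probability prefix and
    forced-alignment Phred qualities.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    log_probs = np.asarray(log_probs)
    if log_probs.ndim != 2 or log_probs.shape[1] < 2:
        raise ValueError("log_probs must be (frames, classes)")
    T, C = log_probs.shape
    # prefix -> [log P(prefix, ends in blank), log P(prefix, ends in label)]
    beams = {(): (0.0, -np.inf)}
    for t in range(T):
        lp = log_probs[t]
        nxt: dict = {}

        def add(key, which, val):
            pb, pnb = nxt.get(key, (-np.inf, -np.inf))
            if which == 0:
                pb = np.logaddexp(pb, val)
            else:
                pnb = np.logaddexp(pnb, val)
            nxt[key] = (pb, pnb)

        for prefix, (pb, pnb) in beams.items():
            total = np.logaddexp(pb, pnb)
            add(prefix, 0, total + lp[BLANK])            # extend with blank
            if prefix:
                add(prefix, 1, pnb + lp[prefix[-1]])     # repeat last label
            for c in range(1, C):
                if prefix and c == prefix[-1]:
                    add(prefix + (c,), 1, pb + lp[c])    # needs blank between
                else:
                    add(prefix + (c,), 1, total + lp[c])
        ranked = sorted(nxt.items(),
                        key=lambda kv: -np.logaddexp(kv[1][0], kv[1][1]))
        beams = dict(ranked[:width])
    best = max(beams.items(), key=lambda kv: np.logaddexp(kv[1][0], kv[1][1]))[0]
    seq = "".join(ALPHABET[c - 1] for c in best)
    if not seq:
        return "", np.zeros(0, dtype=np.int64)
    frames = forced_alignment_frames(log_probs, best)
    probs = np.exp(log_probs[frames, list(best)])
    return seq, _phred(1.0 - probs)


def forced_alignment_frames(log_probs: np.ndarray,
                            labels: Sequence[int]) -> np.ndarray:
    """Viterbi-align a label sequence to the frames; return emission frames.

    Used to attach per-base confidences to beam-search calls: each base's
    quality is read from the frame where the most probable consistent path
    first enters that base's state.
    """
    T, C = log_probs.shape
    L = len(labels)
    ext = np.full(2 * L + 1, BLANK, dtype=np.int64)
    ext[1::2] = labels
    S = len(ext)
    skip_ok = np.zeros(S, dtype=bool)
    skip_ok[2:] = (ext[2:] != BLANK) & (ext[2:] != ext[:-2])
    v = np.full((T, S), -np.inf)
    ptr = np.zeros((T, S), dtype=np.int8)
    v[0, 0] = log_probs[0, ext[0]]
    if S > 1:
        v[0, 1] = log_probs[0, ext[1]]
    for t in range(1, T):
        stay = v[t - 1]
        step = np.concatenate(([-np.inf], v[t - 1, :-1]))
        skip = np.concatenate(([-np.inf, -np.inf], v[t - 1, :-2]))
        skip = np.where(skip_ok, skip, -np.inf)
        cands = np.stack([stay, step, skip])
        choice = np.argmax(cands, axis=0)
        v[t] = cands[choice, np.arange(S)] + log_probs[t, ext]
        ptr[t] = choice
    s = S - 1 if L == 0 or v[T - 1, S - 1] >= v[T - 1, S - 2] else S - 2
    states = np.empty(T, dtype=np.int64)
    for t in range(T - 1, -1, -1):
        states[t] = s
        s = int(s) - int(ptr[t, s])
    frames = np.zeros(L, dtype=np.int64)
    seen = set()
    for t, s in enumerate(states):
        if s % 2 == 1 and s not in seen:
            frames[(s - 1) // 2] = t
            seen.add(s)
    return frames


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch(chunk_frames: Sequence[np.ndarray],
           intervals: Sequence[Tuple[int, int]],
           cfg: ChunkingConfig,
           decimation: int = 1,
           valid_samples: Optional[Sequence[int]] = None) -> np.ndarray:
    """Merge per-chunk frame matrices into one frame matrix for the read.

    Operates in frame space before decoding: for every pair of neighbouring
    chunks the cut is placed at the midpoint of their actual sample overlap,
    so each chunk contributes the frames nearest its own center; the first and
    last chunks keep their outer flanks.  Padded frames (short final chunk)
    are dropped first.
    """
    if len(chunk_frames) != len(intervals):
        raise ValueError("one frame matrix per interval is required")
    if not chunk_frames:
        return np.zeros((0, 5))
    pieces = []
    n = len(intervals)
    for i, (frames, (s, e)) in enumerate(zip(chunk_frames, intervals)):
        frames = np.asarray(frames)
        if valid_samples is not None:
            n_valid = -(-int(valid_samples[i]) // decimation)
            frames = frames[:n_valid]
        span = e - s
        expected = -(-span // decimation)
        if frames.shape[0] < min(expected, 1):
            raise ValueError(f"chunk {i}: frame count inconsistent with interval")
        lo = s if i == 0 else (intervals[i - 1][1] + s) // 2
        hi = e if i == n - 1 else (e + intervals[i + 1][0]) // 2
        f_lo = max(0, math.ceil((lo - s) / decimation))
        f_hi = min(frames.shape[0], math.ceil((hi - s) / decimation))
        pieces.append(frames[f_lo:f_hi])
    return np.concatenate(pieces, axis=0)


# ---------------------------------------------------------------------------
# Read-level driver
# ---------------------------------------------------------------------------

def basecall_signal(network, signal: np.ndarray, cfg: ChunkingConfig,
                    read_id: str = "read", decoder: str = "beam",
                    beam_width: int = 8,
                    normalize: bool = True) -> BasecallResult:
    """Normalize, chunk, forward, stitch and decode one raw read."""
    if decoder not in ("greedy", "beam"):
        raise ValueError(f"unknown decoder {decoder!r}")
    x = normalize_signal(signal) if normalize else np.asarray(signal, dtype=float)
    intervals = chunk_signal(x, cfg)
    mat, valid = extract_chunks(x, intervals, cfg)
    logp = network.forward(mat, train=False)  # (n, frames, 5)
    dec = network.spec.decimation
    merged = stitch(list(logp), intervals, cfg, decimation=dec,
                    valid_samples=valid)
    if decoder == "greedy":
        seq, quals = greedy_decode(merged)
    else:
        seq, quals = beam_decode(merged, width=beam_width)
    return BasecallResult(read_id=read_id, sequence=seq, qualities=quals,
                          decode_method=decoder, intervals=intervals)


def basecall_reads(network, reads, cfg: ChunkingConfig, decoder: str = "beam",
                   beam_width: int = 8) -> List[BasecallResult]:
    """Basecall an iterable of ``(read_id, raw_signal)`` pairs."""
    return [basecall_signal(network, sig, cfg, read_id=rid, decoder=decoder,
                            beam_width=beam_width)
            for rid, sig in reads]


def basecall_file(network, reads, cfg: ChunkingConfig, out_path,
                  fmt: str = "fastq", decoder: str = "beam",
                  beam_width: int = 8) -> List[BasecallResult]:
    """Basecall reads and write a FASTA or FASTQ file; returns the calls."""
    from . import io as pio
    results = basecall_reads(network, reads, cfg, decoder=decoder,
                             beam_width=beam_width)
    if fmt == "fasta":
        pio.write_fasta([(r.read_id, r.sequence) for r in results], out_path)
    elif fmt == "fastq":
        pio.write_fastq([(r.read_id, r.sequence, r.qualities) for r in results],
                        out_path)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return results
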