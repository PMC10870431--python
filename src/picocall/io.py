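"""Readers and writers for the formats every stage touches.

FASTA/FASTQ go through Biopython.  The internal training currency — the
:class:`SignalChunkSet` of normalized signal chunks with aligned ground-truth
base labels — is stored as an HDF5 archive of named arrays plus a JSON
metadata string, so it round-trips losslessly and is inspectable with
standard HDF5 tooling.  Writers are deterministic (timestamp tracking off);
readers validate the invariants of what they construct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to its expected format."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[Tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs; empty file -> empty list."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
                break
    try:
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(records: Sequence[Tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=str(rid), description="")
            for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Sequence[Tuple[str, str, Sequence[int]]], path) -> None:
    """Write (id, sequence, phred_qualities) triplets (offset-33 encoding)."""
    recs = []
    for rid, seq, quals in records:
        quals = list(np.asarray(quals, dtype=int))
        if len(quals) != len(seq):
            raise ValueError(f"{rid}: quality length differs from sequence")
        rec = SeqRecord(Seq(seq), id=str(rid), description="")
        rec.letter_annotations["phred_quality"] = quals
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# SignalChunkSet
# ---------------------------------------------------------------------------

@dataclass
class SignalChunkSet:
    """Normalized signal chunks with aligned ground-truth base labels.

    ``signals`` is (N, T); ``labels`` is the flattened per-chunk base-index
    vector (values 0..3 for A,C,G,T) delimited by ``offsets`` (length N+1);
    ``intervals`` holds each chunk's half-open sample interval in its source
    read; ``read_ids`` names the source read of every chunk.
    """
    signals: np.ndarray
    labels: np.ndarray
    offsets: np.ndarray
    read_ids: List[str]
    intervals: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = self.signals.shape[0]
        if self.offsets.shape != (n + 1,):
            raise FormatError("offsets must have one entry per chunk plus one")
        if np.any(np.diff(self.offsets) < 0) or self.offsets[0] != 0:
            raise FormatError("offsets must be non-decreasing from zero")
        if self.offsets[-1] != len(self.labels):
            raise FormatError("offsets do not span the label vector")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() > 3):
            raise FormatError("labels must be base indices in {0,1,2,3}")
        if len(self.read_ids) != n or self.intervals.shape != (n, 2):
            raise FormatError("per-chunk arrays disagree on chunk count")

    def __len__(self) -> int:
        return self.signals.shape[0]

    @property
    def chunk_length(self) -> int:
        return self.signals.shape[1]

    def labels_for(self, i: int) -> np.ndarray:
        return self.labels[self.offsets[i]:self.offsets[i + 1]]

    def label_list(self) -> List[np.ndarray]:
        return [self.labels_for(i) for i in range(len(self))]

    def subset(self, indices) -> "SignalChunkSet":
        indices = np.asarray(indices)
        labs = [self.labels_for(int(i)) for i in indices]
        offsets = np.concatenate(([0], np.cumsum([len(l) for l in labs])))
        return SignalChunkSet(
            signals=self.signals[indices],
            labels=(np.concatenate(labs) if labs else
                    np.zeros(0, dtype=self.labels.dtype)),
            offsets=offsets.astype(np.int64),
            read_ids=[self.read_ids[int(i)] for i in indices],
            intervals=self.intervals[indices],
            metadata=dict(self.metadata))


def write_signals(reads: Sequence[Tuple[str, np.ndarray]], path) -> None:
    """Store raw per-read signals (variable length) for later basecalling."""
    with h5py.File(path, "w", track_order=False) as fh:
        grp = fh.create_group("reads")
        for rid, sig in reads:
            grp.create_dataset(str(rid), data=np.asarray(sig, dtype=np.float32),
                               track_times=False)


def read_signals(path) -> List[Tuple[str, np.ndarray]]:
    try:
        with h5py.File(path, "r") as fh:
            if "reads" not in fh:
                raise FormatError(f"{path}: missing group 'reads'")
            return [(rid, fh["reads"][rid][...].astype(np.float64))
                    for rid in sorted(fh["reads"])]
    except OSError as exc:
        raise FormatError(f"{path}: not a readable signal archive ({exc})") from exc


_CHUNKSET_ARRAYS = ("signals", "labels", "offsets", "intervals")


def write_chunkset(chunkset: SignalChunkSet, path) -> None:
    chunkset.validate()
    with h5py.File(path, "w", track_order=False) as fh:
        for name in _CHUNKSET_ARRAYS:
            fh.create_dataset(name, data=getattr(chunkset, name),
                              track_times=False)
        ids = np.array(chunkset.read_ids, dtype=h5py.string_dtype())
        fh.create_dataset("read_ids", data=ids, track_times=False)
        fh.attrs["metadata"] = json.dumps(chunkset.metadata, sort_keys=True)


def read_chunkset(path) -> SignalChunkSet:
    try:
        with h5py.File(path, "r") as fh:
            arrays = {}
            for name in _CHUNKSET_ARRAYS + ("read_ids",):
                if name not in fh:
                    raise FormatError(f"{path}: missing array {name!r}")
                arrays[name] = fh[name][...]
            metadata = json.loads(fh.attrs.get("metadata", "{}"))
    except OSError as exc:
        raise FormatError(f"{path}: not a readable chunk archive ({exc})") from exc
    read_ids = [s.decode() if isinstance(s, bytes) else str(s)
                for s in arrays.pop("read_ids")]
    return SignalChunkSet(read_ids=read_ids, metadata=metadata, **arrays)
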