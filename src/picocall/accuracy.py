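"""Alignment-based read accuracy.

Read accuracy is the fraction of alignment columns that are exact base
matches, with insertions and deletions counted in the denominator, reported
as a percentage.  Alignment is global (Needleman-Wunsch) with unit match
score and configurable mismatch/gap penalties; reads long enough that the
full dynamic program would be wasteful fall back to a banded variant centred
on the main diagonal.  Tie-breaking is deterministic: match > mismatch >
deletion > insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

NEG = -1e30
_FULL_DP_LIMIT = 10_000  # switch to banded above this length


@dataclass
class Alignment:
    """Global alignment as an operation string over '=', 'X', 'I', 'D'.

    'I' consumes a read base absent from the reference (insertion), 'D' a
    reference base absent from the read (deletion).
    """
    ops: str
    score: float

    @property
    def matches(self) -> int:
        return self.ops.count("=")

    @property
    def columns(self) -> int:
        return len(self.ops)


def align(read: str, reference: str, match: float = 1.0,
          mismatch: float = -1.0, gap: float = -1.0,
          band: Optional[int] = None) -> Alignment:
    """Globally align ``read`` against ``reference``."""
    if not read or not reference:
        raise ValueError("cannot align empty sequences")
    n, m = len(read), len(reference)
    if band is None:
        band = max(n, m) if max(n, m) <= _FULL_DP_LIMIT else abs(n - m) + 256
    band = max(band, abs(n - m) + 1)
    a = np.frombuffer(read.encode(), dtype=np.uint8)
    b = np.frombuffer(reference.encode(), dtype=np.uint8)

    # banded H storage: row i covers columns [lo[i], hi[i]]
    centers = np.round(np.arange(n + 1) * (m / n)).astype(np.int64)
    lo = np.maximum(0, centers - band)
    hi = np.minimum(m, centers + band)
    width = int((hi - lo).max()) + 1
    H = np.full((n + 1, width), NEG)
    H[0, :hi[0] - lo[0] + 1] = (np.arange(lo[0], hi[0] + 1)) * gap

    for i in range(1, n + 1):
        js = np.arange(lo[i], hi[i] + 1)

        # previous-row values at requested columns (NEG outside its band)
        def prev_at(cols):
            vals = np.full(len(cols), NEG)
            ok = (cols >= lo[i - 1]) & (cols <= hi[i - 1])
            vals[ok] = H[i - 1, cols[ok] - lo[i - 1]]
            return vals

        up = prev_at(js)
        diag = prev_at(js - 1)
        sub = np.where(a[i - 1] == b[js - 1], match, mismatch)
        # j = 0 column (only when in band): H[i,0] = i*gap
        cand = np.maximum(diag + sub, up + gap)
        if js[0] == 0:
            cand[0] = i * gap
        # left moves within the row: H[i,j] = max_k<=j (cand[k] + (j-k)*gap)
        shifted = np.maximum.accumulate(cand - js * gap)
        row = shifted + js * gap
        H[i, :len(js)] = row
        if len(js) < width:
            H[i, len(js):] = NEG

    def cell(i, j):
        if j < lo[i] or j > hi[i]:
            return NEG
        return H[i, j - lo[i]]

    # traceback with deterministic preference: = > X > D > I
    ops: List[str] = []
    i, j = n, m
    score = cell(n, m)
    tol = 1e-9
    while i > 0 or j > 0:
        h = cell(i, j)
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if abs(cell(i - 1, j - 1) + s - h) <= tol:
                ops.append("=" if a[i - 1] == b[j - 1] else "X")
                i, j = i - 1, j - 1
                continue
        if j > 0 and abs(cell(i, j - 1) + gap - h) <= tol:
            ops.append("D")
            j -= 1
            continue
        if i > 0 and abs(cell(i - 1, j) + gap - h) <= tol:
            ops.append("I")
            i -= 1
            continue
        raise RuntimeError("alignment traceback left the band; increase band")
    return Alignment(ops="".join(reversed(ops)), score=float(score))


def identity(alignment: Alignment) -> float:
    """Percent identity: 100 * matches / alignment columns (incl. indels)."""
    if alignment.columns == 0:
        return 0.0
    return 100.0 * alignment.matches / alignment.columns


def read_identity(read: str, reference: str, **kw) -> float:
    return identity(align(read, reference, **kw))


@dataclass
class AccuracyReport:
    per_read: Dict[str, Optional[float]] = field(default_factory=dict)
    median_identity: float = float("nan")
    mean_identity: float = float("nan")
    aligned_fraction: float = 0.0
    n_reads: int = 0
    metadata: Dict = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "median_identity": self.median_identity,
            "mean_identity": self.mean_identity,
            "aligned_fraction": self.aligned_fraction,
            "n_reads": self.n_reads,
            "per_read": self.per_read,
            "metadata": self.metadata,
        }


def evaluate_run(basecalls: Sequence, references: Mapping[str, str],
                 min_identity: float = 50.0,
                 metadata: Optional[Dict] = None) -> AccuracyReport:
    """Align each basecalled read to its reference and summarize.

    ``basecalls`` holds objects with ``read_id``/``sequence`` attributes (or
    ``(id, seq)`` pairs).  Reads whose id has no reference, with an empty
    call, or falling below ``min_identity`` count as unaligned; the
    median/mean are over aligned reads only.
    """
    report = AccuracyReport(metadata=dict(metadata or {}))
    idents: List[float] = []
    for bc in basecalls:
        rid, seq = (bc.read_id, bc.sequence) if hasattr(bc, "read_id") else bc
        ref = references.get(rid)
        if not ref or not seq:
            report.per_read[rid] = None
            continue
        ident = read_identity(seq, ref)
        if ident < min_identity:
            report.per_read[rid] = None
            continue
        report.per_read[rid] = ident
        idents.append(ident)
    report.n_reads = len(report.per_read)
    report.aligned_fraction = (len(idents) / report.n_reads
                               if report.n_reads else 0.0)
    if idents:
        report.median_identity = float(np.median(idents))
        report.mean_identity = float(np.mean(idents))
    return report
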