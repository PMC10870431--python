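"""Connectionist temporal classification loss (forward-backward, log space).

The alphabet is ``blank + bases``; index 0 is the blank.  ``ctc_loss`` takes
per-frame log-probabilities (the network output already passes through
log-softmax, so gradients returned here are w.r.t. those log-probabilities)
and a list of integer label sequences, and returns the mean negative
log-likelihood plus its gradient.  The recursion is vectorized over the batch
and loops only over time.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

NEG_INF = -np.inf


class CTCInfeasibleError(ValueError):
    """Raised when a label cannot be emitted within the available frames."""


def min_frames(label: np.ndarray) -> int:
    """Minimum CTC path length for a label: length + adjacent repeats."""
    label = np.asarray(label)
    if label.size == 0:
        return 0
    return int(label.size + np.sum(label[1:] == label[:-1]))


def _extended(labels: Sequence[np.ndarray], blank: int) -> Tuple[np.ndarray, np.ndarray]:
    """Stack blank-interleaved labels into (N, S_max) plus state counts."""
    S = np.array([2 * len(l) + 1 for l in labels])
    ext = np.full((len(labels), S.max() if len(S) else 1), blank, dtype=np.int64)
    for i, l in enumerate(labels):
        ext[i, 1:2 * len(l):2] = l
    return ext, S


def ctc_loss(log_probs: np.ndarray,
             labels: Sequence[np.ndarray],
             blank: int = 0,
             want_grad: bool = True,
             ) -> Tuple[float, Optional[np.ndarray], np.ndarray]:
    """Mean CTC negative log-likelihood over a batch.

    Parameters
    ----------
    log_probs : (N, T, C) array of per-frame log-probabilities.
    labels : length-N sequence of 1-D integer arrays (values != blank).

    Returns
    -------
    loss : float — mean over the batch.
    grad : (N, T, C) gradient of the mean loss w.r.t. ``log_probs`` (or None).
    per_sample : (N,) individual negative log-likelihoods.
    """
    log_probs = np.asarray(log_probs, dtype=np.float64)
    N, T, C = log_probs.shape
    labels = [np.asarray(l, dtype=np.int64) for l in labels]
    if len(labels) != N:
        raise ValueError("labels batch size does not match log_probs")
    for i, l in enumerate(labels):
        need = min_frames(l)
        if need > T:
            raise CTCInfeasibleError(
                f"chunk {i}: label needs {need} frames but only {T} are available")
    ext, S = _extended(labels, blank)
    S_max = ext.shape[1]
    n_idx = np.arange(N)[:, None]
    state_idx = np.arange(S_max)[None, :]
    valid = state_idx < S[:, None]
    # allow the s-2 transition only between distinct non-blank symbols
    skip_ok = np.zeros((N, S_max), dtype=bool)
    if S_max > 2:
        skip_ok[:, 2:] = (ext[:, 2:] != blank) & (ext[:, 2:] != ext[:, :-2])

    emit = np.take_along_axis(
        log_probs, np.broadcast_to(ext[:, None, :], (N, T, S_max)), axis=2)  # (N,T,S)

    alpha = np.full((T, N, S_max), NEG_INF)
    alpha[0, :, 0] = emit[:, 0, 0]
    has_label = S > 1
    if S_max > 1:
        alpha[0, has_label, 1] = emit[has_label, 0, 1]
    for t in range(1, T):
        prev = alpha[t - 1]
        shift1 = np.full_like(prev, NEG_INF)
        shift1[:, 1:] = prev[:, :-1]
        shift2 = np.full_like(prev, NEG_INF)
        shift2[:, 2:] = prev[:, :-2]
        shift2[~skip_ok] = NEG_INF
        acc = np.logaddexp(prev, shift1)
        acc = np.logaddexp(acc, shift2)
        alpha[t] = np.where(valid, acc + emit[:, t, :], NEG_INF)

    last = alpha[T - 1, n_idx[:, 0], S - 1]
    second = np.where(S > 1, alpha[T - 1, n_idx[:, 0], np.maximum(S - 2, 0)], NEG_INF)
    logp = np.logaddexp(last, second)
    per_sample = -logp
    loss = float(per_sample.mean())
    if not want_grad:
        return loss, None, per_sample

    beta = np.full((T, N, S_max), NEG_INF)
    beta[T - 1, n_idx[:, 0], S - 1] = emit[n_idx[:, 0], T - 1, S - 1]
    if S_max > 1:
        beta[T - 1, has_label, S[has_label] - 2] = \
            emit[has_label, T - 1, S[has_label] - 2]
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1]
        shift1 = np.full_like(nxt, NEG_INF)
        shift1[:, :-1] = nxt[:, 1:]
        shift2 = np.full_like(nxt, NEG_INF)
        shift2[:, :-2] = np.where(skip_ok[:, 2:], nxt[:, 2:], NEG_INF)
        acc = np.logaddexp(nxt, shift1)
        acc = np.logaddexp(acc, shift2)
        beta[t] = np.where(valid, acc + emit[:, t, :], NEG_INF)

    # state posterior excludes the doubly counted emission term
    post = alpha + beta - np.transpose(emit, (1, 0, 2)) - logp[None, :, None]
    post = np.where(np.isfinite(post), post, NEG_INF)
    grad = np.zeros_like(log_probs)
    w = np.exp(post)  # (T, N, S_max)
    w = np.where(valid[None], w, 0.0)
    for c in range(C):
        grad[:, :, c] = np.einsum("tns,ns->nt", w, (ext == c).astype(np.float64),
                                  optimize=True)
    grad *= -1.0 / N
    return loss, grad, per_sample
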