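# Methods

`picocall` is a desk-scale design kit for compact convolutional CTC
basecallers: it simulates labelled nanopore-like squiggles, trains and
compresses networks on them (bit-width-aware architecture search,
distillation-driven skip removal, one-shot L1 pruning), and runs the full
signal→sequence pipeline with alignment-based evaluation.  This note records
the models, the defaults and why they are what they are, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Squiggle simulator

A pore model assigns every k-mer over {A,C,G,T} an expected current level,
drawn i.i.d. from N(0, `level_spread`).  Levels are dimensionless: the
pipeline normalizes by median/MAD, so absolute scale carries no information.
A read's signal visits the levels of its consecutive k-mer windows; each
window emits `dwell` consecutive samples with additive N(0, `noise_sd`)
noise.  Two dwell laws are available:

* `geometric` (default) — minimum 1, mean `dwell_mean`; memoryless, which is
  the qualitatively right model for translocation variability.
* `fixed` — exactly `round(dwell_mean)` samples per base.

Defaults: k = 4 (256 levels; real pores blur ~6 bases, but 4 keeps tasks
trainable in minutes), `dwell_mean` = 5, `noise_sd` = 0.25, reads of
800–1200 bases, GC fraction 0.5.  Signals are normalized per read and cut
into chunks (default 4000 samples, 500 overlap, matching the pipeline); a
chunk's label is every base whose dwell interval lies entirely inside the
chunk's half-open sample interval — partially covered edge bases are dropped
so supervision at chunk edges is unambiguous.  Reads shorter than one chunk
are dropped from training sets (padding exists only at inference).  All
outputs are pure functions of (parameters, seed).

The simulator does **not** model pore physics: no stray current, adapter
stalls, strand jitter, context-dependent noise, or signal drift.  Passing
the synthetic benchmarks therefore demonstrates that the algorithms and the
training machinery work end to end — not that any given architecture would
reach a particular accuracy on real flow-cell data.

### The noise-free capability task

The end-to-end capability tests use a deliberately easy instance: k = 1,
`noise_sd` = 0, **fixed** dwell of 4 samples per base, 240-sample chunks
with 40 overlap.  Fixed dwell is a considered choice, not a simplification
of convenience: with memoryless (geometric) dwell, the total dwell of a
homopolymer run is the only evidence for its length, and the Bayes-optimal
guess of "r repeats vs r+1" from a negative-binomial dwell sum is wrong so
often that no decoder — however good — can exceed roughly the high-80s in
percent identity on i.i.d. sequence.  A capability test must not sit above
the identifiability ceiling of its own data, so the capability task uses the
deterministic dwell law, where run length is exactly decodable and observed
accuracy measures the network, not the noise floor.

## Network substrate

Networks are built from grouped 1-D convolutions with 'same' padding,
per-channel batch normalization (affine), ReLU, and a pointwise head
projecting to 5 classes (blank + A,C,G,T) under log-softmax.  The engine is
a compact numpy implementation with explicit manual backpropagation; AdamW
is the optimizer throughout with learning rate 2e-3, second-moment
coefficient 0.999 (first moment at the conventional 0.9), weight decay 0.01
(applied only to weight tensors), epsilon 1e-8, batch size 64.

**Fake quantization.** Quantized layers round their weights to a symmetric
uniform grid of `2^b − 1` levels spanning `[−max|w|, +max|w|]` each forward
pass (per-tensor scaling), and likewise their activations after the
nonlinearity.  Because the grid always covers the data there is no clipping,
and the straight-through estimator is exactly the identity.  Bit-widths come
from {4, 8, 16, 32}; 32 means untouched floating point.  Biases and
normalization parameters are never quantized numerically.

**CTC.** Loss and gradients use the standard log-space forward–backward
recursion over the blank-interleaved state lattice, vectorized over the
batch.  A label that cannot fit its frames (length + adjacent repeats >
frames) raises an error naming the offending chunk.

## Size, parameter and BOPs accounting

* `param_count` = conv weights `(in/groups)·out·kernel` + biases + 2·out
  per batch norm; identity layers contribute 0.
* `model_size_bits` charges **every parameter of a layer at that layer's
  weight bit-width**.  This makes uniform re-quantization scale the stored
  size exactly — <16,16> vs fp32 is exactly 2×, 8-bit weights exactly 4× —
  for any architecture.  The alternative (auxiliary parameters pinned at 32
  bits) breaks those exact ratios by an architecture-dependent epsilon; we
  prefer the convention whose invariants are checkable.  Numerically the
  auxiliary parameters remain full precision; only the accounting uses the
  layer width.
* `bops` = Σ per layer `frames · (in/groups) · out · kernel · w_bits ·
  a_bits`, ignoring accumulator width and bias/norm ops.  The formula is
  deliberately simple and documented so reported numbers are reproducible.
* Skip projections (pointwise convs inserted when a skip spans a channel
  change) inherit the quantization of their block's final layer and are
  included in all three accountings, as is the mandatory head.

## Architecture search

The search space mirrors the package's network layout: `n_groups` = 5
channel-size groups × `repeats` = 4 decision layers.  Each decision layer
picks one of: 10 kernel sizes {3,5,7,9,25,31,55,75,115,123} × 4
weight/activation bit-width pairs {<8,4>,<8,8>,<16,8>,<16,16>}, or an
identity that deletes the layer — 41 candidates, hence 41^20 ≈ 1.8×10^32
configurations (11^20 ≈ 6.7×10^20 counting operators only).  Channel sizes
per group are fixed by configuration, not searched; a fixed stem, pointwise
per-group transitions and the head sit outside the searched layers.

The search is a differentiable supernet: each decision layer outputs the
softmax-weighted sum of its candidates' outputs.  Quantization variants of
one kernel share the underlying convolution weights and differ only in their
fake-quantization wrappers, so supernet memory grows with kernels, not with
kernels × bit-widths.  The objective is

    CTC(mixture) + λ · E[cost],   λ = 0.6 by default,

where `E[cost]` is the softmax-weighted per-candidate cost normalized by the
all-max configuration, and the cost model is either analytic BOPs or a
user-supplied latency table (identity always costs 0).  Weights and
architecture logits are updated alternately on disjoint 50/50 halves of the
search subset (up to 30 000 chunks by default) — the standard bi-level
arrangement for differentiable NAS.  Discretization takes the per-layer
argmax; exact ties break toward the cheaper candidate, then the smaller
kernel; identity selections delete their layer.  The derived network keeps
an identity skip around each non-empty group.  Derived architectures are
retrained from fresh initialization rather than inheriting supernet weights.

## Skip removal under distillation

Skip connections lengthen activation lifetimes and add projection
parameters, which is why a deployment-oriented design wants them gone — but
a skip-free network trained from scratch converges poorly.  The package
therefore trains the skip-free student against a skip-bearing teacher with

    loss = α·τ²·KL(soften(teacher) ‖ soften(student)) + (1−α)·CTC,

α = 0.9, τ = 2 by default; `soften` is the temperature-scaled per-frame
class distribution, the KL uses the teacher as reference (forward KL) and is
averaged over frames, and the τ² factor is the standard correction keeping
gradient magnitude comparable across temperatures.  Removal is scheduled:
one skip every `skip_stride` epochs, ascending block order, abrupt at the
epoch boundary; five skip blocks at stride 1 are gone after epoch 5, at
stride 3 after epoch 15.  Fine-tuning continues after the last removal, and
matters: the per-epoch identity trajectory shows a sharp dip at each removal
followed by recovery, so comparisons between the clipped student and a
skip-bearing twin are made at a budget where both have converged (the tests
use stride 1 with ~14 recovery epochs on the capability task).

## Pruning

One-shot L1 pruning in two flavours, with the prunable set defined as
convolution weight tensors only (biases and normalization excluded):

* **Unstructured** — per tensor, the ⌊s·n⌋ smallest-magnitude weights are
  zeroed and frozen by a mask the optimizer re-applies after every step, so
  sparsity survives fine-tuning.  Ties break by flat index (stable sort).
  Stored-size accounting counts nonzero weights only and ignores index
  overhead, giving the closed form 1/(1−s): 6.67× at 85%, 33.33× at 97%.
* **Structured** — output channels are ranked per layer by filter L1 norm
  and the lowest ⌈s·out⌉ removed; consuming layers' inputs shrink to match,
  and the result is rebuilt as a genuinely smaller dense network carrying
  the surviving weights and batch-norm statistics.  Blocks with identity
  skips have their final layer pruned to the block's (pruned) input width so
  the addition stays well formed; skip projections follow their block's
  final-layer channel selection; grouped (groups > 1) layers are left
  unpruned.  A sparsity that would empty a layer is an error.

Sweeps report (sparsity, remaining weights, size, reduction factor,
post-fine-tune identity) per grid point; the knee is the last grid point
before the largest accuracy drop.

## Basecalling pipeline

Normalization is `(x − median) / (1.4826·MAD)` per read (zero MAD falls back
to unit scale with a warning).  Chunking starts at 0 and advances by
`chunk − overlap` (defaults 4000/500); the final window is anchored to end
at the signal end, and sub-chunk signals are zero-padded with the padding
recorded and the padded frames dropped before decoding.  Stitching operates
in frame space before decoding: the cut between neighbouring chunks is
placed at the midpoint of their actual sample overlap (rounded to the frame
grid), each chunk contributes the frames nearest its own centre, and the
concatenated frames are decoded once.  With identical frames in the overlap
this reproduces the whole-signal decode bit-exactly at decimation 1.

Decoders: greedy best-path (frame argmax, collapse repeats, drop blanks) and
CTC prefix beam search (default width 8) that merges blank- and
label-ending probability mass per prefix.  Per-base FASTQ qualities are
Phred-encoded (offset 33) posteriors taken at each base's emission frame —
for beam calls, the frame assigned by a Viterbi forced alignment of the
chosen sequence.

## Evaluation

Read accuracy is 100 × matches / alignment columns, insertions and
deletions included, from a global Needleman–Wunsch alignment with unit match
score and configurable mismatch/gap penalties (defaults −1/−1); ties break
deterministically match > mismatch > deletion > insertion.  Above 10 kb the
aligner switches to a banded variant centred on the main diagonal (band
256 + length difference).  With match score 0 the optimum coincides with
minimum edit distance, which is how the aligner is cross-checked against an
independent edit-distance library in the tests.  Run reports give per-read
identity, median/mean over aligned reads, and the aligned fraction; reads
with no matching reference, empty calls, or identity below a threshold
(default 50%) count as unaligned.  Throughput is deliberately not part of
any acceptance surface — it is hardware-bound.

## Problem sizes used by the test and acceptance suites

The suites run the capability task at desk scale as the package's chosen
study conditions: ~1000 chunks of 240 samples (120 reads), a 4-conv-layer
network (16/32/32/32 channels, kernel 9) trained 8 epochs at batch 32;
search properties use 2-group × 2-repeat spaces with 2 kernels × 2 bit-width
pairs over ≤128 chunks and 5 paired seeds; decoder exactness is checked on
1000 random ≤6-frame inputs against full enumeration.  All randomness is
seeded; training is deterministic per seed up to floating-point reduction
order (single-threaded numpy makes repeat runs bit-identical in practice).

## Known limitations

* The simulator's idealized noise model means synthetic accuracies do not
  transfer to real reads; the package's claims are about mechanism, not
  flow-cell performance.
* The numpy engine is single-threaded and desk-scale by design; paper-scale
  searches (tens of GPU-hours) are out of scope.
* Structured pruning does not prune grouped convolutions and prunes
  per-layer rather than globally.
* `beam_decode` explores label prefixes exactly but its per-base qualities
  derive from a single forced alignment, a simplification.
* Derived architectures are retrained from scratch; supernet weight
  inheritance is not implemented.
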