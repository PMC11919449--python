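# Methods

`esalign` aligns short sequencer reads to a reference genome by vector
search instead of seed-and-extend indexing. This note documents the model,
the procedure, the defaults, and the limits of what the synthetic
benchmarks can show.

## Problem setting and model

A read `r = (b̃_1 … b̃_Q)` over `{A,C,G,T}` is a noisy substring of a
reference `R` of length `N ≫ Q`. Alignment seeks the start position `q*`
minimizing a Smith–Waterman (SW) alignment score between `r` and the
substring of `R` at `q*` (we use a lower-is-better convention throughout).
Scanning `R` costs `O(NQ)`; instead the reference is sharded into
overlapping fragments `F_1, F_2, …` and the search is approximated by

    v* ≈ min_{F_j ∈ top-K retrieved} SW(r, F_j),

which is sound when (i) fragments are read-scale, not reference-scale,
(ii) the fragment set covers `R`, and (iii) `K` is much smaller than `N/Q`.
Retrieval uses a learned encoder `h(·)` mapping reads and fragments into a
shared unit sphere so that cosine distance `d = 1 − cos` acts as a
surrogate for edit similarity: for a read `r_j` originating from fragment
`F_j`, a usable encoder only has to satisfy the ordering constraint
`d(h(r_j), h(F_i)) ≥ d(h(r_j), h(F_j))` for `i ≠ j` often enough that the
true fragment lands in the top-K neighborbood.

## Encoder and contrastive training

The encoder is a pre-norm transformer (learned absolute positions, masked
mean pooling over final-layer token states, linear projection, L2
normalization). Pre-norm blocks and mean pooling were chosen because the
residual stream then carries token-level composition directly to the
pooled state, which both stabilizes optimization and gives the untrained
model a sensible starting representation. The network and its
backpropagation are implemented directly on numpy arrays; gradients are
validated against finite differences in the test suite. GELU uses the
tanh approximation, and all tensors are kept strictly in the configured
dtype (float32 by default; float64 for gradient checking).

Training is self-supervised. Each batch holds `B` positive pairs: a
fragment sliced uniformly from the genome with length `~ U([800, 2000])`
and a read sliced uniformly from within it with length `~ U([150, 500])`;
40% of reads receive substitution noise at a per-read rate drawn from
`[0.01, 0.05]`. The loss for read `r` with positive fragment `F_j` and the
other `B−1` fragments as negatives is

    l_r = −log [ e^{−d(h(r),h(F_j))/τ} / Σ_i e^{−d(h(r),h(F_i))/τ} ],

averaged over the batch, with temperature `τ = 0.05`. Reads and fragments
share weights but pass through separate forward calls, so they receive
independently sampled dropout masks (p = 0.1); within each group,
sequences are padded to the batch maximum under an attention mask.
Optimization is Adam with gradient accumulation, global-norm clipping at
1.0, and a one-cycle cosine schedule (linear warmup over the first 10% of
steps, cosine anneal to 1% of peak). The loss value `ln B` is the
uninformative baseline (all similarities equal); training quality is
probed by held-out top-1 read→fragment retrieval accuracy.

Reference-scale architecture: 6 layers, 12 heads, 1020-d projection,
10,000-token vocabulary, batch 16 with 16-step gradient accumulation.
Desk-scale profile (`EncoderConfig.small()`), used by the tests and the
acceptance runs: 2 layers, 4 heads, width 256, feed-forward width 512,
vocabulary 1024, no gradient accumulation, peak learning rate 1e-4. The
projection head stays at the reference 1020 dimensions even at desk
scale: it is nearly free to compute and retrieval degrades measurably
with a width-matched (256-d) head. The peak rate is deliberately
conservative: with `τ = 0.05` the softmax is sharp and larger rates —
even with longer warmup, heavier gradient accumulation, or a lower Adam
β₂ — collapse the embedding space toward uniformity; attention and
feed-forward output projections use residual-scaled initialization
(1/√(2·n_layers)) for the same reason. Positional encoding is learned
absolute positions (`positional="none"` is available as an ablation; it
lowers early loss but plateaus slightly worse).

## Tokenization

Byte-pair encoding over `{A,C,G,T}` with the four single bases pinned in
the vocabulary; encoding is greedy longest-match, which is deterministic
and lossless. On uniform-composition DNA, BPE effectively enumerates
k-mers by frequency, yielding ~4–5 bases per token at vocabulary 1024.
Training merges run on an integer corpus array (numba) and stop at the
vocabulary budget or when no pair repeats; the training corpus is capped
(default 500 kb) by seeded subsampling so cost is bounded on large
genomes.

## Sharding, vector store, retrieval

Fragments default to length 1250 with overlap 250 and stride 1000; a
final fragment is right-anchored at each chromosome end, so coverage is
total and every indel-free read up to the overlap length is wholly
contained in at least one fragment. For a 3 Gb reference this yields
3.0 M fragments. The store keeps one unit vector per fragment with
metadata (chromosome, 0-based start, raw sequence). Queries return the
top-K by cosine distance, either globally or — the default "diversity
prior" — top-K per chromosome, with exact ties broken by (chromosome
order, start). Backends: an exact brute-force scan, and an inverted-file
approximation (k-means coarse quantizer, `nprobe` cells scanned) for
larger stores; the exact scan is the reference behavior and the
approximate backend is validated against it.

A deterministic k-mer-profile hash encoder (counts of hashed 8-mers,
sqrt-transformed, L2-normalized) is provided alongside the learned
encoder. It requires no training and is used to exercise the
shard/search/align plumbing independently of representation learning.

## Fine alignment

Retrieved fragments are aligned with affine-gap local Smith–Waterman
under the lower-is-better scheme: match −2, mismatch +1, gap open +0.5
(charged on the first gap base), gap extension +0.1. Internally the DP
negates and scales the scheme to integers (the defaults are exact in
tenths), so scores and tie-breaking are exact integer arithmetic with no
floating-point path ambiguity. Each cell tracks the fragment column where
its local path began; on score ties the smaller origin is preferred, so
the reported fragment offset `q|F*` is deterministic. The global position
is reconstructed as `q* = q|F* + q_{F*|R}` with 0-based, half-open
coordinates everywhere (SAM output converts to 1-based at the boundary).
When reverse-complement search is enabled both orientations are aligned
and the better score kept. Alignments across the K candidates are
independent; results are identical regardless of execution order.

The normalized optimality gap of an alignment is

    d_SW = (v* − mQ) / ((n − m)Q),

0 for a perfect full-length match, with `m = −2` the match score and
`n = +1` the mismatch penalty; one extra mismatch costs `(n−m)/( (n−m)Q )
= 1/Q` of the scale, i.e. 0.004 at Q=250. Note that at the default bound
`d_SW = 2%` the formula admits up to 5 extra mismatches in a 250-base
read (15/3 with `n − m = 3`).

## Read simulation

The simulator emulates an Illumina-style error model at the level its
parameters are usually reported: per-base Phred drawn uniformly from a
configured range (error probability `10^(−phred/10)`), substitution to a
uniformly chosen different base, and position-wise Bernoulli
insertions/deletions at rates I and D. The read is built by walking the
reference from the true origin until exactly Q bases are emitted, so
every read has length Q and a well-defined 0-based forward-strand origin
`q̂*` recorded as ground truth. Empirical quality profiles, quality decay
along the read, and paired-end structure are deliberately out of scope;
consequences: simulated errors are uniform along the read, which is
slightly kinder to alignment than real MiSeq error clustering at read
ends. Reads default to the forward strand (the training recipe pairs
fragments with forward substrings); `strand_mode="both"` emits
reverse-complement reads and the aligner searches both orientations.

## Evaluation

A read is judged successful under `exact_location` if its predicted
global start is on the true chromosome (and strand, when strands are
simulated) within ±2 of `q̂*` — the slack absorbs end-of-read mutations
that shift the local alignment start — or under `d_sw_bound` if
`d_SW ≤` the bound (default 2%), which accepts perfect alignments to a
different copy of a repeat. The default criterion is their OR, with both
sub-verdicts logged per read. Recall is exact (`n_success/n_reads`) with
an exact Clopper–Pearson interval at 95% from Beta quantiles.

## Scaled study conditions

The reference-scale configuration (3 Gb genome, GPU-weeks of training)
is not this package's target; the pipeline is exercised end to end on
synthetic genomes sized for a single CPU:

- Plumbing benchmark (no learning): 500 kb repeat-free genome, 1000 pure
  250-bp reads, k-mer hash encoder, exact backend, K=5.
- Learned benchmark: 800 kb genome in two chromosomes, desk-scale encoder
  trained for 500 optimizer steps (8,000 contrastive pairs), 200
  simulated reads at Q=250, I=D=0.01, Phred [30,60], retrieval at top-50
  per chromosome, d_SW bound 2%.
- Repeat benchmark: genome with planted exact repeat copies at recorded
  positions; reads drawn from the copies probe multi-mapping behavior
  under both criteria.

The synthetic genome is uniform-composition with optionally planted exact
repeats. It reproduces the combinatorial structure of the task (scale,
noise, multi-mapping) but not the long-range compositional heterogeneity,
repeat families, or GC skew of real genomes; passing these benchmarks
shows the machinery is correct and that contrastive training produces
retrievable embeddings at this scale, not that the desk-scale model
matches a production aligner on real data.

At this training budget the learned benchmark's recall saturates in the
low-to-mid 0.9s: the remaining failures are uniform near-misses (true
fragments ranked just outside the top-50, not lost), and pushing steps,
projection width, feed-forward width, vocabulary size, positional
scheme, or batch accumulation further moves the number by at most a
point or two. Closing the remaining gap to reference-scale recall is a
matter of substantially longer training (and ultimately model width),
not of any single configuration switch.

## Numerical and degenerate-input choices

- Ambiguity codes in input FASTA are replaced at load time by seeded
  random concrete bases (count logged), keeping the alphabet strictly
  `{A,C,G,T}`.
- Chromosomes shorter than the fragment length yield one whole-chromosome
  fragment; chromosomes shorter than the read length are a simulation
  error.
- Scoring schemes must be exact multiples of 1/1000 so the integer DP is
  exact; ties anywhere in the pipeline resolve by (chromosome file order,
  position) for reproducibility.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the CLI derives per-stage child seeds from
  one global seed by stable hashing.

## Known limitations

- The numpy encoder trains at desk scale only; there is no GPU path.
- The IVF approximate backend can miss a chromosome entirely under the
  diversity prior when no probed cell contains its fragments; the exact
  backend is the default below 10^5 vectors.
- Base qualities are not used in alignment scoring.
- BPE segmentation is greedy longest-match rather than merge-order
  canonical; round-trip losslessness, not segmentation uniqueness, is the
  contract.
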