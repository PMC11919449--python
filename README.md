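# esalign

Short-read DNA alignment by embedding retrieval: a contrastively trained
transformer encoder maps reads and overlapping reference fragments into a
shared vector space, a fragment vector store answers top-K
nearest-neighbor queries, and Smith–Waterman fine alignment resolves the
exact genomic position. The package is aimed at people studying
learned sequence representations who want a complete, inspectable,
CPU-scale implementation of the embed–search–align idea: every stage —
read simulation, tokenizer and encoder training, indexing, retrieval,
alignment, evaluation — is plain Python/numpy and runs on synthetic
genomes in minutes.

## Method

A read `r = (b̃_1 … b̃_Q)` is a noisy substring of a reference `R` of
length `N ≫ Q`. Instead of scanning `R` (`O(NQ)`), the reference is cut
into fragments of length 1250 overlapping by ≥ 250 (so every read up to
250 bases is wholly contained in some fragment, and coverage is total),
and alignment is approximated over a retrieved candidate set:

    v* ≈ min_{F_j ∈ top-K} SW(r, F_j),    q* = q|F* + q_{F*|R}

where SW is affine-gap local alignment under a lower-is-better scheme
(match −2, mismatch +1, gap open +0.5, gap extend +0.1), `q|F*` is the
within-fragment offset and `q_{F*|R}` the fragment's global start.
Candidates come from cosine-distance search over fragment embeddings
`h(F)`, optionally top-K *per chromosome* (a diversity prior). The
encoder `h` is trained with an InfoNCE-style contrastive loss
(temperature τ = 0.05) on (read, fragment) pairs sliced from the genome,
with the other B−1 fragments of the batch as negatives, so that
`d(h(r_j), h(F_i)) ≥ d(h(r_j), h(F_j))` for `i ≠ j` — the only property
retrieval needs. Alignment quality per read is summarized by the
normalized optimality gap `d_SW = (v* − mQ)/((n − m)Q)`, zero for a
perfect full-length match; recall is reported with exact Clopper–Pearson
95% intervals. See `docs/methods.md` for the full account.

## Worked example

```python
import esalign
from esalign.encoder import EncoderConfig, TrainConfig, train
from esalign.evaluation import evaluate
from esalign.index import build_index, shard
from esalign.simulate import SimulatorConfig, simulate_reads
from esalign.tokenizer import train_vocab

# 1. synthetic two-chromosome genome and noisy reads with ground truth
genome, _ = esalign.generate_synthetic_genome([400_000, 400_000], seed=11)
reads = simulate_reads(genome, SimulatorConfig(
    Q=250, phred_range=(30, 60), ins_rate=0.01, del_rate=0.01,
    n_reads=200, seed=21))

# 2. tokenizer + contrastive encoder (desk-scale profile)
tok = train_vocab(list(genome.chromosomes.values()), vocab_size=1024, seed=11)
encoder, trace = train(genome, tok, EncoderConfig.small(tok.vocab_size),
                       TrainConfig(steps=500, grad_accum=1, peak_lr=1e-4, seed=11))

# 3. index the sharded genome and evaluate recall
store = build_index(shard(genome, 1250, 250), encoder, genome.names)
report, per_read = evaluate(reads, store, encoder, k=50,
                            criterion="either", d_sw_bound=0.02)
print(f"loss {sum(trace[:5])/5:.3f} -> {sum(trace[-10:])/10:.3f}; "
      f"recall {report.recall:.3f} [{report.ci[0]:.3f}, {report.ci[1]:.3f}]")
```

Output (about 15 minutes on one CPU):

```
loss 2.152 -> 0.843; recall 0.935 [0.891, 0.965]
```

The loss falls from near its uninformative starting value (ln 16 ≈ 2.77
is the all-equal-distances baseline for batch size 16) as the encoder
learns to place each read next to its source fragment; 93.5% of the 200
noisy reads are then recovered within ±2 bases of their true origin (or
within the 2% `d_SW` bound), with the bracketed exact 95% binomial
interval. The remaining misses are reads whose source fragment ranks
just outside the top-50 — at this desk scale the encoder is the
bottleneck, and recall rises with longer training. The same pipeline is available as a CLI
(`esalign simulate-genome / simulate-reads / train / build-index /
align / evaluate`), which writes FASTA/FASTQ/SAM/TSV/JSON artifacts plus
a reproducibility manifest per stage.

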