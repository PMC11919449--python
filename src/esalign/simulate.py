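"""Read simulation with Phred-governed substitutions and indel noise.

Emulates the error structure of an Illumina-style simulator: per-base
Phred qualities drawn uniformly from a configured range, substitution
probability 10^(-phred/10) per base, and position-wise Bernoulli
insertions/deletions. Indel mechanics are deliberately simple: the read
is built by walking the reference from the true origin until exactly Q
bases have been emitted, so every read has length Q and a well-defined
0-based origin q̂* on the forward reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from esalign.reference import ALPHABET, ReferenceGenome, reverse_complement

_PHRED_OFFSET = 33


@dataclass
class ReadTruth:
    chrom: str
    start: int  # 0-based origin on the forward reference
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Read:
    name: str
    seq: str
    qualities: list[int]
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qualities):
            raise ValueError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SimulatorConfig:
    """Noise model settings.

    phred_range
        Inclusive [lo, hi] range; each base's quality is uniform on it.
        The error probability of a base with quality q is 10^(-q/10).
    ins_rate / del_rate
        Per-position Bernoulli rates for inserting a random base after the
        current one, or dropping a reference base.
    strand_mode
        "forward_only" or "both" (fair coin, reverse-complemented reads).
    """

    Q: int = 250
    phred_range: tuple[int, int] = (30, 60)
    ins_rate: float = 0.0
    del_rate: float = 0.0
    n_reads: int = 1000
    seed: int = 0
    strand_mode: str = "forward_only"

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        lo, hi = self.phred_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid phred_range {self.phred_range}")
        for rate in (self.ins_rate, self.del_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("indel rates must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if self.strand_mode not in ("forward_only", "both"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")


def _noisy_read(template: str, cfg: SimulatorConfig, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Emit exactly Q bases by walking ``template`` with the noise model."""
    lo, hi = cfg.phred_range
    out: list[str] = []
    quals: list[int] = []
    i = 0
    while len(out) < cfg.Q:
        if i >= len(template):
            # deletions consumed the template buffer; pad with random bases
            base = ALPHABET[rng.integers(0, 4)]
        else:
            base = template[i]
            i += 1
            if cfg.del_rate and rng.random() < cfg.del_rate:
                continue
        q = int(rng.integers(lo, hi + 1))
        if rng.random() < 10.0 ** (-q / 10.0):
            others = ALPHABET.replace(base, "")
            base = others[rng.integers(0, 3)]
        out.append(base)
        quals.append(q)
        if cfg.ins_rate and len(out) < cfg.Q and rng.random() < cfg.ins_rate:
            out.append(ALPHABET[rng.integers(0, 4)])
            quals.append(int(rng.integers(lo, hi + 1)))
    return "".join(out), quals


def simulate_reads(genome: ReferenceGenome, cfg: SimulatorConfig) -> list[Read]:
    """Simulate reads with ground truth, deterministic under ``cfg.seed``.

    Start positions are uniform over all valid positions genome-wide
    (chromosomes weighted by their number of valid starts). The truth
    record stores the pre-noise origin on the forward strand.
    """
    rng = np.random.default_rng(cfg.seed)
    names = genome.names
    # template buffer beyond Q so deletions rarely exhaust it
    buffer = cfg.Q + max(10, int(4 * cfg.Q * cfg.del_rate) + 10)
    n_valid = []
    for name in names:
        L = len(genome.chromosomes[name])
        if L < cfg.Q:
            raise ValueError(f"chromosome {name!r} shorter than read length {cfg.Q}")
        n_valid.append(L - cfg.Q + 1)
    weights = np.asarray(n_valid, dtype=float)
    weights /= weights.sum()

    reads: list[Read] = []
    for idx in range(cfg.n_reads):
        ci = int(rng.choice(len(names), p=weights))
        chrom = names[ci]
        L = len(genome.chromosomes[chrom])
        start = int(rng.integers(0, n_valid[ci]))
        strand = "+"
        if cfg.strand_mode == "both" and rng.random() < 0.5:
            strand = "-"
        if strand == "+":
            template = genome.fetch(chrom, start, min(start + buffer, L))
        else:
            template = reverse_complement(genome.fetch(chrom, max(0, start + cfg.Q - buffer), start + cfg.Q))
        seq, quals = _noisy_read(template, cfg, rng)
        reads.append(Read(name=f"read_{idx}", seq=seq, qualities=quals,
                          truth=ReadTruth(chrom=chrom, start=start, strand=strand)))
    return reads


def write_fastq(reads: Sequence[Read], path: str | Path, truth_path: str | Path | None = None) -> Path:
    """Write 4-line FASTQ (Phred+33); truth goes to a sibling TSV if given."""
    path = Path(path)
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + _PHRED_OFFSET) for q in read.qualities)
            fh.write(f"@{read.name}\n{read.seq}\n+\n{qual}\n")
    if truth_path is not None:
        write_truth(reads, truth_path)
    return path


def write_truth(reads: Sequence[Read], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart0\tstrand\n")
        for read in reads:
            if read.truth is None:
                raise ValueError(f"read {read.name!r} carries no truth record")
            t = read.truth
            fh.write(f"{read.name}\t{t.chrom}\t{t.start}\t{t.strand}\n")
    return path


def read_truth(path: str | Path) -> dict[str, ReadTruth]:
    truths: dict[str, ReadTruth] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "chrom", "start0", "strand"]:
            raise ValueError(f"unexpected truth TSV header {header}")
        for line in fh:
            name, chrom, start, strand = line.rstrip("\n").split("\t")
            truths[name] = ReadTruth(chrom=chrom, start=int(start), strand=strand)
    return truths


def read_fastq(path: str | Path, truth: dict[str, ReadTruth] | None = None) -> list[Read]:
    """Parse 4-line FASTQ; attaches truth records by read name when given."""
    reads: list[Read] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            name = header[1:].split()[0]
            reads.append(Read(name=name, seq=seq,
                              qualities=[ord(c) - _PHRED_OFFSET for c in qual],
                              truth=truth.get(name) if truth else None))
    return reads
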