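"""Reference genomes: FASTA I/O, synthetic genomes with planted repeats.

Coordinate convention used across the whole package: 0-based, half-open
intervals. SAM output converts to 1-based at the writing boundary only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """Named chromosome sequences over the {A,C,G,T} alphabet.

    ``chromosomes`` preserves insertion order (file order for FASTA input);
    fragment identifiers and tie-breaking depend on that order being stable.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")

    @property
    def N(self) -> int:
        """Total genome length in bases."""
        return sum(len(s) for s in self.chromosomes.values())

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.chromosomes.items())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the half-open slice [start, end) of a chromosome."""
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"slice [{start}, {end}) out of range for {chrom} (len {len(seq)})")
        return seq[start:end]


def _normalize_sequence(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Uppercase and replace any non-ACGT character by a seeded random base."""
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    bad = ~np.isin(arr, _BASES)
    n_bad = int(bad.sum())
    if n_bad:
        arr[bad] = _BASES[rng.integers(0, 4, size=n_bad)]
    return arr.tobytes().decode("ascii"), n_bad


def load_fasta(path: str | Path, *, ambiguity_seed: int = 0) -> ReferenceGenome:
    """Load a (multi-record) FASTA file as a reference genome.

    One chromosome per record, in file order. Sequences are uppercased;
    ambiguity codes (N, IUPAC) are replaced by a concrete base drawn from a
    generator seeded with ``ambiguity_seed``, and the replacement count is
    logged — the downstream alphabet is strictly {A,C,G,T}.
    """
    path = Path(path)
    rng = np.random.default_rng(ambiguity_seed)
    chromosomes: dict[str, str] = {}
    n_replaced = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate record name {record.id!r} in {path}")
        seq, n_bad = _normalize_sequence(str(record.seq), rng)
        if not seq:
            raise ValueError(f"record {record.id!r} in {path} has an empty sequence")
        n_replaced += n_bad
        chromosomes[record.id] = seq
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    if n_replaced:
        logger.warning("replaced %d ambiguous bases with random concrete bases", n_replaced)
    return ReferenceGenome(chromosomes)


def write_fasta(genome: ReferenceGenome, path: str | Path, *, line_width: int = 60) -> Path:
    """Write a genome to FASTA with fixed line width; round-trips exactly."""
    if line_width <= 0:
        raise ValueError("line_width must be positive")
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    return path


@dataclass
class RepeatFamily:
    """An exactly repeated subsequence planted into a synthetic genome."""

    seq: str
    copies: list[tuple[str, int]] = field(default_factory=list)  # (chrom, 0-based start)

    @property
    def length(self) -> int:
        return len(self.seq)

    def to_dict(self) -> dict:
        return {"length": self.length, "seq": self.seq,
                "copies": [{"chrom": c, "start": s} for c, s in self.copies]}


def generate_synthetic_genome(
    chrom_lengths: Sequence[int],
    repeat_spec: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> tuple[ReferenceGenome, list[RepeatFamily]]:
    """Generate a uniform-composition genome with optional planted repeats.

    Parameters
    ----------
    chrom_lengths
        Length of each chromosome in bases.
    repeat_spec
        ``(length, n_copies)`` pairs; for each pair one random repeat unit is
        drawn and planted as ``n_copies`` exact, non-overlapping copies at
        recorded positions (returned so multi-mapping behaviour can be probed).
    seed
        Bit-reproducible output for a fixed seed.

    Returns
    -------
    (genome, repeat_families)
    """
    if not chrom_lengths or any(l <= 0 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be positive")
    total = sum(chrom_lengths)
    footprint = sum(length * n for length, n in repeat_spec)
    if footprint >= total:
        raise ValueError(f"repeat footprint {footprint} exceeds genome size {total}")
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
    if len(names) != len(chrom_lengths):
        raise ValueError("names and chrom_lengths must have equal length")

    rng = np.random.default_rng(seed)
    seqs = {name: _BASES[rng.integers(0, 4, size=length)]
            for name, length in zip(names, chrom_lengths)}

    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    families: list[RepeatFamily] = []
    lengths = np.asarray(chrom_lengths, dtype=float)
    for rep_len, n_copies in repeat_spec:
        if rep_len <= 0 or n_copies <= 0:
            raise ValueError("repeat lengths and copy numbers must be positive")
        unit = _BASES[rng.integers(0, 4, size=rep_len)].tobytes().decode("ascii")
        family = RepeatFamily(seq=unit)
        for _ in range(n_copies):
            placed = False
            for _attempt in range(10_000):
                # chromosomes weighted by length so placement is ~uniform genome-wide
                ci = rng.choice(len(names), p=lengths / lengths.sum())
                chrom = names[ci]
                if chrom_lengths[ci] < rep_len:
                    continue
                start = int(rng.integers(0, chrom_lengths[ci] - rep_len + 1))
                if any(start < e and s < start + rep_len for s, e in occupied[chrom]):
                    continue
                seqs[chrom][start : start + rep_len] = np.frombuffer(unit.encode(), dtype="S1")
                occupied[chrom].append((start, start + rep_len))
                family.copies.append((chrom, start))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place repeat copy without overlap; "
                                   "reduce repeat footprint")
        families.append(family)

    genome = ReferenceGenome({name: arr.tobytes().decode("ascii") for name, arr in seqs.items()})
    return genome, families


def write_repeat_metadata(families: Sequence[RepeatFamily], path: str | Path) -> Path:
    """JSON sidecar with planted-repeat positions (for multi-mapping tests)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"repeats": [f.to_dict() for f in families]}, fh, indent=2)
    return path


def read_repeat_metadata(path: str | Path) -> list[RepeatFamily]:
    with open(path) as fh:
        data = json.load(fh)
    return [RepeatFamily(seq=r["seq"], copies=[(c["chrom"], c["start"]) for c in r["copies"]])
            for r in data["repeats"]]
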