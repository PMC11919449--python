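"""Genome sharding and the fragment vector store.

The reference is cut into overlapping fragments (default length 1250,
overlap 250) so that every read up to the overlap length is fully
contained in at least one fragment, and the fragment set covers every
chromosome position. Fragment embeddings live in a local vector store:
an exact brute-force cosine scan by default, or an inverted-file
approximate backend (k-means coarse quantizer) for larger stores.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from esalign.reference import ReferenceGenome


@dataclass(frozen=True)
class Fragment:
    """A contiguous chromosome slice; the indexed unit of the search."""

    chrom: str
    start: int  # 0-based global start within its chromosome
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


def shard_count(N: int, frag_len: int = 1250, overlap: int = 250) -> int:
    """Fragments produced for one chromosome of length N (closed form)."""
    if overlap >= frag_len or overlap < 1:
        raise ValueError("require frag_len > overlap >= 1")
    if N <= frag_len:
        return 1
    stride = frag_len - overlap
    n_regular = (N - frag_len) // stride + 1
    last_end = (n_regular - 1) * stride + frag_len
    return n_regular + (1 if last_end < N else 0)


def shard(genome: ReferenceGenome, frag_len: int = 1250, overlap: int = 250) -> list[Fragment]:
    """Cut every chromosome into overlapping fragments.

    Starts advance by ``stride = frag_len - overlap``; a final fragment is
    right-anchored at the chromosome end so coverage is total. Chromosomes
    shorter than ``frag_len`` yield a single whole-chromosome fragment.
    Consecutive fragments overlap by >= ``overlap`` bases, so any read of
    length <= ``overlap`` taken without indels from the reference is fully
    contained in at least one fragment.
    """
    if overlap >= frag_len or overlap < 1:
        raise ValueError("require frag_len > overlap >= 1")
    stride = frag_len - overlap
    fragments: list[Fragment] = []
    for chrom, seq in genome:
        L = len(seq)
        if L <= frag_len:
            fragments.append(Fragment(chrom, 0, seq))
            continue
        starts = list(range(0, L - frag_len + 1, stride))
        if starts[-1] + frag_len < L:
            starts.append(L - frag_len)
        for s in starts:
            fragments.append(Fragment(chrom, s, seq[s : s + frag_len]))
    return fragments


@runtime_checkable
class SequenceEncoder(Protocol):
    """Anything that maps DNA strings to unit-norm embedding rows."""

    def embed_batch(self, seqs: Sequence[str]) -> np.ndarray: ...


class KmerHashEncoder:
    """Deterministic k-mer-profile hash embedding (no training).

    Counts k-mers, hashes them into ``dim`` buckets with a fixed
    multiplicative mix, sqrt-transforms and L2-normalizes. Used as an
    oracle encoder to exercise the shard/search/align plumbing
    independently of contrastive training.
    """

    _MIX = 0x9E3779B1

    def __init__(self, k: int = 8, dim: int = 4096):
        if k < 1 or dim < 1:
            raise ValueError("k and dim must be positive")
        self.k = k
        self.dim = dim

    def embed(self, seq: str) -> np.ndarray:
        return self.embed_batch([seq])[0]

    def embed_batch(self, seqs: Sequence[str]) -> np.ndarray:
        from esalign.align import _seq_to_arr  # base->int mapping shared with SW

        out = np.zeros((len(seqs), self.dim), dtype=np.float32)
        for row, seq in enumerate(seqs):
            arr = _seq_to_arr(seq).astype(np.int64)
            n = len(arr) - self.k + 1
            if n <= 0:
                raise ValueError(f"sequence shorter than k={self.k}")
            codes = np.zeros(n, dtype=np.int64)
            for i in range(self.k):
                codes = codes * 4 + arr[i : i + n]
            idx = ((codes * self._MIX) & 0xFFFFFFFF) % self.dim
            counts = np.bincount(idx, minlength=self.dim).astype(np.float32)
            vec = np.sqrt(counts)
            norm = np.linalg.norm(vec)
            out[row] = vec / norm if norm else vec
        return out


@dataclass
class Hit:
    fragment: Fragment
    distance: float  # cosine distance, 1 - cos
    index: int


class VectorStore:
    """Fragment embeddings + metadata with top-K cosine retrieval.

    ``backend="exact"`` scans all vectors; ``backend="approx"`` is an
    inverted-file index (k-means coarse quantizer, ``nprobe`` nearest
    cells scanned per query). Metadata (chromosome, start, raw sequence)
    is retrievable for every hit.
    """

    def __init__(self, vectors: np.ndarray, fragments: Sequence[Fragment],
                 chrom_order: Sequence[str], backend: str = "exact",
                 nprobe: int = 8, seed: int = 0):
        if len(vectors) != len(fragments):
            raise ValueError("one vector per fragment required")
        if len(vectors) == 0:
            raise ValueError("empty store")
        if backend not in ("exact", "approx"):
            raise ValueError(f"unknown backend {backend!r}")
        self.vectors = np.ascontiguousarray(vectors, dtype=np.float32)
        self.fragments = list(fragments)
        self.chrom_order = list(chrom_order)
        self._chrom_rank = {c: i for i, c in enumerate(self.chrom_order)}
        self.backend = backend
        self.nprobe = nprobe
        self.seed = seed
        self._chrom_ids = np.array([self._chrom_rank[f.chrom] for f in self.fragments])
        self._starts = np.array([f.start for f in self.fragments])
        self._centroids: np.ndarray | None = None
        self._labels: np.ndarray | None = None
        if backend == "approx":
            self._fit_ivf()

    def __len__(self) -> int:
        return len(self.fragments)

    def _fit_ivf(self) -> None:
        from sklearn.cluster import KMeans

        n_clusters = max(1, min(len(self) // 4, int(np.sqrt(len(self)) * 2)))
        km = KMeans(n_clusters=n_clusters, n_init=3, random_state=self.seed)
        self._labels = km.fit_predict(self.vectors)
        self._centroids = km.cluster_centers_.astype(np.float32)

    def _candidate_indices(self, vec: np.ndarray) -> np.ndarray:
        if self.backend == "exact":
            return np.arange(len(self))
        cd = ((self._centroids - vec[None, :]) ** 2).sum(axis=1)
        cells = np.argsort(cd)[: self.nprobe]
        return np.flatnonzero(np.isin(self._labels, cells))

    def query(self, read_embedding: np.ndarray, k: int, diversity: bool = True) -> list[Hit]:
        """Top-K nearest fragments, per chromosome when ``diversity`` is on.

        Hits are sorted by cosine distance ascending; exact ties break by
        (chromosome order, start).
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        vec = np.asarray(read_embedding, dtype=np.float32).ravel()
        cand = self._candidate_indices(vec)
        dists = 1.0 - self.vectors[cand] @ vec
        order = np.lexsort((self._starts[cand], self._chrom_ids[cand], dists))
        if diversity:
            chosen: list[int] = []
            per_chrom: dict[int, int] = {}
            for pos in order:
                c = int(self._chrom_ids[cand[pos]])
                if per_chrom.get(c, 0) < k:
                    per_chrom[c] = per_chrom.get(c, 0) + 1
                    chosen.append(pos)
            sel = chosen
        else:
            sel = list(order[:k])
        return [Hit(fragment=self.fragments[cand[p]], distance=float(dists[p]), index=int(cand[p]))
                for p in sel]

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "vectors.npy", self.vectors)
        with open(directory / "fragments.tsv", "w") as fh:
            fh.write("frag_id\tchrom\tstart0\tlen\n")
            for i, f in enumerate(self.fragments):
                fh.write(f"{i}\t{f.chrom}\t{f.start}\t{f.length}\n")
        with open(directory / "fragments.fa", "w") as fh:
            for i, f in enumerate(self.fragments):
                fh.write(f">frag_{i}\n{f.seq}\n")
        manifest = {
            "n_fragments": len(self), "dim": int(self.vectors.shape[1]),
            "backend": self.backend, "nprobe": self.nprobe, "seed": self.seed,
            "chrom_order": self.chrom_order,
            "vectors_sha256": hashlib.sha256(self.vectors.tobytes()).hexdigest(),
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "VectorStore":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        vectors = np.load(directory / "vectors.npy")
        seqs: list[str] = []
        with open(directory / "fragments.fa") as fh:
            for line in fh:
                if not line.startswith(">"):
                    seqs.append(line.strip())
        fragments: list[Fragment] = []
        with open(directory / "fragments.tsv") as fh:
            fh.readline()
            for i, line in enumerate(fh):
                _, chrom, start, _length = line.rstrip("\n").split("\t")
                fragments.append(Fragment(chrom, int(start), seqs[i]))
        return cls(vectors, fragments, manifest["chrom_order"], backend=manifest["backend"],
                   nprobe=manifest["nprobe"], seed=manifest["seed"])

    def to_bed(self, path: str | Path) -> Path:
        """Fragment intervals as BED for inspection."""
        path = Path(path)
        with open(path, "w") as fh:
            for i, f in enumerate(self.fragments):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tfrag_{i}\n")
        return path


def build_index(fragments: Sequence[Fragment], encoder: SequenceEncoder,
                chrom_order: Sequence[str], backend: str = "exact",
                batch_size: int = 64, seed: int = 0) -> VectorStore:
    """Embed every fragment and insert it with metadata into a store."""
    if not fragments:
        raise ValueError("no fragments to index")
    blocks = []
    for i in range(0, len(fragments), batch_size):
        blocks.append(encoder.embed_batch([f.seq for f in fragments[i : i + batch_size]]))
    vectors = np.vstack(blocks)
    return VectorStore(vectors, fragments, chrom_order, backend=backend, seed=seed)
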