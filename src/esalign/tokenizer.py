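"""Subword tokenization for DNA.

A byte-pair-encoding vocabulary is learned over sampled genome
fragments; encoding uses greedy longest-match segmentation, which is
deterministic and lossless (the four single bases are always in the
vocabulary, so every {A,C,G,T} string segments without UNK).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit, types
from numba.typed import Dict

PAD, UNK, CLS = 0, 1, 2
_SPECIALS = ["<pad>", "<unk>", "<cls>"]
_N_SPECIALS = len(_SPECIALS)


@njit(cache=False)
def _best_pair(arr):  # pragma: no cover - numba
    """Count adjacent pairs in arr (separator -1 breaks pairs); return best.

    Returns (a, b, count); ties broken by smallest (a, b) for determinism.
    """
    pair_count = Dict.empty(types.int64, types.int64)
    for i in range(len(arr) - 1):
        a = np.int64(arr[i])
        b = np.int64(arr[i + 1])
        if a < 0 or b < 0:
            continue
        key = a * 1_000_000 + b
        if key in pair_count:
            pair_count[key] += 1
        else:
            pair_count[key] = 1
    best_key = -1
    best_count = 0
    for key, cnt in pair_count.items():
        if cnt > best_count or (cnt == best_count and key < best_key):
            best_key = key
            best_count = cnt
    if best_key < 0:
        return -1, -1, 0
    return best_key // 1_000_000, best_key % 1_000_000, best_count


@njit(cache=False)
def _merge(arr, a, b, new_id):  # pragma: no cover - numba
    """Replace left-to-right non-overlapping (a, b) occurrences by new_id."""
    out = np.empty_like(arr)
    i = 0
    j = 0
    n = len(arr)
    while i < n:
        if i + 1 < n and arr[i] == a and arr[i + 1] == b:
            out[j] = new_id
            i += 2
        else:
            out[j] = arr[i]
            i += 1
        j += 1
    return out[:j]


class DnaTokenizer:
    """BPE vocabulary over {A,C,G,T} with greedy longest-match encoding."""

    def __init__(self, tokens: Sequence[str]):
        # tokens: full id->string table including specials and the 4 bases
        self.id_to_token = list(tokens)
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")
        for base in "ACGT":
            if base not in self.token_to_id:
                raise ValueError(f"single base {base!r} missing from vocabulary")
        self._max_len = max(len(t) for t in self.id_to_token)

    @property
    def vocab_size(self) -> int:
        return len(self.id_to_token)

    def encode(self, seq: str) -> list[int]:
        """Greedy longest-match segmentation; lossless on {A,C,G,T} input."""
        ids: list[int] = []
        lookup = self.token_to_id
        n = len(seq)
        i = 0
        max_len = self._max_len
        while i < n:
            for L in range(min(max_len, n - i), 0, -1):
                tid = lookup.get(seq[i : i + L])
                if tid is not None:
                    ids.append(tid)
                    i += L
                    break
            else:
                raise ValueError(f"character {seq[i]!r} at position {i} is not in the DNA alphabet")
        return ids

    def decode(self, ids: Sequence[int]) -> str:
        parts = []
        for tid in ids:
            if tid in (PAD, CLS):
                continue
            if tid == UNK:
                raise ValueError("cannot decode UNK token")
            parts.append(self.id_to_token[tid])
        return "".join(parts)

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"tokens": self.id_to_token}, fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DnaTokenizer":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data["tokens"])


def train_vocab(
    corpus: Iterable[str],
    vocab_size: int = 10_000,
    seed: int = 0,
    max_corpus_bases: int = 500_000,
    min_pair_count: int = 2,
) -> DnaTokenizer:
    """Learn a BPE vocabulary from DNA sequences.

    Merges stop when ``vocab_size`` entries exist or no adjacent pair
    occurs at least ``min_pair_count`` times. The corpus is capped at
    ``max_corpus_bases`` by seeded subsampling of whole sequences, so
    training cost is bounded regardless of genome size.
    """
    seqs = [s for s in corpus if s]
    if not seqs:
        raise ValueError("empty training corpus")
    if vocab_size < _N_SPECIALS + 4 + 1:
        raise ValueError(f"vocab_size must be at least {_N_SPECIALS + 5}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seqs))
    sample: list[str] = []
    total = 0
    for i in order:
        sample.append(seqs[i])
        total += len(seqs[i])
        if total >= max_corpus_bases:
            break

    tokens = list(_SPECIALS) + list("ACGT")
    base_id = {b: tokens.index(b) for b in "ACGT"}

    pieces = []
    for s in sample:
        s = s.upper()
        try:
            pieces.append(np.array([base_id[c] for c in s], dtype=np.int32))
        except KeyError as exc:
            raise ValueError(f"corpus contains non-ACGT character {exc.args[0]!r}") from exc
        pieces.append(np.array([-1], dtype=np.int32))
    arr = np.concatenate(pieces)

    while len(tokens) < vocab_size:
        a, b, count = _best_pair(arr)
        if a < 0 or count < min_pair_count:
            break
        new_id = len(tokens)
        tokens.append(tokens[a] + tokens[b])
        arr = _merge(arr, a, b, new_id)
    return DnaTokenizer(tokens)
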