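"""Sharding geometry, containment guarantees, and vector-store retrieval."""

import numpy as np
import pytest

import esalign
from esalign.index import Fragment, KmerHashEncoder, VectorStore, build_index, shard, shard_count
from helpers import random_dna


class TestShard:
    def test_single_fragment_for_exact_length_chromosome(self):
        g, _ = esalign.generate_synthetic_genome([1250], seed=0)
        frags = shard(g, 1250, 250)
        assert len(frags) == 1 and frags[0].start == 0

    def test_starts_include_right_anchored_terminal(self):
        g, _ = esalign.generate_synthetic_genome([3000], seed=1)
        frags = shard(g, 1250, 250)
        assert [f.start for f in frags] == [0, 1000, 1750]
        assert all(f.seq == g.fetch("chr1", f.start, f.end) for f in frags)

    def test_every_overlap_length_window_contained(self):
        g, _ = esalign.generate_synthetic_genome([3000], seed=1)
        frags = shard(g, 1250, 250)
        for pos in range(0, 3000 - 250 + 1):
            assert any(f.start <= pos and pos + 250 <= f.end for f in frags)

    def test_coverage_is_total(self, two_chrom_genome):
        frags = shard(two_chrom_genome, 1250, 250)
        for chrom, seq in two_chrom_genome:
            covered = np.zeros(len(seq), dtype=bool)
            for f in frags:
                if f.chrom == chrom:
                    covered[f.start : f.end] = True
            assert covered.all()

    @pytest.mark.parametrize("N", [1250, 1251, 2249, 2250, 3000, 9999, 100_000])
    def test_closed_form_matches_materialized_count(self, N):
        g, _ = esalign.generate_synthetic_genome([N], seed=2)
        assert shard_count(N, 1250, 250) == len(shard(g, 1250, 250))

    def test_genome_scale_arithmetic(self):
        # ~3M fragments for a 3 Gb reference at length 1250 / overlap 250
        assert shard_count(3_000_000_000, 1250, 250) == 3_000_000

    def test_invalid_overlap_rejected(self, small_genome):
        with pytest.raises(ValueError):
            shard(small_genome, 1250, 1250)


class TestKmerHashEncoder:
    def test_deterministic_and_unit_norm(self):
        enc = KmerHashEncoder(k=8, dim=512)
        seq = random_dna(300, 3)
        v1, v2 = enc.embed(seq), enc.embed(seq)
        assert np.array_equal(v1, v2)
        assert np.linalg.norm(v1) == pytest.approx(1.0, abs=1e-5)

    def test_read_closer_to_source_fragment_than_to_random(self):
        enc = KmerHashEncoder(k=8, dim=1024)
        frag = random_dna(1250, 4)
        other = random_dna(1250, 5)
        read = frag[400:650]
        z = enc.embed_batch([read, frag, other])
        assert z[0] @ z[1] > z[0] @ z[2]


@pytest.fixture(scope="module")
def store(two_chrom_genome):
    frags = shard(two_chrom_genome, 1250, 250)
    return build_index(frags, KmerHashEncoder(k=8, dim=1024),
                       two_chrom_genome.names, backend="exact")


class TestVectorStore:
    def test_one_vector_per_fragment(self, store, two_chrom_genome):
        assert len(store) == len(shard(two_chrom_genome, 1250, 250))

    def test_self_retrieval_at_rank_one(self, store):
        for idx in (0, 17, len(store) - 1):
            hits = store.query(store.vectors[idx], k=3, diversity=False)
            assert hits[0].index == idx
            assert hits[0].distance == pytest.approx(0.0, abs=1e-5)

    def test_diversity_returns_top_k_per_chromosome(self, store):
        q = store.vectors[5]
        hits = store.query(q, k=2, diversity=True)
        assert len(hits) <= 4
        for chrom in store.chrom_order:
            assert sum(h.fragment.chrom == chrom for h in hits) <= 2
        # distances ascending
        d = [h.distance for h in hits]
        assert d == sorted(d)

    def test_single_chromosome_diversity_is_noop(self, small_genome):
        frags = shard(small_genome, 1250, 250)
        st = build_index(frags, KmerHashEncoder(k=8, dim=512), small_genome.names)
        q = st.vectors[3]
        on = [h.index for h in st.query(q, k=5, diversity=True)]
        off = [h.index for h in st.query(q, k=5, diversity=False)]
        assert on == off

    def test_k_saturation_returns_all_fragments(self, store):
        hits = store.query(store.vectors[0], k=10 * len(store), diversity=True)
        assert len(hits) == len(store)

    def test_save_load_round_trip(self, store, tmp_path):
        store.save(tmp_path / "store")
        loaded = VectorStore.load(tmp_path / "store")
        assert np.array_equal(loaded.vectors, store.vectors)
        assert loaded.fragments == store.fragments
        q = store.vectors[9]
        assert [h.index for h in loaded.query(q, k=4)] == [h.index for h in store.query(q, k=4)]

    def test_bed_export(self, store, tmp_path):
        bed = store.to_bed(tmp_path / "frags.bed")
        lines = bed.read_text().splitlines()
        assert len(lines) == len(store)
        chrom, start, end, _name = lines[0].split("\t")
        assert int(end) - int(start) == store.fragments[0].length

    def test_empty_store_rejected(self):
        with pytest.raises(ValueError):
            VectorStore(np.zeros((0, 4), dtype=np.float32), [], [])


def test_retrieved_slate_is_small_relative_to_exhaustive_scan(store):
    # the whole point of retrieval: candidates <= K * n_chromosomes, far
    # below the N/Q fragments an exhaustive scan would touch
    K = 5
    hits = store.query(store.vectors[0], k=K, diversity=True)
    n_chroms = len(store.chrom_order)
    assert len(hits) <= K * n_chroms
    N = sum(f.length for f in store.fragments)  # upper bound on genome size
    assert K * n_chroms < N / 250


def test_exact_and_approx_backends_agree_on_top1():
    # 10^4 stored vectors; queries are stored vectors perturbed by small noise
    rng = np.random.default_rng(0)
    vecs = rng.normal(size=(10_000, 64)).astype(np.float32)
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    frags = [Fragment("chr1", i, "ACGT") for i in range(len(vecs))]
    exact = VectorStore(vecs, frags, ["chr1"], backend="exact")
    approx = VectorStore(vecs, frags, ["chr1"], backend="approx", nprobe=8, seed=0)
    agree = 0
    n_queries = 1000
    idx = rng.integers(0, len(vecs), n_queries)
    for i in idx:
        q = vecs[i] + rng.normal(scale=0.05, size=64).astype(np.float32)
        q /= np.linalg.norm(q)
        a = exact.query(q, k=1, diversity=False)[0].index
        b = approx.query(q, k=1, diversity=False)[0].index
        agree += a == b
    assert agree / n_queries >= 0.99
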