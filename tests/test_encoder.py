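"""Encoder forward/backward correctness, contrastive-loss identities, training recipe."""

import numpy as np
import pytest

import esalign
from esalign.encoder import (
    EncoderConfig, RdeEncoder, TrainConfig, _loss_and_grads, contrastive_loss,
    one_cycle_lr, retrieval_accuracy, sample_training_batch, train,
)
from esalign.tokenizer import DnaTokenizer
from helpers import random_dna

TINY_TOKENS = ["<pad>", "<unk>", "<cls>", "A", "C", "G", "T", "AC", "GT", "ACG"]


def tiny_encoder(dtype="float64", dropout=0.0, seed=0):
    tok = DnaTokenizer(TINY_TOKENS)
    cfg = EncoderConfig(vocab_size=len(TINY_TOKENS), n_layers=2, n_heads=2,
                        model_width=16, ff_width=32, projection_dim=8,
                        dropout=dropout, max_tokens=64, dtype=dtype)
    return RdeEncoder(cfg, tok, seed=seed)


class TestContrastiveLoss:
    def test_equal_distances_give_log_batch_size(self):
        # all embeddings identical: softmax over B equal logits
        z = np.tile(np.eye(1, 32), (16, 1))
        assert contrastive_loss(z, z, 0.05) == pytest.approx(np.log(16), abs=1e-12)

    def test_extreme_separation_drives_loss_to_zero(self):
        # B=2 with d(positive)=0 and d(negative)=2 at tau=0.05:
        # analytic value log(1 + e^-40) ~ 4.25e-18
        e1 = np.eye(1, 8).ravel()
        zr = np.stack([e1, -e1])
        zf = np.stack([e1, -e1])
        assert contrastive_loss(zr, zf, 0.05) == pytest.approx(np.log1p(np.exp(-40.0)), abs=1e-12)

    def test_monotone_in_positive_distance(self):
        # rotate read 1 toward its fragment inside the plane orthogonal to
        # everything else, so every negative distance stays fixed while the
        # positive distance shrinks: the loss must never increase
        f1 = np.array([1.0, 0.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0, 0.0])
        e3 = np.array([0.0, 0.0, 1.0, 0.0])
        zf = np.stack([f1, e3])
        losses = []
        for theta in np.linspace(np.pi / 2, 0.0, 12):
            r1 = np.cos(theta) * f1 + np.sin(theta) * e2
            losses.append(contrastive_loss(np.stack([r1, e3]), zf, 0.05))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_invariant_under_joint_pair_permutation(self):
        rng = np.random.default_rng(1)
        zr = rng.normal(size=(16, 8))
        zf = rng.normal(size=(16, 8))
        zr /= np.linalg.norm(zr, axis=1, keepdims=True)
        zf /= np.linalg.norm(zf, axis=1, keepdims=True)
        perm = rng.permutation(16)
        assert contrastive_loss(zr, zf, 0.05) == pytest.approx(
            contrastive_loss(zr[perm], zf[perm], 0.05), abs=1e-12)

    def test_shape_and_temperature_validation(self):
        z = np.eye(4, 8)
        with pytest.raises(ValueError):
            contrastive_loss(z, z[:3], 0.05)
        with pytest.raises(ValueError):
            contrastive_loss(z, z, 0.0)

    def test_loss_nonnegative_and_finite(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            z1 = rng.normal(size=(6, 12))
            z2 = rng.normal(size=(6, 12))
            z1 /= np.linalg.norm(z1, axis=1, keepdims=True)
            z2 /= np.linalg.norm(z2, axis=1, keepdims=True)
            loss = contrastive_loss(z1, z2, 0.05)
            assert np.isfinite(loss) and loss >= 0.0


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        enc = tiny_encoder()
        rng = np.random.default_rng(1)
        seqs_r = ["ACGTAC", "GGTACA", "TTTT"]
        seqs_f = ["ACGTACGGT", "GGTACATT", "TTTTGGA"]
        ids_r, m_r = enc._prepare(seqs_r)
        ids_f, m_f = enc._prepare(seqs_f)

        def loss_fn():
            zr, _ = enc._forward(ids_r, m_r)
            zf, _ = enc._forward(ids_f, m_f)
            return _loss_and_grads(zr, zf, 0.05)[0]

        zr, cr = enc._forward(ids_r, m_r)
        zf, cf = enc._forward(ids_f, m_f)
        _, dzr, dzf = _loss_and_grads(zr, zf, 0.05)
        gr = enc._backward(cr, dzr)
        gf = enc._backward(cf, dzf)
        grads = {k: gr[k] + gf[k] for k in gr}

        eps = 1e-6
        names = ["tok_emb", "pos_emb", "proj.w", "proj.b", "lnf.g",
                 "l0.wq", "l0.wk", "l0.wv", "l0.wo", "l0.w1", "l0.w2",
                 "l0.ln1.g", "l0.ln2.b", "l1.wq", "l1.b1"]
        for name in names:
            p = enc.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss_fn()
                p[idx] = old - eps
                lm = loss_fn()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), name


class TestEmbed:
    def test_eval_mode_deterministic_and_unit_norm(self):
        enc = tiny_encoder(dropout=0.1)
        seq = random_dna(40, 0)
        z1, z2 = enc.embed(seq), enc.embed(seq)
        assert np.array_equal(z1, z2)
        assert np.linalg.norm(z1) == pytest.approx(1.0, abs=1e-6)
        # cosine self-distance is exactly zero up to rounding
        assert 1.0 - z1 @ z1 == pytest.approx(0.0, abs=1e-6)

    def test_sequence_exceeding_max_tokens_rejected(self):
        enc = tiny_encoder()
        with pytest.raises(ValueError):
            enc.embed("A" * 100)  # tokenizes to >64 single-base tokens

    def test_dropout_masks_differ_between_forward_calls(self):
        enc = tiny_encoder(dropout=0.3)
        ids, mask = enc._prepare(["ACGTACGT"])
        rng = np.random.default_rng(0)
        z1, _ = enc._forward(ids, mask, train=True, rng=rng)
        z2, _ = enc._forward(ids, mask, train=True, rng=rng)
        assert not np.array_equal(z1, z2)

    def test_checkpoint_round_trip(self, tmp_path):
        enc = tiny_encoder(dtype="float32")
        path = enc.save(tmp_path / "ckpt.npz")
        loaded = RdeEncoder.load(path)
        seq = random_dna(30, 5)
        assert np.array_equal(loaded.embed(seq), enc.embed(seq))
        assert loaded.config == enc.config


class TestBatchSampling:
    CFG = TrainConfig(steps=1, batch_size=16, grad_accum=1,
                      fragment_len_range=(800, 2000), read_len_range=(150, 500))

    def test_noise_free_reads_are_fragment_substrings(self, small_genome):
        cfg = TrainConfig(steps=1, noise_read_fraction=0.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            for read, frag in sample_training_batch(small_genome, cfg, rng):
                assert read in frag
                assert 800 <= len(frag) <= 2000
                assert 150 <= len(read) <= 500

    def test_fragment_length_distribution_moments(self, small_genome):
        # U([800, 2000]) has mean 1400; mean over 1000*16 samples within +-3 sigma
        rng = np.random.default_rng(1)
        lengths = []
        for _ in range(1000):
            lengths += [len(f) for _, f in sample_training_batch(small_genome, self.CFG, rng)]
        assert 1380 <= np.mean(lengths) <= 1420

    def test_noised_read_fraction_near_forty_percent(self, small_genome):
        rng = np.random.default_rng(2)
        noisy = total = 0
        for _ in range(100):
            for read, frag in sample_training_batch(small_genome, self.CFG, rng):
                noisy += read not in frag
                total += 1
        # per-read noise probability 0.40 (a read can also be noised yet remain
        # a substring by chance; negligible at rates >= 1%)
        assert abs(noisy / total - 0.40) <= 0.05

    def test_genome_too_short_rejected(self):
        g, _ = esalign.generate_synthetic_genome([1000], seed=0)
        with pytest.raises(ValueError):
            sample_training_batch(g, self.CFG, np.random.default_rng(0))


class TestTraining:
    def test_short_run_reduces_loss_and_improves_retrieval(self, small_genome, small_tokenizer):
        cfg = EncoderConfig(vocab_size=small_tokenizer.vocab_size, n_layers=1, n_heads=2,
                            model_width=32, ff_width=64, projection_dim=32, dropout=0.1,
                            max_tokens=512)
        tc = TrainConfig(steps=30, batch_size=8, grad_accum=1, peak_lr=1e-4, seed=0,
                         fragment_len_range=(300, 600), read_len_range=(80, 250))
        probe_cfg = TrainConfig(steps=1, batch_size=8, grad_accum=1, noise_read_fraction=0.0,
                                fragment_len_range=(300, 600), read_len_range=(80, 250), seed=9)
        prng = np.random.default_rng(7)
        probe = []
        for _ in range(8):
            probe += sample_training_batch(small_genome, probe_cfg, prng)

        before = retrieval_accuracy(RdeEncoder(cfg, small_tokenizer, seed=0), probe)
        enc, trace = train(small_genome, small_tokenizer, cfg, tc)
        after = retrieval_accuracy(enc, probe)
        assert len(trace) == tc.steps * tc.grad_accum
        assert np.isfinite(trace).all()
        assert np.mean(trace[-5:]) < np.mean(trace[:5])
        assert after > before

    def test_shuffled_pairs_sit_near_log_b_baseline(self, small_genome, small_tokenizer):
        # an untrained model scored on mismatched (read, fragment) pairs has
        # no positive-pair signal, so its loss sits in a broad band around the
        # uninformative ln B baseline (the sharp temperature amplifies the
        # residual similarity spread, so the band is coarse), far above the
        # near-zero loss of a well-separated batch
        cfg = EncoderConfig(vocab_size=small_tokenizer.vocab_size, n_layers=1, n_heads=2,
                            model_width=32, ff_width=64, projection_dim=32, max_tokens=1024)
        enc = RdeEncoder(cfg, small_tokenizer, seed=1)
        rng = np.random.default_rng(3)
        pairs = sample_training_batch(
            small_genome, TrainConfig(steps=1, fragment_len_range=(800, 2000)), rng)
        reads = [r for r, _ in pairs]
        frags = [f for _, f in pairs]
        rng.shuffle(frags)  # break read/fragment correspondence
        zr = enc.embed_batch(reads)
        zf = enc.embed_batch(frags)
        assert 0.5 * np.log(16) <= contrastive_loss(zr, zf, 0.05) <= 2.0 * np.log(16)

    def test_one_cycle_schedule_shape(self):
        tc = TrainConfig(steps=100, peak_lr=1e-3, warmup_frac=0.1)
        lrs = [one_cycle_lr(s, tc) for s in range(100)]
        assert max(lrs) == pytest.approx(1e-3)
        assert np.argmax(lrs) == 9  # end of warmup
        assert lrs[-1] < 0.05 * 1e-3 + 1e-5
        assert all(a <= b + 1e-12 for a, b in zip(lrs[:9], lrs[1:10]))  # warmup rises
        assert all(a >= b - 1e-12 for a, b in zip(lrs[10:], lrs[11:]))  # anneal falls
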