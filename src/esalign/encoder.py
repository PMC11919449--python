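"""Reference-free DNA embedding encoder and contrastive training.

A small transformer encoder (pre-norm blocks, learned absolute
positions) maps token streams to a masked mean-pooled state, projects it
linearly and L2-normalizes, so cosine distance between a read embedding
h(r) and a fragment embedding h(F) acts as a surrogate for sequence
similarity. Training is self-supervised: each batch holds B (read,
fragment) pairs where the read is a (possibly noised) substring of its
fragment; an InfoNCE-style loss pulls positive pairs together and pushes
each read away from the B-1 other fragments, scaled by temperature.

The network, including backpropagation, is implemented directly on numpy
arrays; gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from esalign.reference import ALPHABET, ReferenceGenome
from esalign.tokenizer import PAD, DnaTokenizer

# tanh-approximation GELU constants (python floats so float32 arrays stay float32)
_GELU_C = float(np.sqrt(2.0 / np.pi))
_GELU_A = 0.044715


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    The reference-scale profile is 6 layers / 12 heads with a 1020-d
    projection; ``EncoderConfig.small()`` gives the desk-scale profile
    (2 layers, 4 heads, width 256) used throughout the test suite.
    """

    vocab_size: int
    n_layers: int = 6
    n_heads: int = 12
    model_width: int = 768
    ff_width: int | None = None  # defaults to 4 * model_width
    projection_dim: int = 1020
    dropout: float = 0.1
    max_tokens: int = 1024
    positional: str = "learned"  # "learned" absolute positions | "none"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.ff_width is None:
            self.ff_width = 4 * self.model_width
        if self.projection_dim < 1 or self.n_layers < 1 or self.n_heads < 1:
            raise ValueError("dimensions must be positive")
        if self.model_width % self.n_heads:
            raise ValueError("model_width must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.positional not in ("learned", "none"):
            raise ValueError(f"unknown positional mode {self.positional!r}")

    @classmethod
    def small(cls, vocab_size: int, **kwargs) -> "EncoderConfig":
        # the projection head is kept at the reference 1020 even at desk
        # scale: it is nearly free to compute and measurably improves
        # retrieval over a width-matched head
        defaults = dict(n_layers=2, n_heads=4, model_width=256, ff_width=512,
                        projection_dim=1020, max_tokens=1024)
        defaults.update(kwargs)
        return cls(vocab_size=vocab_size, **defaults)


@dataclass
class TrainConfig:
    """Contrastive-training recipe.

    Defaults follow the reference recipe: batch size 16 with gradient
    accumulation over 16 micro-batches, temperature 0.05, one-cycle
    cosine learning-rate schedule, fragment lengths ~ U([800, 2000]),
    read lengths ~ U([150, 500]), and substitution noise at a per-read
    rate in [1%, 5%] applied to 40% of reads.
    """

    steps: int = 500                      # optimizer steps
    batch_size: int = 16
    grad_accum: int = 16
    temperature: float = 0.05
    peak_lr: float = 1e-4
    warmup_frac: float = 0.1
    final_lr_frac: float = 0.01
    fragment_len_range: tuple[int, int] = (800, 2000)
    read_len_range: tuple[int, int] = (150, 500)
    noise_read_fraction: float = 0.40
    noise_rate_range: tuple[float, float] = (0.01, 0.05)
    grad_clip: float = 1.0  # global-norm clip; <=0 disables
    adam_beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.noise_read_fraction <= 1.0:
            raise ValueError("noise_read_fraction must be in [0, 1]")
        for lo, hi in (self.fragment_len_range, self.read_len_range, self.noise_rate_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo <= hi)")
        if self.read_len_range[1] > self.fragment_len_range[0]:
            raise ValueError("reads must fit inside the shortest fragment")


# --------------------------------------------------------------------
# layer primitives (forward returns a cache consumed by the backward)

def _ln_f(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_b(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _gelu_f(u):
    t = np.tanh(_GELU_C * (u + _GELU_A * u * u * u))
    return 0.5 * u * (1.0 + t)


def _gelu_b(du, u):
    t = np.tanh(_GELU_C * (u + _GELU_A * u * u * u))
    dinner = _GELU_C * (1.0 + 3.0 * _GELU_A * u * u)
    return du * (0.5 * (1.0 + t) + 0.5 * u * (1.0 - t * t) * dinner)


def _dropout_mask(shape, p, train, rng, dtype):
    if not train or p == 0.0:
        return None
    u = rng.random(shape, dtype=np.float32 if dtype == np.float32 else np.float64)
    return (u >= p).astype(dtype) / np.asarray(1.0 - p, dtype=dtype)


class RdeEncoder:
    """Transformer encoder with an L2-normalized projection head."""

    def __init__(self, config: EncoderConfig, tokenizer: DnaTokenizer, seed: int = 0):
        if config.vocab_size != tokenizer.vocab_size:
            raise ValueError("config.vocab_size must match the tokenizer")
        self.config = config
        self.tokenizer = tokenizer
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameters ----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        dt = np.dtype(c.dtype)

        def normal(*shape):
            return (rng.normal(0.0, 0.02, size=shape)).astype(dt)

        p = self.params
        p["tok_emb"] = normal(c.vocab_size, c.model_width)
        p["pos_emb"] = normal(c.max_tokens, c.model_width)
        for l in range(c.n_layers):
            for name in ("ln1", "ln2"):
                p[f"l{l}.{name}.g"] = np.ones(c.model_width, dtype=dt)
                p[f"l{l}.{name}.b"] = np.zeros(c.model_width, dtype=dt)
            for name in ("wq", "wk", "wv"):
                p[f"l{l}.{name}"] = normal(c.model_width, c.model_width)
            for name in ("bq", "bk", "bv", "bo"):
                p[f"l{l}.{name}"] = np.zeros(c.model_width, dtype=dt)
            # residual-branch output projections are down-scaled at init so
            # the residual stream starts close to the identity (stabilizes
            # the sharp-temperature contrastive objective)
            res_scale = 1.0 / np.sqrt(2.0 * c.n_layers)
            p[f"l{l}.wo"] = (normal(c.model_width, c.model_width) * res_scale).astype(dt)
            p[f"l{l}.w1"] = normal(c.model_width, c.ff_width)
            p[f"l{l}.b1"] = np.zeros(c.ff_width, dtype=dt)
            p[f"l{l}.w2"] = (normal(c.ff_width, c.model_width) * res_scale).astype(dt)
            p[f"l{l}.b2"] = np.zeros(c.model_width, dtype=dt)
        p["lnf.g"] = np.ones(c.model_width, dtype=dt)
        p["lnf.b"] = np.zeros(c.model_width, dtype=dt)
        p["proj.w"] = normal(c.model_width, c.projection_dim)
        p["proj.b"] = np.zeros(c.projection_dim, dtype=dt)

    # -- tokenization / padding ---------------------------------------
    def _prepare(self, seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        c = self.config
        token_lists = [self.tokenizer.encode(s) for s in seqs]
        for s, toks in zip(seqs, token_lists):
            if len(toks) > c.max_tokens:
                raise ValueError(f"sequence of {len(s)} bases tokenizes to {len(toks)} tokens, "
                                 f"exceeding max_tokens={c.max_tokens}")
            if not toks:
                raise ValueError("cannot embed an empty sequence")
        T = max(len(t) for t in token_lists)
        ids = np.full((len(seqs), T), PAD, dtype=np.int64)
        mask = np.zeros((len(seqs), T), dtype=np.dtype(c.dtype))
        for i, toks in enumerate(token_lists):
            ids[i, : len(toks)] = toks
            mask[i, : len(toks)] = 1.0
        return ids, mask

    # -- forward -------------------------------------------------------
    def _forward(self, ids: np.ndarray, mask: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        c = self.config
        p = self.params
        dt = np.dtype(c.dtype)
        B, T = ids.shape
        H, dh = c.n_heads, c.model_width // c.n_heads
        scale = float(1.0 / np.sqrt(dh))
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")

        cache: dict = {"ids": ids, "mask": mask, "layers": []}
        x = p["tok_emb"][ids]
        if c.positional == "learned":
            x = x + p["pos_emb"][:T][None, :, :]
        m0 = _dropout_mask(x.shape, c.dropout, train, rng, dt)
        if m0 is not None:
            x = x * m0
        cache["emb_drop"] = m0
        att_bias = ((1.0 - mask) * -1e9).astype(dt)[:, None, None, :]

        for l in range(c.n_layers):
            lc: dict = {}
            h, lc["ln1"] = _ln_f(x, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            q = h @ p[f"l{l}.wq"] + p[f"l{l}.bq"]
            k = h @ p[f"l{l}.wk"] + p[f"l{l}.bk"]
            v = h @ p[f"l{l}.wv"] + p[f"l{l}.bv"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            s = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale + att_bias
            s -= s.max(-1, keepdims=True)
            e = np.exp(s)
            att = e / e.sum(-1, keepdims=True)
            ctx = np.matmul(att, vh)
            ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, T, c.model_width)
            o = ctx2 @ p[f"l{l}.wo"] + p[f"l{l}.bo"]
            mo = _dropout_mask(o.shape, c.dropout, train, rng, dt)
            if mo is not None:
                o = o * mo
            lc.update(h=h, qh=qh, kh=kh, vh=vh, att=att, ctx2=ctx2, att_drop=mo)
            x = x + o

            h2, lc["ln2"] = _ln_f(x, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            u = h2 @ p[f"l{l}.w1"] + p[f"l{l}.b1"]
            a = _gelu_f(u)
            y = a @ p[f"l{l}.w2"] + p[f"l{l}.b2"]
            my = _dropout_mask(y.shape, c.dropout, train, rng, dt)
            if my is not None:
                y = y * my
            lc.update(h2=h2, u=u, a=a, ffn_drop=my)
            x = x + y
            cache["layers"].append(lc)

        xf, cache["lnf"] = _ln_f(x, p["lnf.g"], p["lnf.b"])
        denom = mask.sum(1, keepdims=True)
        pooled = (xf * mask[:, :, None]).sum(1) / denom
        z0 = pooled @ p["proj.w"] + p["proj.b"]
        norm = np.linalg.norm(z0, axis=1, keepdims=True)
        z = z0 / norm
        cache.update(pooled=pooled, z0=z0, norm=norm, z=z, denom=denom)
        return z, cache

    # -- backward ------------------------------------------------------
    def _backward(self, cache: dict, dz: np.ndarray) -> dict[str, np.ndarray]:
        c = self.config
        p = self.params
        ids, mask = cache["ids"], cache["mask"]
        B, T = ids.shape
        H, dh = c.n_heads, c.model_width // c.n_heads
        scale = float(1.0 / np.sqrt(dh))
        g: dict[str, np.ndarray] = {}

        z, z0, norm = cache["z"], cache["z0"], cache["norm"]
        dz0 = (dz - z * (z * dz).sum(1, keepdims=True)) / norm
        pooled = cache["pooled"]
        g["proj.w"] = pooled.T @ dz0
        g["proj.b"] = dz0.sum(0)
        dpooled = dz0 @ p["proj.w"].T
        dxf = (dpooled[:, None, :] * mask[:, :, None]) / cache["denom"][:, :, None]
        dx, g["lnf.g"], g["lnf.b"] = _ln_b(dxf, cache["lnf"])

        for l in range(c.n_layers - 1, -1, -1):
            lc = cache["layers"][l]
            # FFN block
            dy = dx if lc["ffn_drop"] is None else dx * lc["ffn_drop"]
            g[f"l{l}.w2"] = lc["a"].reshape(-1, c.ff_width).T @ dy.reshape(-1, c.model_width)
            g[f"l{l}.b2"] = dy.sum((0, 1))
            da = dy @ p[f"l{l}.w2"].T
            du = _gelu_b(da, lc["u"])
            g[f"l{l}.w1"] = lc["h2"].reshape(-1, c.model_width).T @ du.reshape(-1, c.ff_width)
            g[f"l{l}.b1"] = du.sum((0, 1))
            dh2 = du @ p[f"l{l}.w1"].T
            dxl, g[f"l{l}.ln2.g"], g[f"l{l}.ln2.b"] = _ln_b(dh2, lc["ln2"])
            dx = dx + dxl
            # attention block
            do = dx if lc["att_drop"] is None else dx * lc["att_drop"]
            ctx2 = lc["ctx2"]
            g[f"l{l}.wo"] = ctx2.reshape(-1, c.model_width).T @ do.reshape(-1, c.model_width)
            g[f"l{l}.bo"] = do.sum((0, 1))
            dctx2 = do @ p[f"l{l}.wo"].T
            dctx = dctx2.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            att, vh, qh, kh = lc["att"], lc["vh"], lc["qh"], lc["kh"]
            datt = np.matmul(dctx, vh.transpose(0, 1, 3, 2))
            dvh = np.matmul(att.transpose(0, 1, 3, 2), dctx)
            ds = att * (datt - (datt * att).sum(-1, keepdims=True))
            dqh = np.matmul(ds, kh) * scale
            dkh = np.matmul(ds.transpose(0, 1, 3, 2), qh) * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, c.model_width)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, c.model_width)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, c.model_width)
            h = lc["h"]
            hf = h.reshape(-1, c.model_width)
            g[f"l{l}.wq"] = hf.T @ dq.reshape(-1, c.model_width)
            g[f"l{l}.wk"] = hf.T @ dk.reshape(-1, c.model_width)
            g[f"l{l}.wv"] = hf.T @ dv.reshape(-1, c.model_width)
            g[f"l{l}.bq"] = dq.sum((0, 1))
            g[f"l{l}.bk"] = dk.sum((0, 1))
            g[f"l{l}.bv"] = dv.sum((0, 1))
            dhh = dq @ p[f"l{l}.wq"].T + dk @ p[f"l{l}.wk"].T + dv @ p[f"l{l}.wv"].T
            dxl, g[f"l{l}.ln1.g"], g[f"l{l}.ln1.b"] = _ln_b(dhh, lc["ln1"])
            dx = dx + dxl

        if cache["emb_drop"] is not None:
            dx = dx * cache["emb_drop"]
        g["pos_emb"] = np.zeros_like(p["pos_emb"])
        if c.positional == "learned":
            g["pos_emb"][:T] = dx.sum(0)
        g["tok_emb"] = np.zeros_like(p["tok_emb"])
        np.add.at(g["tok_emb"], ids, dx)
        return g

    # -- public API ----------------------------------------------------
    def embed(self, seq: str) -> np.ndarray:
        """Unit-norm embedding of one sequence (eval mode, deterministic)."""
        return self.embed_batch([seq])[0]

    def embed_batch(self, seqs: Sequence[str]) -> np.ndarray:
        ids, mask = self._prepare(seqs)
        z, _ = self._forward(ids, mask, train=False)
        if not np.isfinite(z).all():
            raise FloatingPointError("non-finite embedding")
        return z

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {"config": asdict(self.config), "tokens": self.tokenizer.id_to_token}
        arrays = {f"p_{k}": v for k, v in self.params.items()}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "RdeEncoder":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            enc = cls(EncoderConfig(**meta["config"]), DnaTokenizer(meta["tokens"]))
            for key in data.files:
                if key.startswith("p_"):
                    enc.params[key[2:]] = data[key]
        return enc


# --------------------------------------------------------------------
# contrastive loss

def contrastive_loss(read_embs: np.ndarray, frag_embs: np.ndarray,
                     temperature: float = 0.05) -> float:
    """Batch-mean InfoNCE loss on cosine distances.

    For pair j, the positive is fragment j and the other B-1 fragments in
    the batch are negatives:

        l_j = -log[ exp(-d_jj/t) / sum_i exp(-d_ji/t) ],  d = 1 - cos.
    """
    loss, _, _ = _loss_and_grads(read_embs, frag_embs, temperature)
    return loss


def _loss_and_grads(zr: np.ndarray, zf: np.ndarray, tau: float):
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    zr = np.asarray(zr, dtype=np.float64)
    zf = np.asarray(zf, dtype=np.float64)
    if zr.shape != zf.shape:
        raise ValueError(f"batch shapes differ: {zr.shape} vs {zf.shape}")
    B = zr.shape[0]
    dist = 1.0 - zr @ zf.T
    logits = -dist / tau
    shifted = logits - logits.max(1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(1)) + logits.max(1)
    loss = float(np.mean(lse - np.diag(logits)))
    soft = np.exp(logits - lse[:, None])
    dlogits = (soft - np.eye(B)) / B
    dzr = (dlogits @ zf) / tau
    dzf = (dlogits.T @ zr) / tau
    return loss, dzr, dzf


# --------------------------------------------------------------------
# batch sampling and the training loop

def sample_training_batch(genome: ReferenceGenome, cfg: TrainConfig,
                          rng: np.random.Generator) -> list[tuple[str, str]]:
    """Draw B (read, fragment) positive pairs from the genome.

    Fragments are uniform-random slices with length ~ U(fragment_len_range);
    each read is a uniform-random slice *within* its fragment with length
    ~ U(read_len_range). A noise_read_fraction subset of reads receives
    substitution noise at a per-read rate drawn from noise_rate_range.
    """
    names = genome.names
    lengths = np.array([len(genome.chromosomes[n]) for n in names], dtype=float)
    if lengths.max() < cfg.fragment_len_range[1]:
        raise ValueError("genome chromosomes shorter than the maximum fragment length")
    usable = lengths >= cfg.fragment_len_range[1]
    weights = np.where(usable, lengths, 0.0)
    weights /= weights.sum()
    pairs: list[tuple[str, str]] = []
    for _ in range(cfg.batch_size):
        ci = int(rng.choice(len(names), p=weights))
        chrom_seq = genome.chromosomes[names[ci]]
        flen = int(rng.integers(cfg.fragment_len_range[0], cfg.fragment_len_range[1] + 1))
        fstart = int(rng.integers(0, len(chrom_seq) - flen + 1))
        frag = chrom_seq[fstart : fstart + flen]
        rlen = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
        rstart = int(rng.integers(0, flen - rlen + 1))
        read = frag[rstart : rstart + rlen]
        if rng.random() < cfg.noise_read_fraction:
            rate = rng.uniform(*cfg.noise_rate_range)
            chars = list(read)
            for i in np.flatnonzero(rng.random(rlen) < rate):
                chars[i] = ALPHABET.replace(chars[i], "")[rng.integers(0, 3)]
            read = "".join(chars)
        pairs.append((read, frag))
    return pairs


def one_cycle_lr(step: int, cfg: TrainConfig) -> float:
    """Linear warmup to peak_lr, then cosine anneal to final_lr_frac*peak."""
    warmup = max(1, int(cfg.warmup_frac * cfg.steps))
    if step < warmup:
        return cfg.peak_lr * (step + 1) / warmup
    frac = (step - warmup) / max(1, cfg.steps - warmup)
    floor = cfg.peak_lr * cfg.final_lr_frac
    return floor + 0.5 * (cfg.peak_lr - floor) * (1.0 + np.cos(np.pi * frac))


def train(
    genome: ReferenceGenome,
    tokenizer: DnaTokenizer,
    encoder_config: EncoderConfig,
    train_config: TrainConfig,
    callback: Callable[[int, float], None] | None = None,
) -> tuple[RdeEncoder, list[float]]:
    """Contrastive training loop (Adam, one-cycle cosine schedule).

    Reads and fragments pass through the same weights but through separate
    forward calls, so they receive independently sampled dropout masks.
    Within each group, shorter sequences are padded to the batch max
    length under an attention mask. Returns the trained encoder and the
    per-micro-batch loss trace.
    """
    enc = RdeEncoder(encoder_config, tokenizer, seed=train_config.seed)
    rng = np.random.default_rng(train_config.seed + 1)
    beta1, beta2, eps = 0.9, train_config.adam_beta2, 1e-8
    m = {k: np.zeros_like(v, dtype=np.float64) for k, v in enc.params.items()}
    v = {k: np.zeros_like(val, dtype=np.float64) for k, val in enc.params.items()}
    trace: list[float] = []
    t_adam = 0
    for step in range(train_config.steps):
        accum: dict[str, np.ndarray] = {k: np.zeros_like(val, dtype=np.float64)
                                        for k, val in enc.params.items()}
        for _ in range(train_config.grad_accum):
            pairs = sample_training_batch(genome, train_config, rng)
            reads = [r for r, _ in pairs]
            frags = [f for _, f in pairs]
            # fragments are forwarded in two length-sorted halves so padding
            # is local to each half; the loss still couples all B pairs
            order = np.argsort([len(f) for f in frags])
            halves = [order[: len(order) // 2], order[len(order) // 2:]]
            zr, cache_r = enc._forward(*enc._prepare(reads), train=True, rng=rng)
            zf = np.empty((len(frags), zr.shape[1]), dtype=zr.dtype)
            caches_f = []
            for half in halves:
                zh, ch = enc._forward(*enc._prepare([frags[i] for i in half]),
                                      train=True, rng=rng)
                zf[half] = zh
                caches_f.append(ch)
            loss, dzr, dzf = _loss_and_grads(zr, zf, train_config.temperature)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at step {step}: loss={loss}")
            trace.append(loss)
            grads = [enc._backward(cache_r, dzr.astype(zr.dtype))]
            for half, ch in zip(halves, caches_f):
                grads.append(enc._backward(ch, dzf[half].astype(zf.dtype)))
            for g in grads:
                for k in accum:
                    accum[k] += g[k]
        lr = one_cycle_lr(step, train_config)
        t_adam += 1
        if train_config.grad_clip > 0:
            gnorm = np.sqrt(sum(float((a * a).sum()) for a in accum.values())) / train_config.grad_accum
            clip = min(1.0, train_config.grad_clip / max(gnorm, 1e-12))
        else:
            clip = 1.0
        for k, param in enc.params.items():
            gk = accum[k] * (clip / train_config.grad_accum)
            m[k] = beta1 * m[k] + (1 - beta1) * gk
            v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
            mhat = m[k] / (1 - beta1 ** t_adam)
            vhat = v[k] / (1 - beta2 ** t_adam)
            param -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(param.dtype)
        if callback is not None:
            callback(step, float(np.mean(trace[-train_config.grad_accum:])))
    return enc, trace


def retrieval_accuracy(encoder: RdeEncoder, pairs: Sequence[tuple[str, str]],
                       batch_size: int = 64) -> float:
    """Top-1 accuracy of matching each read to its own fragment by cosine."""
    reads = [r for r, _ in pairs]
    frags = [f for _, f in pairs]

    def batched(seqs):
        return np.vstack([encoder.embed_batch(seqs[i : i + batch_size])
                          for i in range(0, len(seqs), batch_size)])

    zr = batched(reads)
    zf = batched(frags)
    pred = (zr @ zf.T).argmax(1)
    return float(np.mean(pred == np.arange(len(pairs))))
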