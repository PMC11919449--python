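"""Shared test utilities: deterministic sequences and an independent SW oracle."""

import numpy as np

from esalign.align import ScoringScheme


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def brute_force_score(read: str, frag: str, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Independent affine-gap local-alignment DP (maximize negated scores).

    Plain-python Gotoh recursion with none of the implementation's integer
    scaling or origin bookkeeping; returns the minimum (best) score.
    """
    ma, mi = -scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    Q, L = len(read), len(frag)
    NEG = float("-inf")
    H = [[0.0] * (L + 1) for _ in range(Q + 1)]
    E = [[NEG] * (L + 1) for _ in range(Q + 1)]
    F = [[NEG] * (L + 1) for _ in range(Q + 1)]
    best = 0.0
    for i in range(1, Q + 1):
        for j in range(1, L + 1):
            E[i][j] = max(H[i - 1][j] - go, E[i - 1][j] - ge)
            F[i][j] = max(H[i][j - 1] - go, F[i][j - 1] - ge)
            sub = ma if read[i - 1] == frag[j - 1] else -mi
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return -best
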