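"""Smith-Waterman fine alignment under a minimization scoring convention.

The scheme follows the lower-is-better convention: match -2, mismatch +1,
gap open +0.5 (charged on the first gap base), gap extension +0.1 per
subsequent base. A perfect full-length match of a read of length Q scores
m*Q = -2Q; the normalized optimality gap

    d_SW = (v* - m*Q) / ((n - m) * Q)

is 0 for a perfect match and grows with the alignment's distance from
optimal. Internally the DP maximizes the negated scores, scaled to
integers (the default scheme is exact in tenths), which makes scores and
tie-breaking exact — no floating-point path ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from numba import njit

from esalign.index import Fragment
from esalign.reference import reverse_complement

_BASE_ORD = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_ORD[ord(_b)] = _i


def _seq_to_arr(seq: str) -> np.ndarray:
    arr = _BASE_ORD[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment penalties, lower-is-better.

    ``match`` must be negative, ``mismatch`` and the gap penalties
    non-negative. Values must be exact multiples of 1/1000 so the DP can
    run on scaled integers.
    """

    match: float = -2.0
    mismatch: float = 1.0
    gap_open: float = 0.5
    gap_extend: float = 0.1

    def __post_init__(self) -> None:
        if not (self.match < 0 <= self.mismatch):
            raise ValueError("require match < 0 <= mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @property
    def _scale(self) -> int:
        for scale in (1, 10, 100, 1000):
            if all(abs(v * scale - round(v * scale)) < 1e-9
                   for v in (self.match, self.mismatch, self.gap_open, self.gap_extend)):
                return scale
        raise ValueError("scheme values must be exact multiples of 1/1000")

    def _scaled(self) -> tuple[int, int, int, int, int]:
        """(scale, match_gain, mismatch_pen, open_pen, extend_pen), all >= 0.

        Maximization view: a match adds ``match_gain``; mismatches and gaps
        subtract their penalty.
        """
        s = self._scale
        return (s, -round(self.match * s), round(self.mismatch * s),
                round(self.gap_open * s), round(self.gap_extend * s))


@njit(cache=False)
def _sw_score_only(read, frag, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    """Score-only affine-gap local alignment with rolling rows (int32).

    Used to scan candidate slates; the full origin-tracking DP runs only on
    the winning fragment. Scores fit comfortably in int32 for read lengths
    up to ~10^5 at the default scheme.
    """
    Q = len(read)
    L = len(frag)
    NEG = np.int32(-(1 << 28))
    ma = np.int32(match)
    mi = np.int32(mismatch)
    go = np.int32(gap_open)
    ge = np.int32(gap_ext)
    zero = np.int32(0)
    h_prev = np.zeros(L + 1, dtype=np.int32)
    h_cur = np.zeros(L + 1, dtype=np.int32)
    e_row = np.full(L + 1, NEG, dtype=np.int32)
    best = zero
    for i in range(1, Q + 1):
        f = NEG
        h_cur[0] = zero
        ri = read[i - 1]
        diag = h_prev[0]
        for j in range(1, L + 1):
            e = max(h_prev[j] - go, e_row[j] - ge)
            f = max(h_cur[j - 1] - go, f - ge)
            sub = ma if ri == frag[j - 1] else -mi
            h = diag + sub
            diag = h_prev[j]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < zero:
                h = zero
            h_cur[j] = h
            e_row[j] = e
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


@njit(cache=False)
def _sw_core(read, frag, match, mismatch, gap_open, gap_ext, traceback):  # pragma: no cover
    """Affine-gap local alignment, maximization on scaled integers.

    Tracks for every cell the fragment column where its local path began,
    preferring the smallest origin on score ties, so the reported offset
    is the deterministic smallest-offset optimum. Returns
    (best_score, origin, end_i, end_j, ptr) where ptr is the traceback
    pointer matrix (only populated when ``traceback`` is True).
    """
    Q = len(read)
    L = len(frag)
    NEG = np.int64(-(1 << 60))
    H = np.zeros((Q + 1, L + 1), dtype=np.int64)
    E = np.full((Q + 1, L + 1), NEG, dtype=np.int64)   # gap in fragment (read base vs -)
    F = np.full((Q + 1, L + 1), NEG, dtype=np.int64)   # gap in read (- vs fragment base)
    oh = np.zeros((Q + 1, L + 1), dtype=np.int32)
    oe = np.zeros((Q + 1, L + 1), dtype=np.int32)
    of = np.zeros((Q + 1, L + 1), dtype=np.int32)
    # ptr codes: 0 stop, 1 diag from H, 2 from E, 3 from F
    # pe codes: 0 E opened from H, 1 E extended; pf likewise
    if traceback:
        ptr = np.zeros((Q + 1, L + 1), dtype=np.int8)
        pe = np.zeros((Q + 1, L + 1), dtype=np.int8)
        pf = np.zeros((Q + 1, L + 1), dtype=np.int8)
    else:
        ptr = np.zeros((1, 1), dtype=np.int8)
        pe = ptr
        pf = ptr
    best = np.int64(0)
    best_origin = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, Q + 1):
        for j in range(1, L + 1):
            # E: read base i aligned to gap
            e_open = H[i - 1, j] - gap_open
            e_ext = E[i - 1, j] - gap_ext
            if e_ext > e_open or (e_ext == e_open and oe[i - 1, j] < oh[i - 1, j]):
                E[i, j] = e_ext
                oe[i, j] = oe[i - 1, j]
                if traceback:
                    pe[i, j] = 1
            else:
                E[i, j] = e_open
                oe[i, j] = oh[i - 1, j]
                if traceback:
                    pe[i, j] = 0
            # F: fragment base j aligned to gap
            f_open = H[i, j - 1] - gap_open
            f_ext = F[i, j - 1] - gap_ext
            if f_ext > f_open or (f_ext == f_open and of[i, j - 1] < oh[i, j - 1]):
                F[i, j] = f_ext
                of[i, j] = of[i, j - 1]
                if traceback:
                    pf[i, j] = 1
            else:
                F[i, j] = f_open
                of[i, j] = oh[i, j - 1]
                if traceback:
                    pf[i, j] = 0
            sub = match if read[i - 1] == frag[j - 1] else -mismatch
            diag = H[i - 1, j - 1] + sub
            # origin of a diagonal step: fresh start when the incoming H is 0
            # and its own path is empty (origin sentinel handled via score>0)
            diag_origin = oh[i - 1, j - 1] if H[i - 1, j - 1] > 0 else np.int32(j - 1)
            # choose max(0, diag, E, F); ties prefer smaller origin, then diag
            bestv = np.int64(0)
            bestc = np.int8(0)
            besto = np.int32(j)
            if diag > bestv or (diag == bestv and diag > 0 and diag_origin < besto):
                bestv = diag
                bestc = np.int8(1)
                besto = diag_origin
            if E[i, j] > bestv or (E[i, j] == bestv and bestv > 0 and oe[i, j] < besto):
                bestv = E[i, j]
                bestc = np.int8(2)
                besto = oe[i, j]
            if F[i, j] > bestv or (F[i, j] == bestv and bestv > 0 and of[i, j] < besto):
                bestv = F[i, j]
                bestc = np.int8(3)
                besto = of[i, j]
            H[i, j] = bestv
            oh[i, j] = besto if bestv > 0 else np.int32(j)
            if traceback:
                ptr[i, j] = bestc if bestv > 0 else np.int8(0)
            if bestv > best or (bestv == best and bestv > 0 and (
                    besto < best_origin or (besto == best_origin and (j < best_j or (j == best_j and i < best_i))))):
                best = bestv
                best_origin = besto
                best_i = i
                best_j = j
    return best, best_origin, best_i, best_j, ptr, pe, pf


@dataclass
class SwAlignment:
    """Result of aligning a read against one fragment sequence."""

    score: float          # v*, minimization convention (lower is better)
    offset: int           # 0-based start of the aligned region in the fragment
    end: int              # 0-based exclusive end of the aligned region
    read_start: int = 0   # first aligned read base (soft-clip boundary)
    read_end: int = 0
    cigar: str | None = None


def _traceback_cigar(ptr, pe, pf, best_i, best_j, Q) -> tuple[int, int, str]:
    """Recover (read_start, read_end, cigar-with-softclips) from pointers."""
    ops: list[str] = []
    i, j = best_i, best_j
    state = 0  # 0 = in H
    while i > 0 and j > 0:
        if state == 0:
            code = ptr[i, j]
            if code == 0:
                break
            if code == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif code == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            ops.append("I")
            if pe[i, j] == 0:
                state = 0
            i -= 1
        else:
            ops.append("D")
            if pf[i, j] == 0:
                state = 0
            j -= 1
    read_start, read_end = i, best_i
    ops.reverse()
    parts: list[str] = []
    if read_start:
        parts.append(f"{read_start}S")
    k = 0
    while k < len(ops):
        run = k
        while run < len(ops) and ops[run] == ops[k]:
            run += 1
        parts.append(f"{run - k}{ops[k]}")
        k = run
    if Q - read_end:
        parts.append(f"{Q - read_end}S")
    return read_start, read_end, "".join(parts)


def sw_align(read: str, fragment_seq: str, scheme: ScoringScheme = ScoringScheme(),
             traceback: bool = False) -> SwAlignment:
    """Locally align ``read`` to ``fragment_seq``, minimizing the score.

    Returns the minimum score v* and the 0-based fragment offset where the
    aligned region begins; score ties resolve to the smallest offset. With
    ``traceback=True`` the CIGAR (soft-clipped read ends) is also built.
    """
    if not read or not fragment_seq:
        raise ValueError("sequences must be non-empty")
    scale, match, mismatch, gap_open, gap_ext = scheme._scaled()
    r = _seq_to_arr(read)
    f = _seq_to_arr(fragment_seq)
    best, origin, bi, bj, ptr, pe, pf = _sw_core(r, f, match, mismatch, gap_open, gap_ext, traceback)
    result = SwAlignment(score=float(-Fraction(int(best), scale)), offset=int(origin), end=int(bj))
    if traceback:
        rs, re, cigar = _traceback_cigar(ptr, pe, pf, bi, bj, len(read))
        result.read_start, result.read_end, result.cigar = rs, re, cigar
    else:
        result.read_end = len(read)
    return result


def compute_d_sw(v_star: float, Q: int, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Normalized gap between v* and the perfect-match score m*Q."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    m, n = scheme.match, scheme.mismatch
    return (v_star - m * Q) / ((n - m) * Q)


@dataclass
class AlignmentResult:
    """Best fine alignment of a read over a slate of retrieved fragments."""

    fragment: Fragment
    v_star: float
    offset: int            # q|F*, 0-based within the fragment
    chrom: str
    global_pos: int        # q* = q|F* + q_{F*|R}, 0-based
    d_sw: float
    strand: str = "+"
    tie: bool = False      # another fragment position achieved the same v*
    cigar: str | None = None
    read_start: int = 0
    read_end: int = 0


def best_alignment(
    read_seq: str,
    hits: Sequence[tuple[Fragment, float]] | Sequence[Fragment],
    scheme: ScoringScheme = ScoringScheme(),
    search_revcomp: bool = False,
    chrom_order: Sequence[str] | None = None,
    traceback: bool = True,
) -> AlignmentResult:
    """Align a read against every retrieved fragment and keep the optimum.

    All (fragment, orientation) alignments are independent; the minimum v*
    wins, with ties broken by (chromosome order, global position, strand).
    Tied distinct genomic positions are flagged on the result.
    """
    frags = [h[0] if isinstance(h, tuple) else h for h in hits]
    if not frags:
        raise ValueError("empty hit list")
    if chrom_order is None:
        seen: dict[str, int] = {}
        for fr in frags:
            seen.setdefault(fr.chrom, len(seen))
        chrom_rank = seen
    else:
        chrom_rank = {c: i for i, c in enumerate(chrom_order)}

    Q = len(read_seq)
    queries = [("+", read_seq)]
    if search_revcomp:
        queries.append(("-", reverse_complement(read_seq)))
    scale, match, mismatch, gap_open, gap_ext = scheme._scaled()
    # fast score-only scan of the slate; the origin-tracking DP runs only on
    # the minimum-score candidates to resolve offsets and ties
    scored = []
    for strand, query in queries:
        q_arr = _seq_to_arr(query)
        for fr in frags:
            raw = _sw_score_only(q_arr, _seq_to_arr(fr.seq), match, mismatch, gap_open, gap_ext)
            scored.append((int(raw), fr, strand, query))
    best_raw = max(s for s, _, _, _ in scored)
    candidates = []
    for raw, fr, strand, query in scored:
        if raw != best_raw:
            continue
        aln = sw_align(query, fr.seq, scheme, traceback=False)
        global_pos = fr.start + aln.offset
        candidates.append(((chrom_rank[fr.chrom], global_pos, strand), fr, aln, strand, global_pos))
    candidates.sort(key=lambda c: c[0])
    _, frag, aln, strand, global_pos = candidates[0]
    v_star = aln.score
    tie = any(c[4] != global_pos or c[1].chrom != frag.chrom for c in candidates[1:])
    result = AlignmentResult(
        fragment=frag, v_star=v_star, offset=aln.offset, chrom=frag.chrom,
        global_pos=global_pos, d_sw=compute_d_sw(v_star, Q, scheme), strand=strand)
    result.tie = tie
    if traceback:
        query = read_seq if strand == "+" else reverse_complement(read_seq)
        full = sw_align(query, frag.seq, scheme, traceback=True)
        result.cigar = full.cigar
        result.read_start, result.read_end = full.read_start, full.read_end
    return result


def write_sam(results, reads, genome, path) -> None:
    """Write one SAM record per read (1-based POS; v* and d_SW as tags).

    ``results`` may contain None for unaligned reads, which are flagged
    per SAM convention. Reverse-strand hits store the reverse-complement
    of the read sequence, as SAM requires.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, result in zip(reads, results):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            if result is None:
                rec.is_unmapped = True
                rec.query_sequence = read.seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.qualities))
                out.write(rec)
                continue
            seq = read.seq
            quals = list(read.qualities)
            if result.strand == "-":
                rec.is_reverse = True
                seq = reverse_complement(seq)
                quals = quals[::-1]
            rec.query_sequence = seq
            rec.query_qualities = quals
            rec.reference_id = genome.names.index(result.chrom)
            rec.reference_start = result.global_pos  # pysam is 0-based; SAM text gets POS+1
            rec.cigarstring = result.cigar
            rec.mapping_quality = 255
            rec.set_tag("ZS", float(result.v_star), "f")
            rec.set_tag("ZD", float(result.d_sw), "f")
            if result.tie:
                rec.set_tag("ZT", 1, "i")
            out.write(rec)
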