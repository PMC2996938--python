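"""Alignment primitives: ungapped local scoring and a small Smith-Waterman.

The pipeline needs three flavours of local alignment, all on very short
sequences (reads are 36 nt, oligos and primers 20-62 nt):

* ungapped local alignment of a read against an oligo (adapter screening and
  the primer-binding-site scan) -- the best-scoring contiguous diagonal
  segment, equivalent to a maximum-subarray over per-position match scores;
* affine-gap Smith-Waterman (element-motif validation; the configured gap
  costs effectively forbid gaps, but the operation is defined with them);
* exact k-mer machinery (rolling codes) used by the read mapper and the
  duplication scanner.

Everything is vectorised with numpy; batch entry points exist where the
pipeline screens many reads against one oligo.
"""

from __future__ import annotations

import numpy as np

# A,C,G,T -> 0..3; anything else (N, lowercase is upcased first) -> 4, which
# never matches and never forms a valid k-mer.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_batch(seqs: list[str]) -> np.ndarray:
    """Encode equal-length strings as an (n, L) uint8 matrix."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    joined = "".join(seqs)
    arr = _ENC[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return arr.reshape(len(seqs), -1)


def ungapped_best_scores(
    reads: np.ndarray, oligo: np.ndarray, match: int = 5, mismatch: int = -4
) -> np.ndarray:
    """Best ungapped local alignment score of each read row against ``oligo``.

    For every diagonal of the (read x oligo) comparison the best contiguous
    segment score is found by the prefix-sum/running-minimum identity
    ``max_{i<j} sum(s[i:j]) = max_j (P[j] - min_{i<=j} P[i])``; the result is
    the maximum over diagonals.  Scores below 0 report as 0 (empty alignment).
    """
    n, L = reads.shape
    m = oligo.shape[0]
    best = np.zeros(n, dtype=np.int64)
    for t in range(-(L - 1), m):
        lo = max(0, -t)
        hi = min(L, m - t)
        if hi <= lo:
            continue
        seg = np.where(reads[:, lo:hi] == oligo[lo + t : hi + t], match, mismatch)
        p = np.zeros((n, hi - lo + 1), dtype=np.int64)
        np.cumsum(seg, axis=1, out=p[:, 1:])
        runmin = np.minimum.accumulate(p[:, :-1], axis=1)
        np.maximum(best, (p[:, 1:] - runmin).max(axis=1), out=best)
    return best


def ungapped_local_score(a: str, b: str, match: int = 5, mismatch: int = -4) -> int:
    """Best ungapped local alignment score between two sequences."""
    return int(ungapped_best_scores(encode(a)[None, :], encode(b), match, mismatch)[0])


def best_segment_on_diagonal(
    scores: np.ndarray,
) -> tuple[int, int, int]:
    """Maximum-subarray (score, start, end_exclusive) of a per-position score array."""
    best = 0
    best_lo = best_hi = 0
    cur = 0
    cur_lo = 0
    for j, s in enumerate(scores.tolist()):
        if cur <= 0:
            cur = s
            cur_lo = j
        else:
            cur += s
        if cur > best:
            best, best_lo, best_hi = cur, cur_lo, j + 1
    return best, best_lo, best_hi


def smith_waterman(
    a: str,
    b: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = 64,
    gap_extend: int = 8,
) -> int:
    """Affine-gap Smith-Waterman score between two short sequences.

    A gap of length ``L`` costs ``gap_open + L * gap_extend`` (the first
    gapped position pays both the opening and the extension cost, matching
    Bio.Align.PairwiseAligner with ``open_gap_score = -(gap_open+gap_extend)``
    and ``extend_gap_score = -gap_extend``).
    """
    ea, eb = encode(a), encode(b)
    n, m = len(ea), len(eb)
    neg = -(10**9)
    h_prev = np.zeros(m + 1, dtype=np.int64)
    e_prev = np.full(m + 1, neg, dtype=np.int64)  # gap in a (vertical)
    best = 0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1, dtype=np.int64)
        e_cur = np.full(m + 1, neg, dtype=np.int64)
        f = neg  # gap in b (horizontal), scalar along the row
        ai = ea[i - 1]
        for j in range(1, m + 1):
            s = match if ai == eb[j - 1] and ai != 4 else mismatch
            e_cur[j] = max(h_prev[j] - first_gap, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - first_gap, f - gap_extend)
            h = max(0, h_prev[j - 1] + s, e_cur[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return int(best)


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-4 codes of all k-mers of an encoded sequence.

    Returns ``(codes, valid)`` where ``valid[i]`` is False when the window
    contains a non-ACGT base.  Requires ``k <= 31`` (codes fit in uint64).
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = enc.shape[0] - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        codes = codes * np.uint64(4) + np.minimum(enc[i : i + n], 3).astype(np.uint64)
    bad = np.concatenate([[0], np.cumsum(enc == 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid
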