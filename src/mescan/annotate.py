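"""Primer-binding-site scanning, locus classification and locus-list utilities.

``scan_pbs`` finds every ungapped local match of a primer in the reference
(both strands), seeded by exact 7-mers and extended to the maximal-scoring
segment -- the classic word-seeded, gap-free scan.  Sites carry the number
of mismatches in the primer's 3' 10 bases, the quantity that governs whether
a locus amplifies efficiently.

From sequencing-PBS sites the expected 36-nt junction-read endpoint is
computed and matched (+/-3 bp) against called loci, attaching the element
annotation track; loci then fall into three classes: present in the
reference as the target subfamily, present as another (non-specifically
amplified) family, or absent from the reference (novel insertions).

``select_fixed_loci`` reproduces the putatively-fixed locus criteria: both
PBS present with sufficient scores, start positions separated by 224 +/- 15
bp, same orientation, sequencing PBS 3' of the amplification PBS, no
mismatches in either 3' 10 bp, and not on the known-polymorphic list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import best_segment_on_diagonal, encode, kmer_codes
from .oligos import revcomp

AMPLIFICATION = "AMPLIFICATION"
SEQUENCING = "SEQUENCING"

KNOWN_TARGET = "KNOWN_TARGET"
NONSPECIFIC = "NONSPECIFIC"
NOVEL = "NOVEL"

#: default ungapped scoring for the PBS scan (legacy word-seeded gap-free scan)
PBS_MATCH = 1
PBS_MISMATCH = -3


@dataclass(frozen=True)
class PrimerSite:
    chrom: str
    start: int  # 1-based closed, best-scoring segment
    end: int
    strand: str
    score: int
    mismatches_in_3prime_10: int
    role: str
    footprint_start: int = 0  # full primer placement on the reference
    footprint_end: int = 0

    @property
    def predicted_endpoint(self) -> int:
        """Reference position of the last base of the 36-nt read this PBS primes."""
        if self.strand == "+":
            return self.footprint_end + 36
        return self.footprint_start - 36


@dataclass(frozen=True)
class FixedLocusParams:
    """Criteria for putatively fixed, retrievable insertion loci.

    Score thresholds are on the internal raw ungapped scale (match +1,
    mismatch -3): the defaults allow at most one mismatch over the 20-nt
    amplification PBS and the 27-nt sequencing PBS respectively.  Spacing is
    measured between plus-strand start coordinates, bounds inclusive.
    """

    amp_min_score: float = 16.0
    seq_min_score: float = 22.0
    spacing_center: int = 224
    spacing_tol: int = 15
    require_same_orientation: bool = True
    require_seq_downstream: bool = True
    max_3prime_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.spacing_tol < 0:
            raise ValueError("spacing tolerance must be >= 0")


def scan_pbs(
    sequences: dict[str, str],
    primer: str,
    role: str = SEQUENCING,
    match: int = PBS_MATCH,
    mismatch: int = PBS_MISMATCH,
    min_score: int = 18,
    word_size: int = 7,
) -> list[PrimerSite]:
    """All ungapped local matches of ``primer`` on both strands of the reference.

    Candidate placements are seeded by shared exact ``word_size``-mers and
    each distinct diagonal is scored once; the maximal-scoring contiguous
    segment is reported when it reaches ``min_score``.  The 3'-window
    mismatch count compares the primer's last 10 bases with the reference at
    the full-primer placement; positions off the chromosome end count as
    mismatches.
    """
    m = len(primer)
    if m < word_size:
        raise ValueError("primer shorter than word size")
    sites: list[PrimerSite] = []
    for strand in ("+", "-"):
        pseq = primer if strand == "+" else revcomp(primer)
        penc = encode(pseq)
        pcodes, pvalid = kmer_codes(penc, word_size)
        lookup: dict[int, list[int]] = {}
        for off, (code, ok) in enumerate(zip(pcodes.tolist(), pvalid.tolist())):
            if ok:
                lookup.setdefault(code, []).append(off)
        for chrom, seq in sequences.items():
            enc = encode(seq)
            codes, valid = kmer_codes(enc, word_size)
            cand = np.nonzero(valid & np.isin(codes, np.fromiter(lookup, dtype=np.uint64)))[0]
            diagonals: set[int] = set()
            for p in cand.tolist():
                for off in lookup[codes[p]]:
                    diagonals.add(p - off)  # 0-based placement of primer base 0
            for d in sorted(diagonals):
                site = _score_diagonal(chrom, enc, penc, d, strand, m, match, mismatch, min_score, role)
                if site is not None:
                    sites.append(site)
    sites.sort(key=lambda s: (s.chrom, s.footprint_start, s.strand))
    return sites


def _score_diagonal(
    chrom, enc, penc, d, strand, m, match, mismatch, min_score, role
) -> PrimerSite | None:
    n = enc.shape[0]
    lo = max(0, -d)
    hi = min(m, n - d)
    if hi <= lo:
        return None
    ref_seg = enc[d + lo : d + hi]
    pos_scores = np.where(ref_seg == penc[lo:hi], match, mismatch)
    score, seg_lo, seg_hi = best_segment_on_diagonal(pos_scores)
    if score < min_score:
        return None
    # mismatches in the primer's 3' 10 bases over the full placement
    if strand == "+":
        three_prime = range(m - 10, m)  # primer-as-written positions
    else:
        # the reverse-complemented primer's 3' end sits at the low plus-coordinate
        three_prime = range(0, 10)
    mm = 0
    for p in three_prime:
        rp = d + p
        if rp < 0 or rp >= n or enc[rp] != penc[p] or penc[p] == 4:
            mm += 1
    start = d + lo + seg_lo + 1  # back to 1-based
    end = d + lo + seg_hi
    return PrimerSite(
        chrom, start, end, strand, int(score), mm, role, d + 1, d + m
    )


def brute_force_scan(
    sequences: dict[str, str],
    primer: str,
    match: int = PBS_MATCH,
    mismatch: int = PBS_MISMATCH,
    min_score: int = 18,
) -> list[tuple[str, int, str, int]]:
    """Oracle scan: score *every* offset; returns (chrom, footprint_start, strand, score).

    Uses the prefix-sum formulation of the best ungapped segment, vectorised
    over offsets, with no seeding -- independent of the seeded scanner's path.
    """
    out = []
    m = len(primer)
    for strand in ("+", "-"):
        pseq = primer if strand == "+" else revcomp(primer)
        penc = encode(pseq)
        for chrom, seq in sequences.items():
            enc = encode(seq)
            n = enc.shape[0] - m + 1
            if n <= 0:
                continue
            view = np.lib.stride_tricks.sliding_window_view(enc, m)
            s = np.where(view == penc, match, mismatch)
            p = np.concatenate([np.zeros((s.shape[0], 1), dtype=np.int64), np.cumsum(s, axis=1)], axis=1)
            runmin = np.minimum.accumulate(p[:, :-1], axis=1)
            best = (p[:, 1:] - runmin).max(axis=1)
            for off in np.nonzero(best >= min_score)[0]:
                out.append((chrom, int(off) + 1, strand, int(best[off])))
    return sorted(out)


@dataclass
class AnnotatedSite:
    site: PrimerSite
    family: str | None  # track family containing the site, if any
    predicted_endpoint: int


def link_pbs_to_track(
    sites: Sequence[PrimerSite],
    me_track: Sequence,
    position_tol: int = 3,
) -> list[AnnotatedSite]:
    """Attach the containing track element (if any) to each PBS site.

    A site is linked to an element whose interval contains the site's
    footprint start within ``position_tol`` bp of slack at the boundaries.
    """
    out = []
    for s in sites:
        family = None
        for e in me_track:
            if (
                e.chrom == s.chrom
                and e.start - position_tol <= s.footprint_start
                and s.footprint_end <= e.end + position_tol
            ):
                family = e.family
                break
        out.append(AnnotatedSite(s, family, s.predicted_endpoint))
    return out


def classify_loci(
    called_loci: Sequence,
    annotated_sites: Sequence[AnnotatedSite],
    target_family: str = "target",
    position_tol: int = 3,
) -> dict[str, str]:
    """Map each called locus to exactly one class.

    A locus matching an annotated sequencing-PBS endpoint within the
    tolerance is KNOWN_TARGET when the linked element family is the target
    subfamily, NONSPECIFIC when it is any other family; all other loci are
    NOVEL (no linkage to the reference annotation).
    """
    classes: dict[str, str] = {}
    by_chrom: dict[str, list[AnnotatedSite]] = {}
    for a in annotated_sites:
        by_chrom.setdefault(a.site.chrom, []).append(a)
    for rec in called_loci:
        cls = NOVEL
        for a in by_chrom.get(rec.chrom, []):
            if abs(a.predicted_endpoint - rec.position) <= position_tol and a.family is not None:
                cls = KNOWN_TARGET if a.family == target_family else NONSPECIFIC
                break
        classes[rec.locus_id] = cls
    return classes


def select_fixed_loci(
    amp_sites: Sequence[PrimerSite],
    seq_sites: Sequence[PrimerSite],
    params: FixedLocusParams | None = None,
    polymorphic_list: Sequence[str] = (),
) -> list[str]:
    """Loci whose paired PBS meet all fixed-locus criteria; returns locus ids.

    The locus id is ``chrom:endpoint`` where endpoint is the predicted
    junction-read endpoint of the qualifying sequencing PBS.
    """
    if params is None:
        params = FixedLocusParams()
    poly = set(polymorphic_list)
    lo = params.spacing_center - params.spacing_tol
    hi = params.spacing_center + params.spacing_tol
    selected: list[str] = []
    amp_by_chrom: dict[str, list[PrimerSite]] = {}
    for a in amp_sites:
        amp_by_chrom.setdefault(a.chrom, []).append(a)
    for s in seq_sites:
        if s.score < params.seq_min_score or s.mismatches_in_3prime_10 > params.max_3prime_mismatches:
            continue
        for a in amp_by_chrom.get(s.chrom, []):
            if a.score < params.amp_min_score or a.mismatches_in_3prime_10 > params.max_3prime_mismatches:
                continue
            if params.require_same_orientation and a.strand != s.strand:
                continue
            sep = abs(s.footprint_start - a.footprint_start)
            if not lo <= sep <= hi:
                continue
            if params.require_seq_downstream:
                if s.strand == "+" and not s.footprint_start > a.footprint_start:
                    continue
                if s.strand == "-" and not s.footprint_start < a.footprint_start:
                    continue
            locus = f"{s.chrom}:{s.predicted_endpoint}"
            if locus not in poly:
                selected.append(locus)
            break
    return sorted(set(selected))


class DuplicationScanner:
    """Detect near-identical copies of a locus's upstream window elsewhere.

    Seeds with exact 31-mers against a cached genome-wide index and verifies
    candidate placements by full-window identity (matches / window length,
    ungapped), on both strands.
    """

    def __init__(self, sequences: dict[str, str], seed_len: int = 31):
        self.sequences = sequences
        self.seed_len = seed_len
        self.chroms = list(sequences)
        parts = [encode(sequences[c]) for c in self.chroms]
        self.lengths = np.array([p.shape[0] for p in parts], dtype=np.int64)
        self.starts = np.concatenate([[0], np.cumsum(self.lengths)])
        self.enc = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        codes, valid = kmer_codes(self.enc, seed_len)
        for s in self.starts[1:-1]:
            valid[max(0, s - seed_len + 1) : s] = False
        pos = np.nonzero(valid)[0].astype(np.int64)
        order = np.argsort(codes[pos], kind="stable")
        self._codes = codes[pos][order]
        self._pos = pos[order]

    def _concat_offset(self, chrom: str, pos1: int) -> int:
        return int(self.starts[self.chroms.index(chrom)]) + pos1 - 1

    def has_duplicate(
        self, chrom: str, win_start: int, win_end: int, min_identity: float = 0.99
    ) -> bool:
        w = win_end - win_start + 1
        self_off = self._concat_offset(chrom, win_start)
        for flip in (False, True):
            window = self.sequences[chrom][win_start - 1 : win_end]
            if flip:
                window = revcomp(window)
            enc = encode(window)
            cand: set[int] = set()
            step = self.seed_len
            for off in range(0, w - self.seed_len + 1, step):
                codes, valid = kmer_codes(enc[off : off + self.seed_len], self.seed_len)
                if codes.size == 0 or not valid[0]:
                    continue
                code = codes[0]
                lo = np.searchsorted(self._codes, code, side="left")
                hi = np.searchsorted(self._codes, code, side="right")
                for p in self._pos[lo:hi].tolist():
                    cand.add(int(p) - off)
            for start in sorted(cand):
                if start < 0 or start + w > self.enc.shape[0]:
                    continue
                if not flip and abs(start - self_off) < w:
                    continue  # the window itself
                matches = int((self.enc[start : start + w] == enc).sum())
                if matches / w >= min_identity:
                    return True
        return False


def flag_upstream_duplication(
    sequences: dict[str, str] | DuplicationScanner,
    chrom: str,
    junction: int,
    strand: str,
    window: int = 500,
    min_identity: float = 0.99,
    scanner: DuplicationScanner | None = None,
) -> bool:
    """Is there a >=99%-identical copy of the 500 bp upstream of the insertion?

    "Upstream" is the flank side the junction read runs into: coordinates
    below the junction for a plus-sense element, above it for minus-sense.
    Raises when fewer than ``window`` bases exist on that side.
    """
    if scanner is None:
        scanner = sequences if isinstance(sequences, DuplicationScanner) else DuplicationScanner(sequences)
    if strand == "+":
        ws, we = junction - window, junction - 1
    else:
        ws, we = junction + 1, junction + window
    if ws < 1 or we > scanner.lengths[scanner.chroms.index(chrom)]:
        raise ValueError("fewer than `window` bases upstream of the locus")
    return scanner.has_duplicate(chrom, ws, we, min_identity)


def compare_locus_lists(
    list_a: Sequence[tuple[str, int]],
    list_b: Sequence[tuple[str, int]],
    tol: int = 50,
) -> tuple[int, list[tuple[str, int]], list[tuple[str, int]]]:
    """Greedy nearest-match pairing of two locus lists within ``tol`` bp.

    Candidate pairs on the same chromosome are taken in order of increasing
    positional distance; each locus matches at most once.  Returns
    (matched count, unmatched from a, unmatched from b).
    """
    pairs = []
    for i, (ca, pa) in enumerate(list_a):
        for j, (cb, pb) in enumerate(list_b):
            if ca == cb and abs(pa - pb) <= tol:
                pairs.append((abs(pa - pb), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
    un_a = [x for i, x in enumerate(list_a) if i not in used_a]
    un_b = [x for j, x in enumerate(list_b) if j not in used_b]
    return matched, un_a, un_b
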