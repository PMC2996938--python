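"""Read mapping, the dual intact/trimmed scheme, and pair-level filters.

The pipeline accepts alignments from any external aligner via SAM ingestion,
and also ships a small exact mapper (``GenomeIndex`` / ``toy_map``) sufficient
for desk-scale references: it reports *all* end-to-end alignments of a read
with at most ``max_subs`` substitutions, on both strands.  Completeness is
guaranteed by pigeonhole seeding -- the read is partitioned into
``max_subs + 1`` disjoint exact segments, at least one of which must match
the reference verbatim in any qualifying alignment.

Junction reads are mapped twice: intact (36 nt) and with the first 16 nt of
presumed element sequence trimmed off.  A pair that passes the filters when
intact comes from an element present in the reference (the trimmed result is
redundant and ignored); a pair that passes only after trimming is evidence
of an insertion absent from the reference.

Pair filters (in order): not properly paired; mapping quality 0 on either
read (multi-mapping); more than three mismatched or unmatched bases on
either read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .align import encode, kmer_codes
from .oligos import revcomp

INTACT = "INTACT"
TRIMMED = "TRIMMED"

OK = "OK"
NOT_PROPER = "NOT_PROPER"
MAPQ_ZERO = "MAPQ_ZERO"
EDIT_GT3 = "EDIT_GT3"

#: SAM flag pairs of a properly mapped pair (read1 flag, read2 flag)
PROPER_FLAG_PAIRS = {(99, 147), (147, 99), (83, 163), (163, 83)}

UNIQUE_MAPQ = 37

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    total = 0
    for n, op in _CIGAR_RE.findall(cigar):
        if op in _REF_CONSUMING:
            total += int(n)
    if total == 0:
        raise ValueError(f"CIGAR {cigar!r} consumes no reference bases")
    return total


@dataclass(frozen=True)
class MateAlignment:
    mapped: bool
    chrom: str = ""
    pos: int = 0  # 1-based leftmost (SAM POS)
    strand: str = "+"
    cigar: str = ""
    mapq: int = 0
    edit: int = 0  # mismatched + unmatched (clipped/indel) bases

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_reference_length(self.cigar) - 1


@dataclass(frozen=True)
class PairAlignment:
    junction: MateAlignment
    flank: MateAlignment
    properly_paired: bool
    mode: str  # INTACT | TRIMMED
    pair_id: str = ""
    junction_seq: str = ""  # untrimmed junction read sequence, if known


@dataclass(frozen=True)
class MappingVerdict:
    keep: bool
    reason: str

    @staticmethod
    def ok() -> "MappingVerdict":
        return MappingVerdict(True, OK)


def filter_pair(pair: PairAlignment, max_edit: int = 3) -> MappingVerdict:
    """Apply the pair-level filters in their canonical order."""
    if not pair.properly_paired or not (pair.junction.mapped and pair.flank.mapped):
        return MappingVerdict(False, NOT_PROPER)
    if pair.junction.mapq == 0 or pair.flank.mapq == 0:
        return MappingVerdict(False, MAPQ_ZERO)
    if pair.junction.edit > max_edit or pair.flank.edit > max_edit:
        return MappingVerdict(False, EDIT_GT3)
    return MappingVerdict.ok()


# ---------------------------------------------------------------------------
# internal mapper


@dataclass(frozen=True)
class ToyAlignment:
    chrom: str
    pos: int  # 1-based
    strand: str
    n_subs: int
    mapq: int
    cigar: str


class GenomeIndex:
    """Sorted k-mer-code index over a concatenated reference, per seed length."""

    def __init__(self, sequences: dict[str, str], max_seed: int = 12):
        self.max_seed = max_seed
        self.chroms = list(sequences)
        parts = [encode(sequences[c]) for c in self.chroms]
        self.lengths = np.array([p.shape[0] for p in parts], dtype=np.int64)
        self.starts = np.concatenate([[0], np.cumsum(self.lengths)])  # concat offsets
        self.enc = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._per_q: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _index_for(self, q: int) -> tuple[np.ndarray, np.ndarray]:
        if q not in self._per_q:
            codes, valid = kmer_codes(self.enc, q)
            # forbid seeds crossing chromosome boundaries
            for s in self.starts[1:-1]:
                valid[max(0, s - q + 1) : s] = False
            pos = np.nonzero(valid)[0].astype(np.int64)
            order = np.argsort(codes[pos], kind="stable")
            self._per_q[q] = (codes[pos][order], pos[order])
        return self._per_q[q]

    def seed_positions(self, code: int, q: int) -> np.ndarray:
        codes, pos = self._index_for(q)
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return pos[lo:hi]

    def locate(self, concat_pos: int) -> tuple[str, int]:
        """Concatenated offset -> (chrom, 1-based position)."""
        ci = int(np.searchsorted(self.starts, concat_pos, side="right")) - 1
        return self.chroms[ci], int(concat_pos - self.starts[ci] + 1)

    def chrom_span(self, concat_pos: int, length: int) -> bool:
        ci = int(np.searchsorted(self.starts, concat_pos, side="right")) - 1
        return concat_pos + length <= self.starts[ci + 1]


def toy_map(read: str, index: GenomeIndex, max_subs: int = 3) -> list[ToyAlignment]:
    """All end-to-end alignments of ``read`` with <= ``max_subs`` substitutions.

    The single best-scoring alignment receives mapping quality 37 when it is
    unique; when two or more alignments tie at the best substitution count,
    all alignments report quality 0 (the read is not uniquely placeable).
    """
    m = len(read)
    q = min(index.max_seed, m // (max_subs + 1))
    if q < 1:
        return []
    hits: list[tuple[int, str, int]] = []  # (concat start, strand, subs)
    for strand, seq in (("+", read), ("-", revcomp(read))):
        enc = encode(seq)
        codes, valid = kmer_codes(enc, q)
        sorted_codes, sorted_pos = index._index_for(q)
        cand_parts = []
        for blk in range(max_subs + 1):
            off = blk * q
            if off >= codes.shape[0] or not valid[off]:
                continue
            lo = np.searchsorted(sorted_codes, codes[off], side="left")
            hi = np.searchsorted(sorted_codes, codes[off], side="right")
            if hi > lo:
                cand_parts.append(sorted_pos[lo:hi] - off)
        if not cand_parts:
            continue
        starts = np.unique(np.concatenate(cand_parts))
        starts = starts[(starts >= 0) & (starts + m <= index.enc.shape[0])]
        if starts.size == 0:
            continue
        ci = np.searchsorted(index.starts, starts, side="right") - 1
        starts = starts[starts + m <= index.starts[ci + 1]]
        if starts.size == 0:
            continue
        windows = index.enc[starts[:, None] + np.arange(m)]
        subs = (windows != enc).sum(axis=1)
        ok = subs <= max_subs
        for s, ns in zip(starts[ok].tolist(), subs[ok].tolist()):
            hits.append((s, strand, ns))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    n_best = sum(1 for h in hits if h[2] == best)
    out = []
    for s, strand, ns in sorted(hits):
        chrom, pos = index.locate(s)
        mapq = UNIQUE_MAPQ if (ns == best and n_best == 1) else 0
        out.append(ToyAlignment(chrom, pos, strand, ns, mapq, f"{m}M"))
    return out


def best_alignment(alns: list[ToyAlignment]) -> ToyAlignment | None:
    """Deterministic representative: lowest substitution count, then coordinate."""
    if not alns:
        return None
    return min(alns, key=lambda a: (a.n_subs, a.chrom, a.pos, a.strand))


def _mate_from_toy(aln: ToyAlignment | None) -> MateAlignment:
    if aln is None:
        return MateAlignment(False)
    return MateAlignment(True, aln.chrom, aln.pos, aln.strand, aln.cigar, aln.mapq, aln.n_subs)


def _properly_paired(
    a: MateAlignment, b: MateAlignment, min_insert: int, max_insert: int
) -> bool:
    if not (a.mapped and b.mapped) or a.chrom != b.chrom or a.strand == b.strand:
        return False
    fwd, rev = (a, b) if a.strand == "+" else (b, a)
    if fwd.pos > rev.pos:
        return False
    span = rev.ref_end - fwd.pos + 1
    return min_insert <= span <= max_insert


@dataclass
class DualMapResult:
    intact: PairAlignment | None
    trimmed: PairAlignment | None
    intact_verdict: MappingVerdict | None
    trimmed_verdict: MappingVerdict | None
    accepted_mode: str | None  # INTACT, TRIMMED or None
    reason: str  # final verdict reason when nothing accepted

    @property
    def accepted(self) -> PairAlignment | None:
        if self.accepted_mode == INTACT:
            return self.intact
        if self.accepted_mode == TRIMMED:
            return self.trimmed
        return None


def dual_map(
    junction_seq: str,
    flank_seq: str,
    index: GenomeIndex,
    pair_id: str = "",
    trim_len: int = 16,
    max_subs: int = 3,
    min_insert: int = 100,
    max_insert: int = 1000,
) -> DualMapResult:
    """Map a pair under the intact/trimmed junction scheme and filter it.

    ``flank_seq`` must already have its index+'T' prefix trimmed.  When the
    intact mapping passes all filters the trimmed mapping is not attempted
    (it would be redundant); only pairs failing intact fall through to the
    trimmed mode, whose acceptance marks a non-reference insertion.

    Mate placement is pairing-aware: among all candidate alignments of the
    two mates, the properly-paired combination with the fewest substitutions
    is reported (each mate keeps the mapping quality reflecting its own
    genome-wide uniqueness, so a multi-mapping mate still carries quality 0
    even when pairing disambiguates its position).
    """
    f_alns = toy_map(flank_seq, index, max_subs)
    j_alns = toy_map(junction_seq, index, max_subs)
    pa_int = _choose_pair(j_alns, f_alns, min_insert, max_insert, INTACT, pair_id, junction_seq)
    v_int = filter_pair(pa_int, max_subs)
    if v_int.keep:
        return DualMapResult(pa_int, None, v_int, None, INTACT, OK)

    jt_alns = toy_map(junction_seq[trim_len:], index, max_subs)
    pa_tr = _choose_pair(jt_alns, f_alns, min_insert, max_insert, TRIMMED, pair_id, junction_seq)
    v_tr = filter_pair(pa_tr, max_subs)
    if v_tr.keep:
        return DualMapResult(pa_int, pa_tr, v_int, v_tr, TRIMMED, OK)
    return DualMapResult(pa_int, pa_tr, v_int, v_tr, None, v_int.reason)


def _choose_pair(
    j_alns: list[ToyAlignment],
    f_alns: list[ToyAlignment],
    min_insert: int,
    max_insert: int,
    mode: str,
    pair_id: str,
    junction_seq: str,
) -> PairAlignment:
    best_combo = None
    for ja in j_alns[:50]:
        jm = _mate_from_toy(ja)
        for fa in f_alns[:50]:
            fm = _mate_from_toy(fa)
            if _properly_paired(jm, fm, min_insert, max_insert):
                key = (ja.n_subs + fa.n_subs, ja.chrom, ja.pos, fa.pos)
                if best_combo is None or key < best_combo[0]:
                    best_combo = (key, jm, fm)
    if best_combo is not None:
        return PairAlignment(best_combo[1], best_combo[2], True, mode, pair_id, junction_seq)
    jm = _mate_from_toy(best_alignment(j_alns))
    fm = _mate_from_toy(best_alignment(f_alns))
    return PairAlignment(jm, fm, False, mode, pair_id, junction_seq)


# ---------------------------------------------------------------------------
# SAM ingestion


@dataclass
class IngestStats:
    pairs: int = 0
    missing_mate: int = 0
    unparseable: int = 0
    skipped_ids: list[str] = field(default_factory=list)


def ingest_sam(
    paired_sam: str,
    mode: str = INTACT,
    stats: IngestStats | None = None,
) -> Iterator[PairAlignment]:
    """Yield PairAlignments from a headerful paired SAM (any external aligner).

    Mates are paired by read id; read1 is taken as the junction mate and
    read2 as the flank mate.  A pair is properly paired when its flags form
    one of the accepted combinations (99/147 or 83/163).  Edit distance is
    the NM tag plus any clipped bases ("mismatched or unmatched").  Records
    without a mate are counted and dropped.
    """
    import pysam

    if stats is None:
        stats = IngestStats()
    pending: dict[str, "pysam.AlignedSegment"] = {}
    with pysam.AlignmentFile(paired_sam, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            if name in pending:
                other = pending.pop(name)
                r1, r2 = (rec, other) if rec.is_read1 else (other, rec)
                try:
                    yield _pair_from_sam(r1, r2, mode)
                    stats.pairs += 1
                except Exception:
                    stats.unparseable += 1
                    stats.skipped_ids.append(name)
            else:
                pending[name] = rec
    stats.missing_mate += len(pending)
    stats.skipped_ids.extend(pending.keys())


def _mate_from_sam(rec) -> MateAlignment:
    if rec.is_unmapped:
        return MateAlignment(False)
    edit = rec.get_tag("NM") if rec.has_tag("NM") else 0
    clipped = sum(n for op, n in zip(_ops(rec), _lens(rec)) if op in (4, 5))
    return MateAlignment(
        True,
        rec.reference_name,
        rec.reference_start + 1,
        "-" if rec.is_reverse else "+",
        rec.cigarstring or "",
        rec.mapping_quality,
        int(edit) + clipped,
    )


def _ops(rec):
    return [op for op, _n in (rec.cigartuples or [])]


def _lens(rec):
    return [n for _op, n in (rec.cigartuples or [])]


def _pair_from_sam(r1, r2, mode: str) -> PairAlignment:
    proper = (r1.flag & 0xFFF, r2.flag & 0xFFF) in PROPER_FLAG_PAIRS
    return PairAlignment(
        _mate_from_sam(r1),
        _mate_from_sam(r2),
        proper,
        mode,
        r1.query_name,
        r1.query_sequence or "",
    )


def pair_stream_from_sams(
    junction_sam: str, flank_sam: str, mode: str = INTACT, stats: IngestStats | None = None
) -> Iterator[PairAlignment]:
    """Pair two single-end SAMs (junction, flank) by read id."""
    import pysam

    if stats is None:
        stats = IngestStats()
    flanks: dict[str, MateAlignment] = {}
    proper_flags: dict[str, int] = {}
    with pysam.AlignmentFile(flank_sam, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            flanks[rec.query_name] = _mate_from_sam(rec)
            proper_flags[rec.query_name] = rec.flag
    with pysam.AlignmentFile(junction_sam, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            if name not in flanks:
                stats.missing_mate += 1
                stats.skipped_ids.append(name)
                continue
            proper = (rec.flag & 0xFFF, proper_flags[name] & 0xFFF) in PROPER_FLAG_PAIRS
            stats.pairs += 1
            yield PairAlignment(
                _mate_from_sam(rec), flanks[name], proper, mode, name, rec.query_sequence or ""
            )


def brute_force_map(read: str, sequences: dict[str, str], max_subs: int = 3) -> list[ToyAlignment]:
    """Oracle mapper: score every offset on both strands (test-scale only)."""
    m = len(read)
    hits = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        enc = encode(seq)
        for chrom, ref in sequences.items():
            ref_enc = encode(ref)
            n = ref_enc.shape[0] - m + 1
            if n <= 0:
                continue
            view = np.lib.stride_tricks.sliding_window_view(ref_enc, m)
            subs = (view != enc).sum(axis=1)
            for p in np.nonzero(subs <= max_subs)[0]:
                hits.append((chrom, int(p) + 1, strand, int(subs[p])))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    n_best = sum(1 for h in hits if h[3] == best)
    return [
        ToyAlignment(c, p, s, ns, UNIQUE_MAPQ if (ns == best and n_best == 1) else 0, f"{m}M")
        for c, p, s, ns in sorted(hits)
    ]
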