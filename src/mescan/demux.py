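"""Sample-index demultiplexing and read-quality screening.

Every read pair is assigned to a sample by the 5-bp index at the start of the
flank read: an exact match wins; otherwise a unique single-mismatch match is
corrected to the nearest valid index; a 5-mer at distance one from two or
more valid indexes (or at distance >1 from all) is left unassigned.  The
first six flank bases (index + ligated 'T') are trimmed on assignment.

Independently, both reads of a pair are screened by three quality rules:
(a) low complexity -- more than 85% of the read is a single base;
(b) excessive ambiguity -- more than two 'N' calls;
(c) oligonucleotide contamination -- ungapped local alignment score above 60
against any screened library oligo or its reverse complement.
A pair is usable only when both reads pass all three rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .align import encode, encode_batch, ungapped_best_scores
from .oligos import OligoSet

UNASSIGNED = None

#: default ungapped scoring for the contamination screen; with +5/-4 the
#: score-60 threshold needs roughly 13 consecutive matching bases
DEFAULT_MATCH = 5
DEFAULT_MISMATCH = -4
DEFAULT_CONTAM_THRESHOLD = 60

LOW_COMPLEXITY_FRACTION = 0.85
MAX_N = 2
INDEX_LEN = 5
TRIM_LEN = 6  # index + ligated 'T'


@dataclass(frozen=True)
class ReadPairRecord:
    pair_id: str
    junction_seq: str
    flank_seq: str
    junction_qual: str = ""
    flank_qual: str = ""


@dataclass(frozen=True)
class IndexAssignment:
    index: str | None
    distance: int | None
    trimmed_flank: str | None

    @property
    def assigned(self) -> bool:
        return self.index is not None


@dataclass(frozen=True)
class QualityFlags:
    low_complexity: bool = False
    excess_n: bool = False
    adapter_contaminated: bool = False

    @property
    def usable(self) -> bool:
        return not (self.low_complexity or self.excess_n or self.adapter_contaminated)


def assign_index(flank_seq: str, valid_indexes: Iterable[str]) -> IndexAssignment:
    """Assign the 5-bp index with single-mismatch correction.

    'N' counts as a mismatch.  Returns UNASSIGNED when no valid index is
    within Hamming distance 1 or when two valid indexes tie at distance 1.
    """
    valid = list(valid_indexes)
    if not valid:
        raise ValueError("valid index set is empty")
    if any(len(v) != INDEX_LEN for v in valid):
        raise ValueError("valid indexes must be 5 nt")
    if len(set(valid)) != len(valid):
        raise ValueError("valid indexes must be distinct")
    if len(flank_seq) < TRIM_LEN:
        raise ValueError("flank read shorter than index + 'T'")
    observed = flank_seq[:INDEX_LEN]
    if observed in valid:
        return IndexAssignment(observed, 0, flank_seq[TRIM_LEN:])
    hits = [v for v in valid if _hamming(observed, v) == 1]
    if len(hits) == 1:
        return IndexAssignment(hits[0], 1, flank_seq[TRIM_LEN:])
    return IndexAssignment(None, None, None)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_read_quality(
    seq: str,
    oligos: OligoSet | None = None,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    contam_threshold: int = DEFAULT_CONTAM_THRESHOLD,
) -> QualityFlags:
    """Evaluate the three quality rules on one read."""
    if not seq:
        raise ValueError("empty read")
    if oligos is None:
        oligos = OligoSet()
    counts = np.bincount(encode(seq), minlength=5)
    low = counts[:4].max() / len(seq) > LOW_COMPLEXITY_FRACTION
    excess = seq.count("N") > MAX_N
    enc = encode(seq)[None, :]
    contaminated = False
    for _name, oseq in oligos.screened():
        if ungapped_best_scores(enc, encode(oseq), match, mismatch)[0] > contam_threshold:
            contaminated = True
            break
    return QualityFlags(low, excess, contaminated)


def _batch_flags(
    seqs: list[str],
    oligos: OligoSet,
    match: int,
    mismatch: int,
    threshold: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised quality rules over equal-length reads: (low, excess_n, contam)."""
    enc = encode_batch(seqs)
    n, L = enc.shape
    low = np.zeros(n, dtype=bool)
    for b in range(4):
        np.logical_or(low, (enc == b).sum(axis=1) / L > LOW_COMPLEXITY_FRACTION, out=low)
    excess = (enc == 4).sum(axis=1) > MAX_N
    contam = np.zeros(n, dtype=bool)
    for _name, oseq in oligos.screened():
        todo = ~contam
        if not todo.any():
            break
        scores = ungapped_best_scores(enc[todo], encode(oseq), match, mismatch)
        contam[np.nonzero(todo)[0][scores > threshold]] = True
    return low, excess, contam


@dataclass
class DemuxCounters:
    """Stage accounting mirroring the standard read-quality table.

    Quality-rule buckets are mutually exclusive in the order (a) complexity,
    (b) N count, (c) adapter, evaluated on the pair (either read failing).
    """

    total: int = 0
    rule_a_low_complexity: int = 0
    rule_b_excess_n: int = 0
    rule_c_adapter: int = 0
    high_quality: int = 0
    index_valid: int = 0
    unassigned_index: int = 0
    flank_pos6_not_t: int = 0  # diagnostic only; never used for rejection

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadPairRecord]]
    counters: DemuxCounters
    failed_qc: list[str] = field(default_factory=list)  # pair ids
    unassigned: list[str] = field(default_factory=list)


def demux_stream(
    pairs: Iterable[ReadPairRecord],
    valid_indexes: dict[str, str],
    oligos: OligoSet | None = None,
    read_len: int = 36,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    contam_threshold: int = DEFAULT_CONTAM_THRESHOLD,
    chunk_size: int = 4096,
) -> DemuxResult:
    """Partition read pairs into (sample, usable) buckets with accounting.

    ``valid_indexes`` maps the 5-nt index to the sample label.  Every input
    pair lands in exactly one bucket: a sample, failed-QC, or unassigned.
    Reads whose declared length differs from ``read_len`` raise immediately
    (already-trimmed input must not be silently re-trimmed).
    """
    if oligos is None:
        oligos = OligoSet()
    index_to_sample = dict(valid_indexes)
    counters = DemuxCounters()
    by_sample: dict[str, list[ReadPairRecord]] = {s: [] for s in index_to_sample.values()}
    failed: list[str] = []
    unassigned: list[str] = []

    for chunk in _chunks(pairs, chunk_size):
        for rec in chunk:
            if len(rec.junction_seq) != read_len or len(rec.flank_seq) != read_len:
                raise ValueError(
                    f"read pair {rec.pair_id!r}: read length differs from declared "
                    f"{read_len} (already-trimmed input?)"
                )
        counters.total += len(chunk)
        j_low, j_n, j_c = _batch_flags([r.junction_seq for r in chunk], oligos, match, mismatch, contam_threshold)
        f_low, f_n, f_c = _batch_flags([r.flank_seq for r in chunk], oligos, match, mismatch, contam_threshold)
        low = j_low | f_low
        nn = j_n | f_n
        cont = j_c | f_c
        for i, rec in enumerate(chunk):
            if low[i]:
                counters.rule_a_low_complexity += 1
                failed.append(rec.pair_id)
                continue
            if nn[i]:
                counters.rule_b_excess_n += 1
                failed.append(rec.pair_id)
                continue
            if cont[i]:
                counters.rule_c_adapter += 1
                failed.append(rec.pair_id)
                continue
            counters.high_quality += 1
            assignment = assign_index(rec.flank_seq, index_to_sample.keys())
            if not assignment.assigned:
                counters.unassigned_index += 1
                unassigned.append(rec.pair_id)
                continue
            if rec.flank_seq[INDEX_LEN] != "T":
                counters.flank_pos6_not_t += 1
            counters.index_valid += 1
            sample = index_to_sample[assignment.index]
            by_sample[sample].append(
                ReadPairRecord(
                    rec.pair_id,
                    rec.junction_seq,
                    assignment.trimmed_flank,
                    rec.junction_qual,
                    rec.flank_qual[TRIM_LEN:] if rec.flank_qual else "",
                )
            )
    return DemuxResult(by_sample, counters, failed, unassigned)


def _chunks(it: Iterable, size: int) -> Iterator[list]:
    buf: list = []
    for x in it:
        buf.append(x)
        if len(buf) >= size:
            yield buf
            buf = []
    if buf:
        yield buf


def read_pair_fastqs(junction_path: str, flank_path: str) -> Iterator[ReadPairRecord]:
    """Iterate lockstep FASTQ files as ReadPairRecords (ids must correspond)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(junction_path) as jf, open(flank_path) as ff:
        jit = FastqGeneralIterator(jf)
        fit = FastqGeneralIterator(ff)
        for (jid, jseq, jq), (fid, fseq, fq) in zip(jit, fit, strict=True):
            jid_base = jid.split()[0].removesuffix("/1")
            fid_base = fid.split()[0].removesuffix("/2")
            if jid_base != fid_base:
                raise ValueError(f"FASTQ files out of sync: {jid!r} vs {fid!r}")
            yield ReadPairRecord(jid_base, jseq.upper(), fseq.upper(), jq, fq)


def read_index_table(path: str) -> dict[str, str]:
    """Read a (sample, index[, proportion]) TSV; returns index -> sample."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            sample, index = parts[0], parts[1]
            mapping[index] = sample
    return mapping
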