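"""Locus identification from filtered pair alignments.

The reference coordinate of the last sequenced base of the junction read --
about 20 bp past the element's 5' junction -- is used as the locus
identifier; it exists in the reference even when the insertion does not, and
it is identical whether the read mapped intact or with its 16-nt element
prefix trimmed.  Endpoints sharing an exact position form support groups;
lone endpoints within 3 bp of a larger group (rare products of sequencing
error) are absorbed into the most numerous neighbour.  Groups are retained
as insertion loci when they are supported by at least 10 read pairs summed
over all samples and experiments and when at least 50% of their junction
reads contain detectable element sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import smith_waterman, ungapped_local_score
from .mapping import PairAlignment, cigar_reference_length
from .oligos import ME_MOTIF


@dataclass(frozen=True)
class MEMotifParams:
    """Element-motif detection: exact prefix identity or local-alignment score."""

    motif: str = ME_MOTIF
    exact_match_len: int = 10
    min_score: int = 45
    match: int = 5
    mismatch: int = -4
    gap_open: int = 64
    gap_extend: int = 8

    def __post_init__(self) -> None:
        if self.exact_match_len <= 0 or self.min_score <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class JunctionEndpoint:
    chrom: str
    position: int  # reference coordinate of the junction read's last base
    mode: str
    sample: str
    experiment: str = "main"
    lead16: str = ""  # first 16 nt of the (untrimmed) junction read


@dataclass
class LocusGroup:
    chrom: str
    position: int  # identifier: position of the largest exact-position stack
    endpoints: list[JunctionEndpoint]

    @property
    def size(self) -> int:
        return len(self.endpoints)


@dataclass
class LocusRecord:
    chrom: str
    position: int
    support: dict[tuple[str, str], int]  # (experiment, sample) -> pairs
    total_support: int
    me_fraction: float
    modes: set[str] = field(default_factory=set)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.position}"


def junction_endpoint(
    pair: PairAlignment,
    sample: str,
    experiment: str = "main",
    trim_len: int = 16,
) -> JunctionEndpoint:
    """Endpoint of the junction read's final sequenced base on the reference.

    Forward strand: POS + reference-consumed CIGAR length - 1.  Reverse
    strand: POS (the read's last base is its leftmost reference base).  The
    intact and trimmed mappings of the same fragment yield the same value:
    trimming removes the 16 leading element bases, which sit at the opposite
    end of the read from the endpoint.
    """
    mate = pair.junction
    if not mate.mapped:
        raise ValueError("junction mate is unmapped")
    ref_len = cigar_reference_length(mate.cigar)
    pos = mate.pos + ref_len - 1 if mate.strand == "+" else mate.pos
    lead = pair.junction_seq[:trim_len] if pair.junction_seq else ""
    return JunctionEndpoint(mate.chrom, pos, pair.mode, sample, experiment, lead)


def group_endpoints(endpoints: list[JunctionEndpoint], merge_tol: int = 3) -> list[LocusGroup]:
    """Group endpoints by exact position, then absorb nearby singletons.

    Only groups of size 1 are merged; they are absorbed into the most
    numerous group of size >= 2 within ``merge_tol`` bp.  Ties are broken
    toward the nearer group, then toward the lower coordinate.  Two nearby
    multi-read groups always remain distinct.
    """
    stacks: dict[tuple[str, int], list[JunctionEndpoint]] = defaultdict(list)
    for ep in endpoints:
        stacks[(ep.chrom, ep.position)].append(ep)

    groups: dict[tuple[str, int], list[JunctionEndpoint]] = {k: list(v) for k, v in stacks.items()}
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in stacks:
        by_chrom[chrom].append(pos)

    for chrom, positions in by_chrom.items():
        positions.sort()
        sizes = {p: len(stacks[(chrom, p)]) for p in positions}
        for p in positions:
            if sizes[p] != 1:
                continue
            neighbours = [
                q
                for q in positions
                if q != p and abs(q - p) <= merge_tol and sizes[q] >= 2
            ]
            if not neighbours:
                continue
            target = min(neighbours, key=lambda q: (-sizes[q], abs(q - p), q))
            groups[(chrom, target)].extend(groups.pop((chrom, p)))

    return [
        LocusGroup(chrom, pos, eps)
        for (chrom, pos), eps in sorted(groups.items())
    ]


def detect_me_sequence(lead_seq: str, params: MEMotifParams | None = None) -> bool:
    """Does the junction read's leading segment contain the element motif?

    True when the read matches the motif exactly over its first
    ``exact_match_len`` bases, or when a local alignment against the motif
    scores at least ``min_score`` under the configured costs.  An ungapped
    score reaching the threshold short-circuits the gapped alignment (a
    gapped score can only be higher).
    """
    if params is None:
        params = MEMotifParams()
    k = params.exact_match_len
    if lead_seq[:k] == params.motif[:k]:
        return True
    if (
        ungapped_local_score(lead_seq, params.motif, params.match, params.mismatch)
        >= params.min_score
    ):
        return True
    return (
        smith_waterman(
            lead_seq,
            params.motif,
            params.match,
            params.mismatch,
            params.gap_open,
            params.gap_extend,
        )
        >= params.min_score
    )


def detect_me_batch(leads: list[str], params: MEMotifParams | None = None) -> np.ndarray:
    """Vectorised motif detection over many junction-read leading segments.

    The exact-prefix and ungapped-score criteria are evaluated in bulk; only
    the few reads that fail both but could still reach the score threshold
    with gaps fall through to the full Smith-Waterman.
    """
    if params is None:
        params = MEMotifParams()
    if not leads:
        return np.zeros(0, dtype=bool)
    from .align import encode, encode_batch, ungapped_best_scores

    k = params.exact_match_len
    prefix = params.motif[:k]
    out = np.fromiter((s[:k] == prefix for s in leads), dtype=bool, count=len(leads))
    todo = np.nonzero(~out)[0]
    if todo.size:
        enc = encode_batch([leads[i] for i in todo])
        scores = ungapped_best_scores(enc, encode(params.motif), params.match, params.mismatch)
        out[todo[scores >= params.min_score]] = True
        rest = todo[scores < params.min_score]
        for i in rest:
            if (
                smith_waterman(
                    leads[i], params.motif, params.match, params.mismatch,
                    params.gap_open, params.gap_extend,
                )
                >= params.min_score
            ):
                out[i] = True
    return out


def call_loci(
    groups: list[LocusGroup],
    min_support: int = 10,
    min_me_fraction: float = 0.5,
    motif_params: MEMotifParams | None = None,
) -> list[LocusRecord]:
    """Retain groups with enough total support and enough motif-bearing reads.

    Support is summed over all samples and experiments; the motif fraction's
    denominator is every supporting junction read (aggregated before the 50%
    rule).  Both thresholds are inclusive.
    """
    records: list[LocusRecord] = []
    for g in groups:
        if g.size < min_support:
            continue
        flags = detect_me_batch([ep.lead16 for ep in g.endpoints], motif_params)
        frac = int(flags.sum()) / g.size
        if frac < min_me_fraction:
            continue
        support = Counter((ep.experiment, ep.sample) for ep in g.endpoints)
        records.append(
            LocusRecord(
                g.chrom,
                g.position,
                dict(support),
                g.size,
                frac,
                {ep.mode for ep in g.endpoints},
            )
        )
    return records


def genotype_matrix(
    loci: list[LocusRecord],
    min_pairs_per_sample: int = 1,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence calls (and supporting counts) per locus and sample.

    Counts are summed over experiments; a (locus, sample) cell is called
    present when its pair count reaches ``min_pairs_per_sample``.  Returns
    ``(calls, counts)`` DataFrames indexed by locus id.
    """
    per_sample: dict[str, dict[str, int]] = defaultdict(dict)
    for rec in loci:
        agg: dict[str, int] = defaultdict(int)
        for (_exp, sample), n in rec.support.items():
            agg[sample] += n
        for sample, n in agg.items():
            per_sample[rec.locus_id][sample] = n
    counts = pd.DataFrame.from_dict(per_sample, orient="index").fillna(0).astype(int)
    if samples is not None:
        counts = counts.reindex(columns=samples, fill_value=0)
    counts = counts.sort_index()
    calls = (counts >= min_pairs_per_sample).astype(int)
    return calls, counts


def write_locus_table(path: str, loci: list[LocusRecord]) -> None:
    """Locus list TSV: chrom, 1-based endpoint, support, motif fraction, per-sample counts."""
    keys = sorted({k for rec in loci for k in rec.support})
    with open(path, "w") as fh:
        header = ["chrom", "position", "total_support", "me_fraction"] + [
            f"{e}/{s}" for e, s in keys
        ]
        fh.write("# 1-based junction-endpoint coordinates\n")
        fh.write("\t".join(header) + "\n")
        for rec in sorted(loci, key=lambda r: (r.chrom, r.position)):
            row = [rec.chrom, str(rec.position), str(rec.total_support), f"{rec.me_fraction:.4f}"]
            row += [str(rec.support.get(k, 0)) for k in keys]
            fh.write("\t".join(row) + "\n")


def brute_force_group(
    endpoints: list[JunctionEndpoint], merge_tol: int = 3
) -> dict[tuple[str, int], int]:
    """Oracle grouping (independent formulation): returns {(chrom, id): size}.

    Exhaustively forms exact stacks, then re-assigns every singleton by
    scanning all other stacks for the best absorbing neighbour.
    """
    sizes: dict[tuple[str, int], int] = {}
    for ep in endpoints:
        sizes[(ep.chrom, ep.position)] = sizes.get((ep.chrom, ep.position), 0) + 1
    out = dict(sizes)
    for (chrom, p), n in sizes.items():
        if n != 1:
            continue
        best = None
        for (c2, q), n2 in sizes.items():
            if c2 != chrom or q == p or n2 < 2 or abs(q - p) > merge_tol:
                continue
            key = (-n2, abs(q - p), q)
            if best is None or key < best[0]:
                best = (key, (c2, q))
        if best is not None:
            out[best[1]] += 1
            del out[(chrom, p)]
    return out
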