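"""Wet-lab-emulating simulator: references, cohorts, and pooled indexed libraries.

The simulator reproduces the geometry of the targeted-sequencing protocol so
that every downstream stage can be tested hermetically against known truth:

* a random reference with planted target-subfamily elements carrying perfect
  amplification and sequencing primer-binding sites (PBS), decoy older-family
  elements with degenerate PBS, and near-identical duplicated blocks;
* a cohort of individuals with per-locus insertion genotypes (fixed,
  polymorphic, singleton classes; optional non-reference "novel" loci);
* an indexed pooled 2x36-bp paired library: the junction read begins 16 nt
  inside the element's 5' end and reads across the junction into 20 nt of
  genomic flank; the flank read carries the 5-nt sample index, the ligated
  'T', and 30 nt of genomic sequence from the fragment's far end.  Per-locus
  read-pair counts are negative-binomially overdispersed and every base can
  be miscalled at a configured rate.

Coordinates are 1-based fully closed everywhere in this module; BED output is
converted to 0-based half-open at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .oligos import AMPLIFICATION_PBS, CPEA1XA_CONST, JUNCTION_16, SEQUENCING_PRIMER, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TARGET_FAMILY = "target"
DECOY_FAMILY = "decoy"

#: offset of the sequencing-read start inside the element (read geometry)
JUNCTION_INTERNAL = 16
#: genomic flank covered by the junction read past the element 5' end
JUNCTION_FLANK = 20


def _random_seq_array(rng: np.random.Generator, length: int, gc: float = 0.41) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _from_str(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


@dataclass
class MeElement:
    """A planted mobile element. ``strand`` is the element's sense strand."""

    chrom: str
    start: int  # 1-based, closed
    end: int
    strand: str
    family: str
    in_duplication: bool = False

    @property
    def junction(self) -> int:
        """Reference coordinate of the element base at the 5' junction."""
        return self.start if self.strand == "+" else self.end

    @property
    def expected_endpoint(self) -> int:
        """Reference coordinate of the last junction-read base (locus identifier)."""
        return self.junction - JUNCTION_FLANK if self.strand == "+" else self.junction + JUNCTION_FLANK

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.expected_endpoint}"


@dataclass
class DupBlock:
    chrom: str
    src_start: int
    src_end: int
    copy_chrom: str
    copy_start: int
    copy_end: int
    identity: float


@dataclass
class SimReference:
    sequences: dict[str, str]
    me_track: list[MeElement]
    duplicated_blocks: list[DupBlock]
    polymorphic_known: list[str]
    #: unoccupied well-separated sites usable for novel (non-reference) insertions
    spare_sites: list[tuple[str, int]] = field(default_factory=list)

    @property
    def targets(self) -> list[MeElement]:
        return [e for e in self.me_track if e.family == TARGET_FAMILY]

    @property
    def decoys(self) -> list[MeElement]:
        return [e for e in self.me_track if e.family == DECOY_FAMILY]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_track(self, path: str | Path) -> None:
        """6-column BED-like TSV (0-based half-open; name = family label)."""
        with open(path, "w") as fh:
            fh.write("# chrom\tstart\tend\tname\tscore\tstrand (0-based half-open)\n")
            for e in self.me_track:
                fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.family}\t.\t{e.strand}\n")


def read_track(path: str | Path) -> list[MeElement]:
    elements = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, s0, e, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            elements.append(MeElement(chrom, int(s0) + 1, int(e), strand, name))
    return elements


def _build_element(
    rng: np.random.Generator,
    element_len: int,
    polya_len: int,
    decoy: bool,
    decoy_pbs_mismatches: int,
    decoy_junction_mismatches: int,
) -> np.ndarray:
    """Element sequence in '+'-sense layout (5' junction at the left end).

    Layout on the reference plus strand for a plus-sense element: positions
    0..15 hold the reverse complement of the 16-nt junction segment (the
    sequencing read starts here and reads leftward), 16..42 the reverse
    complement of the sequencing PBS, 240..259 the reverse complement of the
    amplification PBS (plus-strand PBS start separation 224), and a poly-A
    tail at the element 3' end.  Decoys receive substitutions in the 3' 10 bp
    of the sequencing PBS (degenerate primer site) and in the junction
    segment (family divergence that still passes motif detection).
    """
    seg = _random_seq_array(rng, element_len)
    seg[0:16] = _from_str(revcomp(JUNCTION_16))
    seg[16 : 16 + len(SEQUENCING_PRIMER)] = _from_str(revcomp(SEQUENCING_PRIMER))
    amp_off = 16 + 224
    seg[amp_off : amp_off + len(AMPLIFICATION_PBS)] = _from_str(revcomp(AMPLIFICATION_PBS))
    if polya_len:
        seg[element_len - polya_len :] = ord("A")
    if decoy:
        # primer 3' end corresponds to the leftmost plus-strand base of the PBS
        pos = rng.choice(np.arange(16, 26), size=decoy_pbs_mismatches, replace=False)
        for p in pos:
            seg[p] = _mutate(rng, seg[p])
        pos = rng.choice(np.arange(0, 16), size=decoy_junction_mismatches, replace=False)
        for p in pos:
            seg[p] = _mutate(rng, seg[p])
    return seg


def _mutate(rng: np.random.Generator, base: int) -> int:
    choices = _BASES[_BASES != base]
    return int(choices[rng.integers(len(choices))])


def make_reference(
    chrom_lengths: dict[str, int] | None = None,
    n_target: int = 50,
    n_decoy: int = 0,
    n_duplications: int = 0,
    n_known_polymorphic: int = 0,
    element_len: int = 300,
    polya_len: int = 20,
    tsd_len: int = 15,
    dup_window: int = 500,
    dup_identity: float = 0.995,
    decoy_pbs_mismatches: int = 1,
    decoy_junction_mismatches: int = 2,
    seed: int = 0,
) -> SimReference:
    """Generate a reference with planted elements, decoys and duplications.

    Elements are placed in disjoint slots that guarantee clearance for the
    longest simulated fragment (so every read window stays on-chromosome) and
    for the duplication-detection window.  Raises ``ValueError`` when the
    requested element count does not fit.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 1_000_000}
    if n_duplications > n_target:
        raise ValueError("n_duplications cannot exceed n_target")
    rng = np.random.default_rng(seed)
    margin = 750  # > max fragment length and > dup_window + read windows
    slot = element_len + 2 * margin

    arrays: dict[str, np.ndarray] = {}
    all_slots: list[tuple[str, int]] = []  # (chrom, slot start offset 0-based)
    for chrom, length in chrom_lengths.items():
        arrays[chrom] = _random_seq_array(rng, length)
        for k in range(length // slot):
            all_slots.append((chrom, k * slot))
    n_elements = n_target + n_decoy
    if n_elements + n_duplications > len(all_slots):
        raise ValueError(
            f"cannot place {n_elements} elements plus {n_duplications} duplicated "
            f"blocks in {len(all_slots)} slots of {slot} bp; increase chromosome length"
        )
    order = rng.permutation(len(all_slots))
    elements: list[MeElement] = []
    for i in range(n_elements):
        chrom, off = all_slots[order[i]]
        decoy = i >= n_target
        strand = "+" if rng.random() < 0.5 else "-"
        seg = _build_element(
            rng, element_len, polya_len, decoy, decoy_pbs_mismatches, decoy_junction_mismatches
        )
        if strand == "-":
            seg = _from_str(revcomp(_to_str(seg)))
        s0 = off + margin  # 0-based start
        arr = arrays[chrom]
        arr[s0 : s0 + element_len] = seg
        if tsd_len:
            arr[s0 + element_len : s0 + element_len + tsd_len] = arr[s0 - tsd_len : s0]
        elements.append(
            MeElement(chrom, s0 + 1, s0 + element_len, strand, DECOY_FAMILY if decoy else TARGET_FAMILY)
        )

    dup_blocks: list[DupBlock] = []
    targets = [e for e in elements if e.family == TARGET_FAMILY]
    if n_duplications:
        dup_idx = rng.choice(len(targets), size=n_duplications, replace=False)
        for k, ti in enumerate(dup_idx):
            e = targets[int(ti)]
            if e.strand == "+":
                src_s, src_e = e.start - dup_window, e.end  # 1-based closed
            else:
                src_s, src_e = e.start, e.end + dup_window
            src = arrays[e.chrom][src_s - 1 : src_e].copy()
            # diverge the copy, but keep the junction-read window identical so
            # that junction reads from source and copy truly tie in the mapper
            j_rel = e.junction - src_s  # 0-based within block
            guard_lo, guard_hi = j_rel - 25, j_rel + 25
            n_sub = int(round(len(src) * (1.0 - dup_identity)))
            allowed = np.array(
                [p for p in range(len(src)) if not (guard_lo <= p <= guard_hi)]
            )
            for p in rng.choice(allowed, size=n_sub, replace=False):
                src[p] = _mutate(rng, src[p])
            chrom_c, off_c = all_slots[order[n_elements + k]]
            c0 = off_c + margin
            arrays[chrom_c][c0 : c0 + len(src)] = src
            dup_blocks.append(
                DupBlock(e.chrom, src_s, src_e, chrom_c, c0 + 1, c0 + len(src), 1.0 - n_sub / len(src))
            )
            e.in_duplication = True

    used = n_elements + n_duplications
    spare = []
    for idx in order[used:]:
        chrom, off = all_slots[idx]
        spare.append((chrom, off + margin + JUNCTION_FLANK + tsd_len))

    poly_known: list[str] = []
    if n_known_polymorphic:
        non_dup = [e for e in targets if not e.in_duplication]
        if n_known_polymorphic > len(non_dup):
            raise ValueError("n_known_polymorphic exceeds available target elements")
        for i in rng.choice(len(non_dup), size=n_known_polymorphic, replace=False):
            poly_known.append(non_dup[int(i)].locus_id)

    sequences = {c: _to_str(a) for c, a in arrays.items()}
    elements.sort(key=lambda e: (e.chrom, e.start))
    return SimReference(sequences, elements, dup_blocks, poly_known, spare)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortLocus:
    locus_id: str
    chrom: str
    junction: int
    strand: str
    cls: str  # fixed | polymorphic | singleton
    in_reference: bool
    family: str = TARGET_FAMILY

    @property
    def expected_endpoint(self) -> int:
        return self.junction - JUNCTION_FLANK if self.strand == "+" else self.junction + JUNCTION_FLANK


@dataclass
class SimCohort:
    individuals: list[str]
    loci: list[CohortLocus]
    genotypes: pd.DataFrame  # individuals x locus_id, values in {0,1,2}

    def carriers(self) -> pd.DataFrame:
        return (self.genotypes > 0).astype(int)


def simulate_cohort(
    ref: SimReference,
    n_individuals: int,
    fixed_fraction: float = 2 / 3,
    allele_freq_spec: float | tuple = 0.5,
    singleton_rate: float = 0.0,
    n_novel: int = 0,
    seed: int = 0,
    individuals: list[str] | None = None,
) -> SimCohort:
    """Assign insertion classes and genotypes over the reference's target loci.

    Each reference target locus is classed fixed (genotype 2 everywhere),
    singleton (one copy in one random individual) or polymorphic (Hardy-
    Weinberg genotypes at the configured allele frequency).  ``n_novel``
    additional non-reference loci are planted at spare sites; their junction
    sequence exists only in carrier individuals, so their reads can map only
    after trimming the element prefix.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not 0 <= fixed_fraction <= 1 or not 0 <= singleton_rate <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if fixed_fraction + singleton_rate > 1 + 1e-12:
        raise ValueError("fixed_fraction + singleton_rate must be <= 1")
    rng = np.random.default_rng(seed)
    if individuals is None:
        individuals = [f"S{i + 1}" for i in range(n_individuals)]

    def draw_freq() -> float:
        if isinstance(allele_freq_spec, tuple) and allele_freq_spec[0] == "beta":
            return float(rng.beta(allele_freq_spec[1], allele_freq_spec[2]))
        f = float(allele_freq_spec)
        if not 0 <= f <= 1:
            raise ValueError("allele frequency outside [0, 1]")
        return f

    targets = ref.targets
    n = len(targets)
    n_single = int(round(singleton_rate * n))
    n_fixed = int(round(fixed_fraction * n))
    n_fixed = min(n_fixed, n - n_single)
    classes = ["fixed"] * n_fixed + ["singleton"] * n_single + ["polymorphic"] * (n - n_fixed - n_single)
    classes = [classes[i] for i in rng.permutation(n)]

    loci: list[CohortLocus] = []
    geno: dict[str, np.ndarray] = {}
    for e, cls in zip(targets, classes):
        lid = e.locus_id
        loci.append(CohortLocus(lid, e.chrom, e.junction, e.strand, cls, True))
        geno[lid] = _draw_genotypes(rng, cls, n_individuals, draw_freq)

    if n_novel > len(ref.spare_sites):
        raise ValueError("not enough spare sites in the reference for requested novel loci")
    for chrom, pos in ref.spare_sites[:n_novel]:
        strand = "+" if rng.random() < 0.5 else "-"
        endpoint = pos - JUNCTION_FLANK if strand == "+" else pos + JUNCTION_FLANK
        locus = CohortLocus(f"{chrom}:{endpoint}", chrom, pos, strand, "polymorphic", False)
        loci.append(locus)
        geno[locus.locus_id] = _draw_genotypes(rng, "polymorphic", n_individuals, draw_freq, novel=True)

    gdf = pd.DataFrame(geno, index=individuals)
    return SimCohort(individuals, loci, gdf)


def _draw_genotypes(rng, cls, n, draw_freq, novel: bool = False) -> np.ndarray:
    if cls == "fixed":
        return np.full(n, 2, dtype=np.int64)
    if cls == "singleton":
        g = np.zeros(n, dtype=np.int64)
        g[rng.integers(n)] = 1
        return g
    f = draw_freq()
    g = rng.binomial(2, f, size=n).astype(np.int64)
    if novel and g.sum() == 0:
        g[rng.integers(n)] = 1  # a novel locus absent from everyone is unobservable
    return g


# ---------------------------------------------------------------------------
# library


@dataclass
class LibraryDesign:
    """Design of one pooled, indexed sequencing library."""

    indexes: dict[str, str]  # sample label -> 5-nt index
    proportions: dict[str, float]  # sample label -> pooling fraction
    total_read_pairs: int = 100_000
    dispersion: float = 10.0  # variance/mean of per-locus pair counts
    error_rate: float = 0.004  # per-base substitution probability
    fragment_len_range: tuple[int, int] = (650, 700)
    decoy_mean_pairs: float = 0.0  # Poisson mean per (decoy element, sample)
    adapter_contam_rate: float = 0.0
    experiment: str = "main"
    seed: int = 0

    def __post_init__(self) -> None:
        idx = list(self.indexes.values())
        if len(set(idx)) != len(idx):
            raise ValueError("sample indexes must be distinct")
        if any(len(i) != 5 for i in idx):
            raise ValueError("indexes must be 5 nt")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("pooling proportions must sum to 1")
        if set(self.proportions) != set(self.indexes):
            raise ValueError("proportions and indexes must cover the same samples")


@dataclass
class SimTruth:
    """Per-pair and per-locus emission truth; the oracle for end-to-end tests."""

    pairs: pd.DataFrame  # read_id, sample, locus_id, endpoint, contaminated
    counts: pd.DataFrame  # locus_id x sample emitted pair counts
    genotypes: pd.DataFrame  # individuals x locus_id
    experiment: str = "main"

    def carrier_matrix(self) -> pd.DataFrame:
        return (self.genotypes > 0).astype(int)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.pairs.to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)
        self.counts.to_csv(directory / "truth_counts.tsv", sep="\t")
        self.genotypes.to_csv(directory / "truth_genotypes.tsv", sep="\t")


@dataclass
class LibraryResult:
    junction_reads: list[tuple[str, str, str]]  # (id, seq, qual)
    flank_reads: list[tuple[str, str, str]]
    truth: SimTruth


def simulate_library(ref: SimReference, cohort: SimCohort, design: LibraryDesign) -> LibraryResult:
    """Emit one pooled paired library (junction + flank reads) with truth.

    Per-(locus, sample) pair counts follow a negative binomial whose mean is
    ``total * proportion * (copies/2)`` normalised over the sample's carried
    loci and whose variance is ``dispersion`` times the mean.  Fragment
    lengths are uniform in the size-selection window; the flank read's 30 nt
    of genomic sequence come from the fragment's far end.
    """
    rng = np.random.default_rng(design.seed)
    for s in design.indexes:
        if s not in cohort.individuals:
            raise ValueError(f"sample {s!r} not present in the cohort")

    fmin, fmax = design.fragment_len_range
    j_seq: list[str] = []
    f_seq: list[str] = []
    samples: list[str] = []
    locus_ids: list[str] = []
    endpoints: list[int] = []

    decoy_loci = [
        CohortLocus(e.locus_id, e.chrom, e.junction, e.strand, "decoy", True, DECOY_FAMILY)
        for e in ref.decoys
    ]

    for sample, index in design.indexes.items():
        prop = design.proportions[sample]
        g = cohort.genotypes.loc[sample]
        carried = [(l, g[l.locus_id] / 2.0) for l in cohort.loci if g[l.locus_id] > 0]
        wsum = sum(w for _, w in carried)
        for locus, w in carried:
            mean = design.total_read_pairs * prop * w / wsum if wsum else 0.0
            count = _overdispersed_count(rng, mean, design.dispersion)
            _emit_pairs(rng, ref, locus, index, count, fmin, fmax, sample, j_seq, f_seq, samples, locus_ids, endpoints)
        for locus in decoy_loci:
            if design.decoy_mean_pairs > 0:
                count = int(rng.poisson(design.decoy_mean_pairs * prop * len(design.indexes)))
                _emit_pairs(rng, ref, locus, index, count, fmin, fmax, sample, j_seq, f_seq, samples, locus_ids, endpoints)

    n = len(j_seq)
    perm = rng.permutation(n)
    j_seq = [j_seq[i] for i in perm]
    f_seq = [f_seq[i] for i in perm]
    samples = [samples[i] for i in perm]
    locus_ids = [locus_ids[i] for i in perm]
    endpoints = [endpoints[i] for i in perm]

    j_seq = _apply_errors(rng, j_seq, design.error_rate)
    f_seq = _apply_errors(rng, f_seq, design.error_rate)

    contaminated = np.zeros(n, dtype=bool)
    n_cont = int(round(design.adapter_contam_rate * n))
    if n_cont:
        which = rng.choice(n, size=n_cont, replace=False)
        tag = CPEA1XA_CONST[:20]
        for i in which:
            s = f_seq[i]
            f_seq[i] = s[:10] + tag + s[10 + len(tag) :]
            contaminated[i] = True

    ids = [f"sim{i:07d}" for i in range(n)]
    qual = "I" * 36
    junction = [(ids[i], j_seq[i], qual) for i in range(n)]
    flank = [(ids[i], f_seq[i], qual) for i in range(n)]

    pairs = pd.DataFrame(
        {"read_id": ids, "sample": samples, "locus_id": locus_ids, "endpoint": endpoints, "contaminated": contaminated}
    )
    counts = (
        pairs.groupby(["locus_id", "sample"]).size().unstack(fill_value=0)
        if n
        else pd.DataFrame()
    )
    truth = SimTruth(pairs, counts, cohort.genotypes, design.experiment)
    return LibraryResult(junction, flank, truth)


def _overdispersed_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1.0:
        return int(rng.poisson(mean))
    r = mean / (dispersion - 1.0)
    p = 1.0 / dispersion
    return int(rng.negative_binomial(r, p))


def _emit_pairs(
    rng, ref, locus, index, count, fmin, fmax, sample, j_seq, f_seq, samples, locus_ids, endpoints
) -> None:
    if count <= 0:
        return
    seq = ref.sequences[locus.chrom]
    j = locus.junction
    frag = rng.integers(fmin, fmax + 1, size=count)
    if locus.strand == "+":
        if locus.in_reference:
            jr = revcomp(seq[j - 21 : j + 15])
        else:
            jr = JUNCTION_16 + revcomp(seq[j - 21 : j - 1])
        for F in frag:
            p = j - (int(F) - JUNCTION_INTERNAL)
            f_seq.append(index + "T" + seq[p - 1 : p + 29])
            j_seq.append(jr)
    else:
        if locus.in_reference:
            jr = seq[j - 16 : j + 20]
        else:
            jr = JUNCTION_16 + seq[j : j + 20]
        for F in frag:
            q = j + (int(F) - JUNCTION_INTERNAL)
            f_seq.append(index + "T" + revcomp(seq[q - 30 : q]))
            j_seq.append(jr)
    ep = locus.expected_endpoint
    samples.extend([sample] * count)
    locus_ids.extend([locus.locus_id] * count)
    endpoints.extend([ep] * count)


def _apply_errors(rng: np.random.Generator, seqs: list[str], rate: float) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.shape[0]) < rate
    idx = np.nonzero(mask)[0]
    if idx.size:
        # substitute with one of the three other bases, uniformly
        from .align import encode

        codes = encode(arr[idx].tobytes().decode("ascii"))
        shift = rng.integers(1, 4, size=idx.size)
        new = (codes.astype(np.int64) + shift) % 4
        ok = codes < 4
        arr[idx[ok]] = _BASES[new[ok]]
    L = len(seqs[0])
    out = arr.tobytes().decode("ascii")
    return [out[i * L : (i + 1) * L] for i in range(len(seqs))]


# ---------------------------------------------------------------------------
# serialisation


def write_fastq(path: str | Path, reads: list[tuple[str, str, str]], suffix: str = "") -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}{suffix}\n{seq}\n+\n{qual}\n")


def write_simulation(
    out_dir: str | Path,
    ref: SimReference,
    cohort: SimCohort,
    design: LibraryDesign,
    result: LibraryResult,
) -> dict[str, str]:
    """Write FASTA/BED/FASTQ/truth and a JSON parameter sidecar; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": str(out / "reference.fa"),
        "track": str(out / "me_track.bed"),
        "junction_fastq": str(out / "junction.fastq"),
        "flank_fastq": str(out / "flank.fastq"),
        "index_table": str(out / "indexes.tsv"),
        "params": str(out / "params.json"),
    }
    ref.write_fasta(paths["reference"])
    ref.write_track(paths["track"])
    write_fastq(paths["junction_fastq"], result.junction_reads, "/1")
    write_fastq(paths["flank_fastq"], result.flank_reads, "/2")
    with open(paths["index_table"], "w") as fh:
        fh.write("# sample\tindex\tproportion\n")
        for s, i in design.indexes.items():
            fh.write(f"{s}\t{i}\t{design.proportions[s]}\n")
    result.truth.write(out)
    params = {
        "design": {
            "indexes": design.indexes,
            "proportions": design.proportions,
            "total_read_pairs": design.total_read_pairs,
            "dispersion": design.dispersion,
            "error_rate": design.error_rate,
            "fragment_len_range": list(design.fragment_len_range),
            "decoy_mean_pairs": design.decoy_mean_pairs,
            "adapter_contam_rate": design.adapter_contam_rate,
            "experiment": design.experiment,
            "seed": design.seed,
        },
        "n_individuals": len(cohort.individuals),
        "n_loci": len(cohort.loci),
        "polymorphic_known": ref.polymorphic_known,
    }
    with open(paths["params"], "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
    return paths


def load_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
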