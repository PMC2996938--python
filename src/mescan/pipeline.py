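"""Pipeline orchestration: simulate -> demux/QC -> map -> call -> annotate -> metrics.

A single :class:`PipelineConfig` drives every stage with the canonical
defaults; :func:`run_all` executes the stages in order and writes a
:class:`RunManifest` with stage-by-stage read-pair accounting (the counters
are non-increasing through the filter cascade), output checksums and a
config snapshot.  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, annotate, demux, loci, mapping, metrics, simulate
from .oligos import AMPLIFICATION_PBS, SEQUENCING_PRIMER, OligoSet

log = logging.getLogger("mescan")


@dataclass
class SimulateConfig:
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_target: int = 300
    n_decoy: int = 0
    n_duplications: int = 0
    n_known_polymorphic: int = 0
    n_individuals: int = 4
    fixed_fraction: float = 2 / 3
    allele_freq: float = 0.5
    singleton_rate: float = 0.0
    n_novel: int = 0
    indexes: dict[str, str] = field(
        default_factory=lambda: {"S1": "ACCAT", "S2": "TATTC", "S3": "GGTTA", "S4": "CGCTA"}
    )
    proportions: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.25, "S2": 0.25, "S3": 0.25, "S4": 0.25}
    )
    total_read_pairs: int = 30_000
    dispersion: float = 10.0
    error_rate: float = 0.004
    decoy_mean_pairs: float = 0.0
    adapter_contam_rate: float = 0.0
    experiment: str = "main"


@dataclass
class PipelineConfig:
    """Every stage threshold, with defaults equal to the method's canonical values."""

    out_dir: str = "mescan_out"
    seed: int = 0
    log_level: str = "INFO"
    # inputs (unused when `sim` is set)
    junction_fastq: str | None = None
    flank_fastq: str | None = None
    reference_fasta: str | None = None
    track: str | None = None
    index_table: str | None = None
    sim: SimulateConfig | None = field(default_factory=SimulateConfig)
    # demux / QC
    read_len: int = 36
    contam_threshold: int = 60
    qc_match: int = 5
    qc_mismatch: int = -4
    # mapping
    max_edit: int = 3
    trim_len: int = 16
    min_insert: int = 100
    max_insert: int = 1000
    # locus calling
    merge_tol: int = 3
    min_support: int = 10
    min_me_fraction: float = 0.5
    min_pairs_per_sample: int = 1
    # annotation
    pbs_word_size: int = 7
    amp_min_scan_score: int = 12
    seq_min_scan_score: int = 18
    fixed_params: annotate.FixedLocusParams = field(default_factory=annotate.FixedLocusParams)
    target_family: str = simulate.TARGET_FAMILY
    flag_duplications: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimulateConfig(**d["sim"])
        if d.get("fixed_params") is not None and not isinstance(
            d.get("fixed_params"), annotate.FixedLocusParams
        ):
            d["fixed_params"] = annotate.FixedLocusParams(**d["fixed_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def validate(self) -> None:
        if self.sim is None:
            missing = [
                k
                for k in ("junction_fastq", "flank_fastq", "reference_fasta", "track", "index_table")
                if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(f"no simulation configured and inputs missing: {missing}")
            for k in ("junction_fastq", "flank_fastq", "reference_fasta", "track", "index_table"):
                if not Path(getattr(self, k)).exists():
                    raise FileNotFoundError(getattr(self, k))


@dataclass
class RunManifest:
    counters: dict[str, int]
    files: dict[str, str]  # path -> sha256
    config: dict
    version: str = __version__

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    loci: list[loci.LocusRecord]
    calls: "object"
    counts: "object"
    classes: dict[str, str]
    fixed_loci: list[str]
    index_report: metrics.IndexProportionReport | None
    truth_eval: metrics.TruthEvaluation | None
    out_dir: Path


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; see the module docstring."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}

    # --- stage 1: simulate or load ------------------------------------------------
    truth = None
    design = None
    if config.sim is not None:
        s = config.sim
        ref = simulate.make_reference(
            chrom_lengths=dict(s.chrom_lengths),
            n_target=s.n_target,
            n_decoy=s.n_decoy,
            n_duplications=s.n_duplications,
            n_known_polymorphic=s.n_known_polymorphic,
            seed=config.seed,
        )
        cohort = simulate.simulate_cohort(
            ref,
            s.n_individuals,
            fixed_fraction=s.fixed_fraction,
            allele_freq_spec=s.allele_freq,
            singleton_rate=s.singleton_rate,
            n_novel=s.n_novel,
            seed=config.seed + 1,
            individuals=list(s.indexes),
        )
        design = simulate.LibraryDesign(
            indexes=dict(s.indexes),
            proportions=dict(s.proportions),
            total_read_pairs=s.total_read_pairs,
            dispersion=s.dispersion,
            error_rate=s.error_rate,
            decoy_mean_pairs=s.decoy_mean_pairs,
            adapter_contam_rate=s.adapter_contam_rate,
            experiment=s.experiment,
            seed=config.seed + 2,
        )
        lib = simulate.simulate_library(ref, cohort, design)
        simulate.write_simulation(out / "sim", ref, cohort, design, lib)
        truth = lib.truth
        sequences = ref.sequences
        me_track = ref.me_track
        polymorphic_known = ref.polymorphic_known
        index_to_sample = {v: k for k, v in design.indexes.items()}
        pairs = (
            demux.ReadPairRecord(rid, js, fs, jq, fq)
            for (rid, js, jq), (_rid, fs, fq) in zip(lib.junction_reads, lib.flank_reads)
        )
        experiment = s.experiment
        expected_pct = {k: 100.0 * v for k, v in design.proportions.items()}
    else:
        sequences = simulate.load_fasta(config.reference_fasta)
        me_track = simulate.read_track(config.track)
        polymorphic_known = []
        index_to_sample = demux.read_index_table(config.index_table)
        pairs = demux.read_pair_fastqs(config.junction_fastq, config.flank_fastq)
        experiment = "main"
        expected_pct = None

    # --- stage 2: demux + QC ------------------------------------------------------
    oligos = OligoSet()
    dm = demux.demux_stream(
        pairs,
        index_to_sample,
        oligos,
        read_len=config.read_len,
        match=config.qc_match,
        mismatch=config.qc_mismatch,
        contam_threshold=config.contam_threshold,
    )
    counters["total_pairs"] = dm.counters.total
    counters["rule_a_low_complexity"] = dm.counters.rule_a_low_complexity
    counters["rule_b_excess_n"] = dm.counters.rule_b_excess_n
    counters["rule_c_adapter"] = dm.counters.rule_c_adapter
    counters["high_quality"] = dm.counters.high_quality
    counters["index_valid"] = dm.counters.index_valid
    counters["unassigned_index"] = dm.counters.unassigned_index
    log.info("demux: %s", dm.counters.as_dict())

    sample_counts = {s: len(v) for s, v in dm.by_sample.items()}
    index_report = (
        metrics.index_proportions(sample_counts, expected_pct) if expected_pct else None
    )

    # motif presence among usable, index-valid junction reads
    usable = [(s, rec) for s, recs in dm.by_sample.items() for rec in recs]
    flags = loci.detect_me_batch([rec.junction_seq[: config.trim_len] for _s, rec in usable])
    counters["junction_has_motif"] = int(flags.sum())

    # --- stage 3: map + filter ----------------------------------------------------
    index = mapping.GenomeIndex(sequences)
    endpoints: list[loci.JunctionEndpoint] = []
    reject = {"NOT_PROPER": 0, "MAPQ_ZERO": 0, "EDIT_GT3": 0}
    for sample, rec in usable:
        res = mapping.dual_map(
            rec.junction_seq,
            rec.flank_seq,
            index,
            pair_id=rec.pair_id,
            trim_len=config.trim_len,
            max_subs=config.max_edit,
            min_insert=config.min_insert,
            max_insert=config.max_insert,
        )
        if res.accepted is None:
            reject[res.reason] = reject.get(res.reason, 0) + 1
            continue
        endpoints.append(loci.junction_endpoint(res.accepted, sample, experiment, config.trim_len))
    counters["mapped_pairs"] = len(endpoints)
    counters.update({f"rejected_{k.lower()}": v for k, v in reject.items()})
    log.info("mapping: %d accepted, rejects %s", len(endpoints), reject)

    # --- stage 4: call loci -------------------------------------------------------
    groups = loci.group_endpoints(endpoints, merge_tol=config.merge_tol)
    called = loci.call_loci(
        groups, min_support=config.min_support, min_me_fraction=config.min_me_fraction
    )
    calls, counts = loci.genotype_matrix(
        called, min_pairs_per_sample=config.min_pairs_per_sample,
        samples=sorted(dm.by_sample),
    )
    counters["called_loci"] = len(called)
    counters["final_support_pairs"] = sum(rec.total_support for rec in called)
    loci.write_locus_table(str(out / "loci.tsv"), called)
    calls.to_csv(out / "genotypes.tsv", sep="\t")
    counts.to_csv(out / "support_counts.tsv", sep="\t")

    # --- stage 5: annotate --------------------------------------------------------
    seq_sites = annotate.scan_pbs(
        sequences, SEQUENCING_PRIMER, role=annotate.SEQUENCING,
        min_score=config.seq_min_scan_score, word_size=config.pbs_word_size,
    )
    amp_sites = annotate.scan_pbs(
        sequences, AMPLIFICATION_PBS, role=annotate.AMPLIFICATION,
        min_score=config.amp_min_scan_score, word_size=config.pbs_word_size,
    )
    annotated = annotate.link_pbs_to_track(seq_sites, me_track)
    classes = annotate.classify_loci(called, annotated, target_family=config.target_family)
    fixed = annotate.select_fixed_loci(amp_sites, seq_sites, config.fixed_params, polymorphic_known)
    with open(out / "locus_classes.tsv", "w") as fh:
        fh.write("# locus_id\tclass\n")
        for lid, cls in sorted(classes.items()):
            fh.write(f"{lid}\t{cls}\n")
    with open(out / "fixed_loci.tsv", "w") as fh:
        fh.write("# locus_id (chrom:junction-endpoint)\n")
        for lid in fixed:
            fh.write(lid + "\n")

    if config.flag_duplications:
        scanner = annotate.DuplicationScanner(sequences)
        with open(out / "duplication_flags.tsv", "w") as fh:
            fh.write("# locus_id\tupstream_duplicated\n")
            for rec in called:
                flagged = _safe_dup_flag(scanner, rec, me_track)
                fh.write(f"{rec.locus_id}\t{int(flagged)}\n")

    # --- stage 6: metrics ---------------------------------------------------------
    truth_eval = None
    if truth is not None:
        truth_eval = metrics.evaluate_against_truth(calls, truth.carrier_matrix())
        with open(out / "truth_metrics.json", "w") as fh:
            json.dump(
                {
                    "overall": truth_eval.overall,
                    "per_sample": truth_eval.per_sample.to_dict(orient="index"),
                    "confusion": truth_eval.confusion,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
    if index_report is not None:
        index_report.table.to_csv(out / "index_proportions.tsv", sep="\t")

    files = {str(p.relative_to(out)): _sha256(p) for p in sorted(out.rglob("*")) if p.is_file()}
    manifest = RunManifest(counters, files, config.to_dict())
    manifest.write(out / "manifest.json")
    return PipelineResult(
        manifest, called, calls, counts, classes, fixed, index_report, truth_eval, out
    )


def _safe_dup_flag(scanner, rec, me_track) -> bool:
    # infer the junction coordinate and strand from the nearest track element;
    # for novel loci assume plus-sense geometry (endpoint 20 bp below junction)
    for e in me_track:
        if e.chrom == rec.chrom and abs(e.expected_endpoint - rec.position) <= 3:
            junction, strand = e.junction, e.strand
            break
    else:
        junction, strand = rec.position + simulate.JUNCTION_FLANK, "+"
    try:
        return annotate.flag_upstream_duplication(scanner, rec.chrom, junction, strand)
    except ValueError:
        return False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def report_table1(manifest: RunManifest):
    """Read-pair accounting table with percentages of the total."""
    import pandas as pd

    c = manifest.counters
    total = c.get("total_pairs", 0)
    rows = [
        ("Total read pairs", c.get("total_pairs", 0)),
        ("Both reads of high quality (not a, b or c)", c.get("high_quality", 0)),
        ("(a) Either read is > 85% one base", c.get("rule_a_low_complexity", 0)),
        ("(b) Either read has > 2 'N' base calls", c.get("rule_b_excess_n", 0)),
        ("(c) Adapter sequence detected in either read", c.get("rule_c_adapter", 0)),
        ("High quality, index valid", c.get("index_valid", 0)),
        ("Junction read has element motif", c.get("junction_has_motif", 0)),
        ("Supports an insertion in the final results", c.get("final_support_pairs", 0)),
    ]
    df = pd.DataFrame(rows, columns=["quality_classification", "read_pairs"])
    df["pct_of_total"] = [
        metrics.round_sig(100.0 * n / total, 3) if total else 0.0 for _, n in rows
    ]
    return df
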