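"""Internal mapper vs brute-force oracle; pair filters; SAM ingestion."""

import pytest

from mescan import mapping, simulate
from mescan.mapping import (
    EDIT_GT3,
    INTACT,
    MAPQ_ZERO,
    NOT_PROPER,
    OK,
    TRIMMED,
    MateAlignment,
    PairAlignment,
    brute_force_map,
    cigar_reference_length,
    dual_map,
    filter_pair,
    toy_map,
)
from mescan.oligos import revcomp


def _mutate(rng, seq, n):
    s = list(seq)
    for p in rng.choice(len(s), size=n, replace=False):
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


class TestToyMap:
    def test_unique_exact_substring_maps_cleanly(self, small_ref, small_index):
        seq = small_ref.sequences["chrA"]
        read = seq[5000:5036]
        alns = toy_map(read, small_index)
        best = [a for a in alns if a.n_subs == 0]
        assert len(best) == 1
        a = best[0]
        assert (a.chrom, a.pos, a.strand, a.mapq) == ("chrA", 5001, "+", 37)

    def test_reverse_strand_read_found(self, small_ref, small_index):
        seq = small_ref.sequences["chrA"]
        read = revcomp(seq[7000:7036])
        alns = toy_map(read, small_index)
        assert any(a.pos == 7001 and a.strand == "-" for a in alns)

    def test_duplicated_block_read_gets_mapq_zero(self, small_ref, small_index):
        blk = small_ref.duplicated_blocks[0]
        # junction-window region of the duplicated element is copied verbatim
        e = next(t for t in small_ref.targets if t.in_duplication)
        j = e.junction
        read = small_ref.sequences[e.chrom][j - 10 : j + 26]
        alns = toy_map(read, small_index)
        zero_sub = [a for a in alns if a.n_subs == 0]
        assert len(zero_sub) >= 2
        assert all(a.mapq == 0 for a in alns)

    def test_four_substitutions_not_reported(self, small_ref, small_index, rng):
        seq = small_ref.sequences["chrA"]
        read = _mutate(rng, seq[9000:9036], 4)
        assert all(a.n_subs <= 3 for a in toy_map(read, small_index))

    def test_matches_brute_force_oracle(self, small_ref, small_index, rng):
        seq = small_ref.sequences["chrA"]
        for trial in range(40):
            start = int(rng.integers(0, len(seq) - 36))
            m = int(rng.choice([20, 30, 36]))
            read = seq[start : start + m]
            nmut = int(rng.integers(0, 4))
            read = _mutate(rng, read, nmut)
            if rng.random() < 0.5:
                read = revcomp(read)
            got = {(a.chrom, a.pos, a.strand, a.n_subs, a.mapq) for a in toy_map(read, small_index)}
            exp = {
                (a.chrom, a.pos, a.strand, a.n_subs, a.mapq)
                for a in brute_force_map(read, small_ref.sequences)
            }
            assert got == exp


class TestFilterPair:
    def _mate(self, mapq=37, edit=0, pos=1000, strand="+", cigar="36M"):
        return MateAlignment(True, "chr1", pos, strand, cigar, mapq, edit)

    def _pair(self, j, f, proper=True):
        return PairAlignment(j, f, proper, INTACT)

    def test_clean_proper_pair_is_ok(self):
        v = filter_pair(self._pair(self._mate(edit=0), self._mate(edit=1, pos=1600, strand="-")))
        assert v.keep and v.reason == OK

    def test_mapq_zero_on_either_mate_discards(self):
        v = filter_pair(self._pair(self._mate(mapq=0), self._mate(pos=1600, strand="-")))
        assert v.reason == MAPQ_ZERO
        v = filter_pair(self._pair(self._mate(), self._mate(mapq=0, pos=1600, strand="-")))
        assert v.reason == MAPQ_ZERO

    def test_edit_distance_four_discards(self):
        v = filter_pair(self._pair(self._mate(edit=4), self._mate(pos=1600, strand="-")))
        assert v.reason == EDIT_GT3

    def test_improper_orientation_discards_first(self):
        v = filter_pair(self._pair(self._mate(mapq=0), self._mate(), proper=False))
        assert v.reason == NOT_PROPER

    def test_unmapped_mate_is_not_proper(self):
        v = filter_pair(self._pair(self._mate(), MateAlignment(False), proper=True))
        assert v.reason == NOT_PROPER


class TestDualMap:
    def test_reference_element_pair_accepts_intact(self, small_ref, small_index):
        design = simulate.LibraryDesign(
            indexes={"S1": "ACCAT"}, proportions={"S1": 1.0},
            total_read_pairs=60, error_rate=0.0, dispersion=1.0, seed=3,
        )
        cohort1 = simulate.simulate_cohort(small_ref, 1, fixed_fraction=1.0, seed=0, individuals=["S1"])
        lib = simulate.simulate_library(small_ref, cohort1, design)
        dup_ids = {e.locus_id for e in small_ref.targets if e.in_duplication}
        tr = lib.truth.pairs.set_index("read_id")
        checked = 0
        for (rid, js, _q), (_r, fs, _q2) in zip(lib.junction_reads, lib.flank_reads):
            if tr.loc[rid, "locus_id"] in dup_ids:
                continue
            res = dual_map(js, fs[6:], small_index)
            assert res.accepted_mode == INTACT
            checked += 1
            if checked >= 10:
                break
        assert checked > 0

    def test_novel_insertion_pair_accepts_trimmed_only(self, small_ref, small_index):
        cohort = simulate.simulate_cohort(
            small_ref, 1, fixed_fraction=0.0, allele_freq_spec=1.0, n_novel=2, seed=9,
            individuals=["S1"],
        )
        design = simulate.LibraryDesign(
            indexes={"S1": "ACCAT"}, proportions={"S1": 1.0},
            total_read_pairs=400, error_rate=0.0, seed=4,
        )
        lib = simulate.simulate_library(small_ref, cohort, design)
        novel_ids = {l.locus_id for l in cohort.loci if not l.in_reference}
        tr = lib.truth.pairs.set_index("read_id")
        seen = 0
        for (rid, js, _q), (_r, fs, _q2) in zip(lib.junction_reads, lib.flank_reads):
            if tr.loc[rid, "locus_id"] in novel_ids:
                res = dual_map(js, fs[6:], small_index)
                assert res.accepted_mode == TRIMMED
                assert not res.intact_verdict.keep
                seen += 1
                if seen >= 10:
                    break
        assert seen > 0

    def test_random_read_pair_is_unmapped(self, small_index, rng):
        js = "".join(rng.choice(list("ACGT"), size=36))
        fs = "".join(rng.choice(list("ACGT"), size=30))
        res = dual_map(js, fs, small_index)
        assert res.accepted is None


class TestCigar:
    @pytest.mark.parametrize(
        "cigar,expected",
        [("36M", 36), ("10M2D26M", 38), ("10M2I24M", 34), ("5S31M", 31), ("20M", 20)],
    )
    def test_reference_consumed_length(self, cigar, expected):
        assert cigar_reference_length(cigar) == expected

    def test_zero_reference_consumption_raises(self):
        with pytest.raises(ValueError):
            cigar_reference_length("36I")


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:10000\n"


def _sam_line(qname, flag, pos, cigar="36M", mapq=37, nm=0):
    seq = "A" * 36
    return (
        f"{qname}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t=\t{pos + 100}\t200\t{seq}\t"
        f"{'I' * 36}\tNM:i:{nm}\n"
    )


class TestIngestSam:
    def _write(self, tmp_path, lines):
        p = tmp_path / "in.sam"
        p.write_text(SAM_HEADER + "".join(lines))
        return str(p)

    @pytest.mark.parametrize("flags,proper", [((99, 147), True), ((83, 163), True), ((97, 145), False)])
    def test_flag_pairs_determine_properness(self, tmp_path, flags, proper):
        sam = self._write(
            tmp_path, [_sam_line("p1", flags[0], 100), _sam_line("p1", flags[1], 300)]
        )
        pairs = list(mapping.ingest_sam(sam))
        assert len(pairs) == 1
        assert pairs[0].properly_paired is proper

    def test_missing_mate_is_counted_and_dropped(self, tmp_path):
        stats = mapping.IngestStats()
        sam = self._write(tmp_path, [_sam_line("lonely", 99, 100)])
        assert list(mapping.ingest_sam(sam, stats=stats)) == []
        assert stats.missing_mate == 1 and stats.skipped_ids == ["lonely"]

    def test_edit_distance_includes_clipped_bases(self, tmp_path):
        sam = self._write(
            tmp_path,
            [_sam_line("p1", 99, 100, cigar="4S32M", nm=1), _sam_line("p1", 147, 300)],
        )
        (pair,) = mapping.ingest_sam(sam)
        assert pair.junction.edit == 5  # NM 1 + 4 soft-clipped
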