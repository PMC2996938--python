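"""PBS scanning, locus classification, fixed-locus selection, duplication flags."""

import pytest

from mescan import loci, simulate
from mescan.annotate import (
    AMPLIFICATION,
    KNOWN_TARGET,
    NONSPECIFIC,
    NOVEL,
    SEQUENCING,
    DuplicationScanner,
    PrimerSite,
    brute_force_scan,
    classify_loci,
    compare_locus_lists,
    flag_upstream_duplication,
    link_pbs_to_track,
    scan_pbs,
    select_fixed_loci,
)
from mescan.oligos import AMPLIFICATION_PBS, SEQUENCING_PRIMER, revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanPbs:
    def test_verbatim_planting_found_with_full_score(self, rng):
        background = _random_seq(rng, 3000)
        seq = background[:1500] + SEQUENCING_PRIMER + background[1500:]
        sites = scan_pbs({"c": seq}, SEQUENCING_PRIMER, min_score=18)
        exact = [s for s in sites if s.score == len(SEQUENCING_PRIMER)]
        assert len(exact) == 1
        s = exact[0]
        assert s.strand == "+" and s.mismatches_in_3prime_10 == 0
        assert (s.footprint_start, s.footprint_end) == (1501, 1500 + len(SEQUENCING_PRIMER))

    def test_single_3prime_substitution_is_counted(self, rng):
        primer = SEQUENCING_PRIMER
        mutated = list(primer)
        p = len(primer) - 5  # 3' position 5
        mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        seq = _random_seq(rng, 1000) + "".join(mutated) + _random_seq(rng, 1000)
        sites = scan_pbs({"c": seq}, primer, min_score=18)
        assert any(s.mismatches_in_3prime_10 == 1 for s in sites)

    def test_scan_is_symmetric_under_reverse_complement(self, rng):
        seq = _random_seq(rng, 800) + SEQUENCING_PRIMER + _random_seq(rng, 800)
        fwd = scan_pbs({"c": seq}, SEQUENCING_PRIMER, min_score=20)
        rev = scan_pbs({"c": revcomp(seq)}, SEQUENCING_PRIMER, min_score=20)
        n = len(seq)
        mirrored = {
            (n - s.footprint_end + 1, n - s.footprint_start + 1, "-" if s.strand == "+" else "+", s.score)
            for s in rev
        }
        assert {(s.footprint_start, s.footprint_end, s.strand, s.score) for s in fwd} == mirrored

    def test_matches_all_offsets_oracle(self, small_ref):
        for primer, min_score in ((SEQUENCING_PRIMER, 18), (AMPLIFICATION_PBS, 12)):
            sites = scan_pbs(small_ref.sequences, primer, min_score=min_score)
            got = {(s.chrom, s.footprint_start, s.strand, s.score) for s in sites}
            exp = set(brute_force_scan(small_ref.sequences, primer, min_score=min_score))
            # the seeded scan must find every oracle hit that shares a 7-mer
            # with the primer; at these thresholds that is all of them
            assert got == exp


@pytest.fixture(scope="module")
def called(small_endpoints):
    endpoints, _ = small_endpoints
    return loci.call_loci(loci.group_endpoints(endpoints), min_support=5)


@pytest.fixture(scope="module")
def annotated(small_ref):
    sites = scan_pbs(small_ref.sequences, SEQUENCING_PRIMER, role=SEQUENCING, min_score=18)
    return link_pbs_to_track(sites, small_ref.me_track)


class TestLinkAndClassify:
    def test_sites_inside_elements_are_linked(self, small_ref, annotated):
        linked = [a for a in annotated if a.family is not None]
        assert len(linked) >= len(small_ref.targets)
        assert {a.family for a in linked} <= {"target", "decoy"}

    def test_predicted_endpoints_match_planted_geometry(self, small_ref, annotated):
        expected = {e.expected_endpoint for e in small_ref.me_track}
        predicted = {a.predicted_endpoint for a in annotated if a.family}
        assert expected <= predicted

    def test_three_classes_assigned_exhaustively(self, small_ref, small_cohort, called, annotated):
        classes = classify_loci(called, annotated)
        assert set(classes) == {rec.locus_id for rec in called}
        novel_ids = {l.locus_id for l in small_cohort.loci if not l.in_reference}
        decoy_ids = {e.locus_id for e in small_ref.decoys}
        target_ids = {e.locus_id for e in small_ref.targets}
        for rec in called:
            cls = classes[rec.locus_id]
            if rec.locus_id in novel_ids:
                assert cls == NOVEL
            elif rec.locus_id in decoy_ids:
                assert cls == NONSPECIFIC
            elif rec.locus_id in target_ids:
                assert cls == KNOWN_TARGET


def _site(chrom="c", start=1000, strand="+", score=30, mm=0, role=SEQUENCING, length=27):
    return PrimerSite(chrom, start, start + length - 1, strand, score, mm, role, start, start + length - 1)


class TestSelectFixedLoci:
    def test_spacing_boundaries_inclusive(self):
        for sep, expected in ((224, 1), (239, 1), (240, 0), (209, 1), (208, 0)):
            amp = [_site(start=1000, role=AMPLIFICATION, length=20)]
            seq = [_site(start=1000 + sep)]
            got = select_fixed_loci(amp, seq)
            assert len(got) == expected, sep

    def test_opposite_orientation_rejected(self):
        amp = [_site(start=1000, role=AMPLIFICATION, length=20)]
        seq = [_site(start=1224, strand="-")]
        assert select_fixed_loci(amp, seq) == []

    def test_sequencing_pbs_must_be_three_prime_of_amplification(self):
        # on the minus strand "downstream" means a lower start coordinate
        amp = [_site(start=1224, strand="-", role=AMPLIFICATION, length=20)]
        seq = [_site(start=1000, strand="-")]
        assert len(select_fixed_loci(amp, seq)) == 1
        assert select_fixed_loci(
            [_site(start=1000, strand="-", role=AMPLIFICATION, length=20)],
            [_site(start=1224, strand="-")],
        ) == []

    def test_3prime_mismatch_excludes(self):
        amp = [_site(start=1000, role=AMPLIFICATION, length=20)]
        seq = [_site(start=1224, mm=1)]
        assert select_fixed_loci(amp, seq) == []

    def test_polymorphic_list_excludes(self):
        amp = [_site(start=1000, role=AMPLIFICATION, length=20)]
        seq = [_site(start=1224)]
        (lid,) = select_fixed_loci(amp, seq)
        assert select_fixed_loci(amp, seq, polymorphic_list=[lid]) == []

    def test_recovers_exactly_planted_targets_on_clean_reference(self):
        ref = simulate.make_reference(
            {"chr1": 200_000}, n_target=15, n_decoy=4, n_duplications=0,
            n_known_polymorphic=3, seed=17,
        )
        seq_sites = scan_pbs(ref.sequences, SEQUENCING_PRIMER, role=SEQUENCING, min_score=18)
        amp_sites = scan_pbs(ref.sequences, AMPLIFICATION_PBS, role=AMPLIFICATION, min_score=12)
        got = select_fixed_loci(amp_sites, seq_sites, polymorphic_list=ref.polymorphic_known)
        expected = sorted(
            e.locus_id for e in ref.targets if e.locus_id not in set(ref.polymorphic_known)
        )
        assert got == expected


class TestUpstreamDuplication:
    def test_duplicated_locus_flagged_unique_locus_not(self, small_ref):
        scanner = DuplicationScanner(small_ref.sequences)
        for e in small_ref.targets:
            flagged = flag_upstream_duplication(scanner, e.chrom, e.junction, e.strand)
            assert flagged == e.in_duplication

    def test_98_percent_identity_is_below_threshold(self, rng):
        window = _random_seq(rng, 500)
        copy = list(window)
        for p in rng.choice(500, size=10, replace=False):  # 98% identity
            copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
        seq = window + _random_seq(rng, 2000) + "".join(copy) + _random_seq(rng, 600)
        assert not flag_upstream_duplication({"c": seq}, "c", 501, "+", min_identity=0.99)
        # an exact copy of the same window is detected
        seq2 = window + _random_seq(rng, 2000) + window + _random_seq(rng, 600)
        assert flag_upstream_duplication({"c": seq2}, "c", 501, "+", min_identity=0.99)

    def test_insufficient_upstream_sequence_raises(self, rng):
        seq = _random_seq(rng, 1000)
        with pytest.raises(ValueError):
            flag_upstream_duplication({"c": seq}, "c", 300, "+")


class TestCompareLocusLists:
    def test_identical_lists_fully_matched(self):
        a = [("c", 100), ("c", 900), ("d", 50)]
        m, ua, ub = compare_locus_lists(a, list(a))
        assert (m, ua, ub) == (3, [], [])

    def test_offset_boundary_at_50(self):
        m, _, _ = compare_locus_lists([("c", 100)], [("c", 150)])
        assert m == 1
        m, ua, ub = compare_locus_lists([("c", 100)], [("c", 151)])
        assert m == 0 and ua == [("c", 100)] and ub == [("c", 151)]

    def test_disjoint_lists_unmatched(self):
        m, ua, ub = compare_locus_lists([("c", 100)], [("e", 100), ("c", 5000)])
        assert m == 0 and len(ua) == 1 and len(ub) == 2

    def test_each_locus_matches_at_most_once(self):
        m, ua, ub = compare_locus_lists([("c", 100)], [("c", 90), ("c", 110)])
        assert m == 1 and len(ub) == 1
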