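"""Junction endpoints, grouping/merging, motif detection and genotyping."""

import numpy as np
import pytest
from Bio import Align

from mescan import loci
from mescan.loci import (
    JunctionEndpoint,
    MEMotifParams,
    brute_force_group,
    call_loci,
    detect_me_sequence,
    genotype_matrix,
    group_endpoints,
    junction_endpoint,
)
from mescan.mapping import INTACT, TRIMMED, MateAlignment, PairAlignment
from mescan.oligos import ME_MOTIF


def _pair(pos, strand="+", cigar="36M", mode=INTACT, seq="G" * 36):
    j = MateAlignment(True, "chr1", pos, strand, cigar, 37, 0)
    f = MateAlignment(True, "chr1", pos + 300, "-" if strand == "+" else "+", "30M", 37, 0)
    return PairAlignment(j, f, True, mode, "p", seq)


class TestJunctionEndpoint:
    @pytest.mark.parametrize(
        "pos,cigar,expected",
        [(1001, "36M", 1036), (1001, "10M2D26M", 1038), (1001, "10M2I24M", 1034)],
    )
    def test_forward_strand_consumes_reference(self, pos, cigar, expected):
        ep = junction_endpoint(_pair(pos, cigar=cigar), "A")
        assert ep.position == expected

    def test_reverse_strand_uses_leftmost_position(self):
        ep = junction_endpoint(_pair(2500, strand="-"), "A")
        assert ep.position == 2500

    def test_trimmed_read_gives_same_endpoint_as_intact(self):
        intact = junction_endpoint(_pair(1001, cigar="36M"), "A")
        trimmed = junction_endpoint(_pair(1017, cigar="20M", mode=TRIMMED), "A")
        assert intact.position == trimmed.position == 1036

    def test_intact_trimmed_identity_on_simulated_pairs(self, small_endpoints, small_library):
        endpoints, _rejects = small_endpoints
        _design, lib = small_library
        truth = lib.truth.pairs.set_index("read_id")["endpoint"]
        # every accepted endpoint equals the simulator's intended endpoint
        # irrespective of the mode it mapped under
        by_pos = {}
        for ep in endpoints:
            by_pos.setdefault((ep.chrom, ep.position), set()).add(ep.mode)
        intended = set(truth.values)
        matched = [p for (_c, p), _m in by_pos.items() if p in intended]
        assert len(matched) >= 0.95 * len(by_pos)


def _ep(pos, sample="A", chrom="chr1", lead=ME_MOTIF + "T"):
    return JunctionEndpoint(chrom, pos, INTACT, sample, "main", lead)


class TestGrouping:
    def test_singleton_absorbed_into_large_neighbour(self):
        eps = [_ep(1036) for _ in range(50)] + [_ep(1037)]
        (g,) = group_endpoints(eps)
        assert g.position == 1036 and g.size == 51

    def test_gap_of_four_keeps_groups_distinct(self):
        eps = [_ep(1036) for _ in range(50)] + [_ep(1040) for _ in range(50)]
        groups = group_endpoints(eps)
        assert sorted(g.position for g in groups) == [1036, 1040]

    def test_boundary_gap_three_is_mergeable(self):
        eps = [_ep(1036) for _ in range(50)] + [_ep(1039)]
        (g,) = group_endpoints(eps)
        assert g.size == 51

    def test_equidistant_singleton_goes_to_lower_coordinate(self):
        eps = (
            [_ep(1036) for _ in range(50)]
            + [_ep(1039)]
            + [_ep(1042) for _ in range(50)]
        )
        groups = {g.position: g.size for g in group_endpoints(eps)}
        assert groups == {1036: 51, 1042: 50}

    def test_two_adjacent_multiread_groups_not_merged(self):
        eps = [_ep(1036), _ep(1036), _ep(1038), _ep(1038)]
        assert len(group_endpoints(eps)) == 2

    def test_support_is_conserved_and_never_moves_far(self, rng):
        positions = rng.choice(np.arange(1000, 1200), size=300).tolist()
        eps = [_ep(int(p)) for p in positions]
        groups = group_endpoints(eps)
        assert sum(g.size for g in groups) == 300
        for g in groups:
            for ep in g.endpoints:
                assert abs(ep.position - g.position) <= 3

    def test_matches_brute_force_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            positions = rng.choice(np.arange(500, 560), size=int(rng.integers(5, 80)))
            eps = [_ep(int(p)) for p in positions]
            got = {(g.chrom, g.position): g.size for g in group_endpoints(eps)}
            assert got == brute_force_group(eps)


class TestMotifDetection:
    def test_perfect_motif_detected(self):
        assert detect_me_sequence(ME_MOTIF + "T")

    def test_two_substitutions_still_scores_above_threshold(self):
        mutated = "T" + ME_MOTIF[1:7] + "A" + ME_MOTIF[8:]  # 13*5 - 2*4 = 57
        assert detect_me_sequence(mutated + "G")

    def test_exact_ten_base_prefix_suffices(self):
        lead = ME_MOTIF[:10] + "TTTTTT"
        assert detect_me_sequence(lead)

    def test_random_16mers_agree_with_smith_waterman_oracle(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -72
        aligner.extend_gap_score = -8
        params = MEMotifParams()
        n_pos = 0
        for _ in range(300):
            lead = "".join(rng.choice(list("ACGT"), size=16))
            oracle = (
                lead[:10] == ME_MOTIF[:10]
                or aligner.score(lead, ME_MOTIF) >= params.min_score
            )
            got = detect_me_sequence(lead, params)
            assert got == oracle
            n_pos += got
        assert n_pos < 30  # random sequence rarely passes

    def test_batch_detection_matches_scalar(self, rng):
        leads = ["".join(rng.choice(list("ACGT"), size=16)) for _ in range(100)]
        leads += [ME_MOTIF + "T", ME_MOTIF[:10] + "AAAAAA"]
        flags = loci.detect_me_batch(leads)
        for lead, flag in zip(leads, flags):
            assert detect_me_sequence(lead) == bool(flag)


class TestCallLoci:
    def _group(self, n, n_motif, pos=1036):
        eps = [
            _ep(pos, lead=(ME_MOTIF + "T" if i < n_motif else "T" * 16))
            for i in range(n)
        ]
        return group_endpoints(eps)

    def test_support_nine_dropped_ten_kept(self):
        assert call_loci(self._group(9, 9)) == []
        assert len(call_loci(self._group(10, 10))) == 1

    def test_motif_fraction_boundary_is_inclusive_at_half(self):
        assert call_loci(self._group(10, 4)) == []  # 0.4
        (rec,) = call_loci(self._group(10, 5))  # 0.5
        assert rec.me_fraction == 0.5

    def test_support_broken_down_by_experiment_and_sample(self):
        eps = [_ep(100, sample="A") for _ in range(7)] + [_ep(100, sample="B") for _ in range(5)]
        (rec,) = call_loci(group_endpoints(eps))
        assert rec.support == {("main", "A"): 7, ("main", "B"): 5}
        assert rec.total_support == 12


class TestGenotypeMatrix:
    def _loci(self):
        eps = [_ep(100, sample="A") for _ in range(12)] + [_ep(100, sample="B")] * 0
        return call_loci(group_endpoints(eps))

    def test_presence_and_absence(self):
        calls, counts = genotype_matrix(self._loci(), samples=["A", "B"])
        assert calls.loc["chr1:100", "A"] == 1
        assert calls.loc["chr1:100", "B"] == 0
        assert counts.loc["chr1:100", "A"] == 12

    def test_threshold_two_suppresses_single_pair_evidence(self):
        eps = [_ep(100, sample="A")] * 1 + [_ep(100, sample="B")] * 11
        recs = call_loci(group_endpoints(eps))
        calls, _ = genotype_matrix(recs, min_pairs_per_sample=2)
        assert calls.loc["chr1:100", "A"] == 0 and calls.loc["chr1:100", "B"] == 1

    def test_matrix_matches_simulated_truth(self, small_endpoints, small_library, small_cohort):
        _design, lib = small_library
        endpoints, _ = small_endpoints
        recs = call_loci(group_endpoints(endpoints))
        calls, _ = genotype_matrix(recs, samples=small_cohort.individuals)
        from mescan import metrics

        ev = metrics.evaluate_against_truth(calls, lib.truth.carrier_matrix())
        # decoy emissions and the duplicated locus aside, calls track truth
        assert ev.overall["sensitivity"] >= 80.0
        assert ev.confusion["tp"] > 0
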