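# Methods

## Assay model

The package analyses (and simulates) a subfamily-targeted sequencing assay
for mobile-element insertions. Genomic DNA is fragmented, ligated to
adapters carrying a 5-nt sample index plus a `T`, pooled across samples, and
enriched by PCR with a biotinylated element-specific primer; fragments of
650–700 bp are size-selected and sequenced as 2×36-bp pairs. A custom
element-internal sequencing primer produces the junction read: 16 nt of
element sequence followed by 20 nt of genomic flank beyond the element's 5′
junction. The mate (flank read) is `index + T + 30 nt` of genomic sequence
from the fragment's far end.

The coordinate of the junction read's **last** sequenced base — about 20 bp
past the 5′ junction — identifies the insertion locus. It is computed from
the alignment (POS + reference-consumed CIGAR length − 1 on the forward
strand; POS on the reverse strand, where the read's last base is its
leftmost reference base) and is identical whether the read mapped intact or
with its 16-nt element prefix trimmed, which is what makes the identifier
usable for insertions absent from the reference.

## Pipeline stages and their parameters

**Demultiplexing.** Exact 5-mer index match wins; a unique Hamming-distance-1
match is corrected; ties at distance 1 (or distance ≥2 from everything) are
unassigned. `N` counts as a mismatch — index matching with ambiguous bases
is not specified by the protocol, and counting `N` as a mismatch lets the
single-mismatch correction handle isolated no-calls naturally. The first 6
flank bases (index + `T`) are trimmed; a non-`T` at position 6 is counted in
a diagnostic but never used for rejection.

**Quality rules.** (a) >85% of a read one base; (b) >2 `N` calls; (c)
ungapped local alignment score >60 against any library oligo or its reverse
complement, excluding the element-specific 3′ 20 nt of the amplification
primer (genuine junction reads legitimately contain that sequence; the
element-internal sequencing primer is excluded from screening for the same
reason). The scoring pair for rule (c) is not dictated by the thresholds'
provenance, so the package uses the common DNA pair match +5 / mismatch −4
(configurable); at that scale the >60 threshold needs roughly 13 consecutive
matching bases. A pair is bucketed by the first failing rule in the order
a, b, c, so the three rule counters are mutually exclusive.

**Mapping and pair filters.** Junction reads are mapped twice — intact, and
with the first 16 nt trimmed. A pair passing the filters intact sits at an
element present in the reference (its trimmed result is redundant and
ignored); a pair passing only after trimming is evidence of a non-reference
insertion. Filters, in order: not properly paired (both mates mapped, on
opposite strands, oriented toward each other, outer span within a
configurable 100–1000 nt window — a fixed stand-in for an aligner's
internally estimated insert distribution, chosen to cover the 650–700
size-selection with margin); mapping quality 0 on either mate; more than 3
mismatched or unmatched bases on either mate (substitutions + clipped or
indel bases).

The built-in mapper reports *all* end-to-end alignments of a read with ≤3
substitutions on both strands. Seeding is by pigeonhole: the read is
partitioned into `max_subs + 1` disjoint exact segments, at least one of
which must be error-free in any qualifying alignment, so the scan is
provably complete (a fixed-length seed cannot guarantee this for a 20-nt
trimmed read with 3 substitutions). A unique best hit gets mapping quality
37; tied best hits get 0 — only zero/nonzero matters downstream. Mate
placement is pairing-aware: among all candidate alignments the
properly-paired combination with fewest substitutions is chosen, but each
mate keeps the quality reflecting its genome-wide uniqueness, so reads from
duplicated regions are still removed by the quality filter even though
pairing could place them. Externally produced alignments enter through SAM
ingestion instead; properly-paired status is taken from the flag pairs
99/147 and 83/163.

**Locus calling.** Endpoints sharing an exact position form support groups.
Only groups of size 1 are merged: a singleton within 3 bp of a group of ≥2
is absorbed into the most numerous neighbour, ties broken toward the nearer
group and then toward the lower coordinate (the published rule names only
"the most numerous neighbouring group"; the tie-breaks are this package's
determinism choice). Two nearby multi-read groups always stay distinct.
Loci are retained with ≥10 supporting pairs summed over all samples and
experiments, and with ≥50% of supporting junction reads containing the
element motif; both thresholds are inclusive. The motif fraction's
denominator aggregates all samples and experiments before the 50% rule.

**Element-motif detection.** A junction read's leading 16 nt contain the
motif when they match it exactly over the first 10 bases, or when a local
alignment against the motif scores ≥45 under match +5 / mismatch −4, gap
open 64, gap extend 8 (a gap of length L costs `64 + 8L`; at these costs
gaps are effectively forbidden, but the full affine Smith–Waterman is
implemented and is the documented criterion). Two interpretation notes: the
printed motif `GCC ACC GCG CCC GGC` is 15 nt although the junction segment
is described as 16 bp — the motif is configurable and the package does not
silently pad it; and "matched at 10 bp" is read as identity over the first
10 motif bases (not any 10 identities), also configurable.

**Genotyping.** Presence for a (locus, sample) cell requires ≥1 supporting
pair by default (any supporting reads are treated as evidence); the
threshold is configurable to study the sensitivity–coverage trade-off. No
diploid dosage is inferred — calls are dominant presence/absence.

**Primer-binding-site scan and annotation.** The scanner finds ungapped
local matches of a primer on both strands, seeded by shared exact 7-mers;
each diagonal's maximal-scoring segment is reported above a threshold,
together with the full-primer placement and the mismatch count in the
primer's 3′ 10 bases. Scoring defaults to match +1 / mismatch −3. The
published fixed-locus score thresholds (32.2 and 46.1) are bit-like scores
of a particular external search tool whose normalisation constants are not
recoverable; the package's `FixedLocusParams` defaults are therefore
calibrated on the raw scale — 16 of a maximal 20 for the amplification PBS
and 22 of a maximal 27 for the sequencing PBS, i.e. one mismatch allowed —
and are fully configurable. Fixed-locus selection additionally requires:
start positions (leftmost plus-strand coordinates) separated by 224 ± 15 bp
inclusive; the same orientation; the sequencing PBS 3′ of the amplification
PBS *in the orientation of the PBS strand*; zero mismatches in both 3′ 10-bp
windows; and absence from the known-polymorphic list. Sequencing-PBS sites
predict the endpoint of the 36-nt read they would prime (footprint end + 36
on the plus strand, footprint start − 36 on the minus strand) and are linked
to called loci within ±3 bp, yielding three exhaustive, exclusive classes:
known target, non-specific (another element family), novel (no linkage).

**Upstream-duplication flag.** A locus is flagged when the 500 bp of flank
on the junction-read side has a ≥99%-identical copy elsewhere (31-mer
seeding, ungapped full-window verification on both strands; identity =
matches/window). Reads from such loci cannot map uniquely and are removed
by the quality filter — the dominant structural cause of false negatives.

**Locus-list comparison.** Greedy nearest-first pairing within 50 bp, each
locus matched at most once.

## The simulator

The simulator emulates the assay geometry exactly, not the biochemistry:
elements of 300 bp are planted in random background sequence (GC 0.41) with
the junction 16-mer, the sequencing PBS, and the amplification PBS at fixed
internal offsets chosen so that the two PBS plus-strand starts are separated
by ~224 bp and the sequencing PBS is 3′ of the amplification PBS; a poly-A
tail (default 20 nt) and target-site duplication (default 15 nt) are planted
for realism only. Decoy ("older family") elements carry ≥1 substitution in
the sequencing PBS's 3′ 10 bp and 2 substitutions in the junction segment —
degenerate enough to fail fixed-locus selection while still being
motif-detectable when they amplify sporadically. Duplicated blocks copy an
element plus its 500-bp upstream flank at ~99.5% identity; the copy's
divergence is placed outside the junction-read window so that junction reads
from source and copy genuinely tie in the mapper, which is the mechanism the
duplication filter is meant to catch.

Coverage per (locus, sample) is negative-binomial with mean
`total_pairs · proportion · (copies/2)` normalised over the sample's carried
loci, and variance `dispersion × mean` (default 10) — a Poisson model cannot
reproduce the empirically observed variance ≳10× mean of amplified fragment
libraries. Fragment length is uniform on 650–700 (the size-selection window;
the true post-selection distribution is unknown, and the window is
configurable). Errors are independent per-base substitutions (default
0.004); indel errors in 36-nt reads are rare and would be absorbed by the
alignment filters, so they are not modelled. Adapter contamination can be
planted at a configurable rate. Element truncation, PCR chimeras and
quality-score profiles are not modelled; decoys without usable motifs cover
the detection-failure path that 5′-truncated elements would exercise.

What passing simulation-based tests shows — and what it does not: the tests
validate the pipeline's logic (geometry, filters, thresholds, accounting)
under the stated generative model. Real libraries have non-uniform fragment
sizes, correlated errors, PCR chimeras and reference artefacts that the
simulator does not reproduce, so simulated sensitivity/specificity bound
the idealised behaviour of the pipeline, not the assay's field performance.

## Numerical and design choices

- Coordinates are 1-based fully closed (SAM convention) everywhere
  internally; BED output converts to 0-based half-open at the boundary.
- Display rounding: 3 significant figures for rates, 1 decimal for the
  adjusted sensitivity; raw floats are retained in every report.
- The adjusted-sensitivity estimate keeps the fractional product
  `confirm_rate × n_residual` unrounded before summation.
- Reverse-strand endpoint convention: the read's last sequenced base is the
  leftmost reference coordinate (POS). The library geometry makes junction
  reads map with a fixed orientation per insertion strand; stating the
  convention keeps both strands symmetric.
- The end-to-end test scale — 1 Mb reference, 300 loci (100 polymorphic at
  allele frequency 0.5), 4 equally pooled samples, 30,000 pairs, dispersion
  10, error rate 0.004 — is the package's deliberate desk-scale rendition of
  a study design with hundreds of thousands of pairs per sample; per-sample
  depth per carried locus (~30 pairs homozygous) is chosen so the ~95%
  sensitivity/specificity property is meaningful rather than
  coverage-limited.
- Seed handling: one integer seed drives reference, cohort and library
  generation (offset per stage); identical config + seed gives
  byte-identical outputs, verified by checksum in the tests.

## Known limitations

- The built-in mapper is exact and substitution-only (no gapped alignment);
  gapped or clipped real-data alignments should come in through SAM
  ingestion from a production aligner.
- `scan_pbs` scores are raw ungapped scores, not bit scores; thresholds
  ported from external search tools must be recalibrated.
- The singleton-merge rule moves only size-1 groups; pathological stacks of
  correlated errors (two reads at an off-by-one position) are not merged,
  matching the published behaviour but leaving tiny satellite loci below
  the support threshold.
- Index misassignment between pooled samples (barcode hopping) is not
  modelled; specificity estimates from simulation are accordingly optimistic.
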