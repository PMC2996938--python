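"""Library-construction oligonucleotides and element-derived constants.

The protocol uses four oligonucleotides: an adapter strand carrying the
sample index (CPEA1Xa), a biotinylated element-specific amplification primer
(ALUBP2, whose 3' 20 nt anneal inside the target element), an adapter-specific
PCR primer (PEP2), and a custom element-internal sequencing primer (ALUSPv2)
that generates the junction read.  Contamination screening considers CPEA1Xa,
ALUBP2 and PEP2 (and reverse complements) but must exclude the element-specific
3' 20 nt of ALUBP2 -- genuine junction reads legitimately contain that sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# Constant (index-independent) part of the indexed adapter strand.  The full
# oligo ends in the 5-nt sample index plus a ligated 'T'; those six bases are
# sample specific and excluded from screening.
CPEA1XA_CONST = "CTCGGCATTCCTGCTGAACCGCTCTTCCGATCT"

# Biotinylated amplification primer: adapter tail + 20 nt of element-specific
# sequence at the 3' end (the amplification primer-binding site, PBS).
ALUBP2 = "ACACTCTTTCCCTACACGACGCTCTTCCGATCTGCCCAGGCCGGACTGCGGAC"
ALUBP2_ELEMENT_LEN = 20
#: 3' 20 nt of ALUBP2 -- the element-specific amplification PBS sequence.
AMPLIFICATION_PBS = ALUBP2[-ALUBP2_ELEMENT_LEN:]

# Adapter-specific PCR primer.
PEP2 = "CAAGCAGAAGACGGCATACGAGATCGGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT"

#: Element-internal sequencing primer (generates the junction read).  Its
#: genomic matches are the sequencing primer-binding sites.
SEQUENCING_PRIMER = "CCCAAAGTGCTGGGATTACAGGCGTGA"

#: Expected element sequence in the first bases of every junction read
#: (as printed on the element's sense strand read by the sequencing primer).
#: Fifteen bases are specified although the junction segment is 16 nt long;
#: see docs/methods.md for how this is handled.
ME_MOTIF = "GCCACCGCGCCCGGC"

#: 16-nt junction segment planted by the simulator immediately inside the
#: element 5' end (the motif plus one element base).
JUNCTION_16 = ME_MOTIF + "T"


@dataclass(frozen=True)
class OligoSet:
    """The oligo sequences screened for read contamination.

    ``screened()`` yields every (name, sequence) pair that reads are aligned
    against: the three library oligos and their reverse complements, with the
    element-specific 3' segment of the amplification primer removed.  The
    sequencing primer is carried for reference but is *not* screened -- it is
    element sequence and would flag every genuine junction read.
    """

    cpea1xa: str = CPEA1XA_CONST
    alubp2: str = ALUBP2
    alubp2_element_len: int = ALUBP2_ELEMENT_LEN
    pep2: str = PEP2
    sequencing_primer: str = SEQUENCING_PRIMER
    extra: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def screened(self) -> list[tuple[str, str]]:
        alubp2_screen = self.alubp2[: -self.alubp2_element_len]
        base = [
            ("CPEA1Xa", self.cpea1xa),
            ("ALUBP2", alubp2_screen),
            ("PEP2", self.pep2),
        ]
        base.extend(self.extra)
        out = []
        for name, seq in base:
            out.append((name, seq))
            out.append((name + "_rc", revcomp(seq)))
        return out
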