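"""Shared ribosome geometry and genetic-code constants.

Every offset the simulator and the analysis share lives here, so a
mis-specified P-site offset shows up as a testable disagreement rather
than a silent bias.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

#: Displacement, in nucleotides, from a footprint's 5' end to the first
#: nucleotide of the P-site codon (the 5' nucleotide itself is position 0).
P_SITE_OFFSET = 12

#: Footprint length retained by the strict read filter (yeast RPFs).
READ_LENGTH = 28

#: Codon-level displacement of each ribosomal site from the P-site codon.
SITE_SHIFT = {"E": -1, "P": 0, "A": +1}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))  # 61 codons, DNA alphabet
CODON_TO_AA = dict(_STANDARD.forward_table)

#: Synonymous families: amino acid -> tuple of DNA codons.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def to_rna(codon: str) -> str:
    """Render a DNA codon in RNA alphabet (AUG-style), for reporting."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize a codon given in either alphabet to DNA."""
    return codon.upper().replace("U", "T")
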