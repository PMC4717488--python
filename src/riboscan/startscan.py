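"""Upstream non-AUG initiation scanning.

Enumerates near-cognate start-codon candidates in the 5' leader of each
ORF and calls supported events from P-site evidence in the N-terminal
extension region. A candidate must be in frame with the annotated AUG,
lie within a bounded upstream distance, and have no in-frame stop codon
between itself and the AUG; it is reported when enough P-sites cover
the extension (reads 5' of the AUG cannot derive from AUG-initiated
ribosomes, so the count is specific to upstream initiation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .geometry import STOP_CODONS, revcomp, to_dna, to_rna
from .refio import GenomeRecord, OrfModel
from .frames import PSiteTrack

#: Near-cognate codons tabulated in the start-count comparison (RNA alphabet).
DEFAULT_CODON_SET = ("UUG", "ACG", "GUG")

#: Upstream search limit, nucleotides from the annotated AUG (inclusive).
DEFAULT_MAX_UPSTREAM_NT = 100

#: Minimum P-site support in the extension region for a reported call.
DEFAULT_MIN_READS = 128


@dataclass
class CandidateStart:
    """An upstream near-cognate start candidate.

    ``offset_codons`` counts codon units relative to the annotated AUG
    (AUG = +1, nearest upstream in-frame codon = -1), matching the
    field convention for N-terminal extensions (e.g. a UUG at -26).
    """

    orf_id: str
    codon: str  # RNA alphabet, e.g. "UUG"
    offset_codons: int  # negative
    offset_nt: int  # = 3 * offset_codons
    supporting_reads: int = 0
    reported: bool = False


def upstream_sequence(
    orf: OrfModel, genome: dict[str, GenomeRecord], length_nt: int
) -> str:
    """The 5' leader in mRNA orientation, truncated at the contig edge.

    Returned string ends at the nucleotide immediately 5' of the AUG and
    is trimmed at the 5' end to whole codons of the AUG-anchored frame.
    """
    chrom = genome[orf.chrom_id]
    if orf.strand == "+":
        lo = max(0, orf.cds_start - 1 - length_nt)
        seq = chrom.sequence[lo : orf.cds_start - 1]
    else:
        hi = min(len(chrom), orf.cds_end + length_nt)
        seq = revcomp(chrom.sequence[orf.cds_end : hi])
    trim = len(seq) % 3
    return seq[trim:]


def enumerate_candidates(
    orfs: Sequence[OrfModel],
    genome: dict[str, GenomeRecord],
    codon_set: Iterable[str] = DEFAULT_CODON_SET,
    max_upstream_nt: int = DEFAULT_MAX_UPSTREAM_NT,
) -> list[CandidateStart]:
    """All in-frame near-cognate candidates within ``max_upstream_nt``.

    The distance limit applies inclusively to the candidate codon's
    first nucleotide (|offset_nt| <= max_upstream_nt); enumeration for
    an ORF stops at the first in-frame stop codon walking outward from
    the AUG, which enforces the no-intervening-stop rule.
    """
    wanted = {to_dna(c) for c in codon_set}
    k_max = max_upstream_nt // 3
    out: list[CandidateStart] = []
    for orf in orfs:
        leader = upstream_sequence(orf, genome, 3 * k_max)
        n_codons = len(leader) // 3
        for k in range(1, n_codons + 1):
            codon = leader[len(leader) - 3 * k : len(leader) - 3 * k + 3]
            if codon in STOP_CODONS:
                break
            if codon in wanted:
                out.append(
                    CandidateStart(
                        orf_id=orf.orf_id,
                        codon=to_rna(codon),
                        offset_codons=-k,
                        offset_nt=-3 * k,
                    )
                )
    return out


def score_candidates(
    candidates: Sequence[CandidateStart],
    track: PSiteTrack,
    orfs: Sequence[OrfModel],
    min_reads: int = DEFAULT_MIN_READS,
) -> list[CandidateStart]:
    """Attach extension-region P-site support and set reported flags.

    Support is the P-site count on the ORF's strand between the
    candidate codon's first nucleotide and the nucleotide before the
    AUG. Candidates with support >= ``min_reads`` are reported.
    """
    by_id = {o.orf_id: o for o in orfs}
    scored = []
    for cand in candidates:
        orf = by_id[cand.orf_id]
        k = -cand.offset_codons
        if orf.strand == "+":
            lo, hi = orf.cds_start - 3 * k, orf.cds_start - 1
        else:
            lo, hi = orf.cds_end + 1, orf.cds_end + 3 * k
        counter = track.positions(orf.chrom_id, orf.strand)
        support = sum(counter.get(p, 0) for p in range(lo, hi + 1))
        scored.append(
            CandidateStart(
                orf_id=cand.orf_id,
                codon=cand.codon,
                offset_codons=cand.offset_codons,
                offset_nt=cand.offset_nt,
                supporting_reads=support,
                reported=support >= min_reads,
            )
        )
    return scored


def compare_start_counts(
    calls_a: Sequence[CandidateStart], calls_b: Sequence[CandidateStart]
) -> pd.DataFrame:
    """Reported-candidate counts per codon in two samples, with ratios.

    The ratio is sample B over sample A (NaN when A reports none of
    that codon); a row per codon appearing in either call set.
    """
    codons = sorted(
        {c.codon for c in calls_a} | {c.codon for c in calls_b}
    )
    rows = []
    for codon in codons:
        n_a = sum(1 for c in calls_a if c.codon == codon and c.reported)
        n_b = sum(1 for c in calls_b if c.codon == codon and c.reported)
        rows.append(
            {
                "codon": codon,
                "reported_a": n_a,
                "reported_b": n_b,
                "ratio_b_over_a": (n_b / n_a) if n_a else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def candidates_to_frame(candidates: Sequence[CandidateStart]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": c.orf_id,
                "codon": c.codon,
                "offset_codons": c.offset_codons,
                "offset_nt": c.offset_nt,
                "supporting_reads": c.supporting_reads,
                "reported": c.reported,
            }
            for c in candidates
        ]
    )
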