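#!/usr/bin/env python
"""Codon translation-efficiency indices and arginine-codon gene ranking.

Computes CAI weights (reference set = the simulated ORF catalog
weighted by observed footprint density), tAI from the bundled yeast
tRNA gene-copy table with classical wobble penalties, and nTE using
footprint counts as a transcript-abundance proxy; then ranks genes by
their use of t6A-dependent (AGA/AGG) vs -independent (CGN) arginine
codons.

Writes results/indices/{codon_index.tsv,arg_usage.tsv}.
"""

import pathlib
from collections import Counter

import riboscan as rs

SIM = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "sim"
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "indices"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    genome = rs.load_genome(SIM / "genome.fa")
    orfs = rs.load_annotation(SIM / "orfs.gff3", genome)

    reads = rs.load_alignments(SIM / "wt.sam", fmt="sam")
    kept, _ = rs.filter_reads(reads)
    track = rs.assign_psites(kept, genome)
    # footprint counts per ORF double as the transcript-abundance proxy
    abundance = {
        o.orf_id: float(
            sum(n for _, n in rs.frames.orf_frame_counts(track, o))
        )
        for o in orfs
    }

    ref_counts = Counter()
    for orf in orfs:
        for i in range(orf.n_codons):
            ref_counts[orf.codon(i)] += 1

    trna = rs.load_trna_table()
    table = rs.codon_index_table(
        trna, reference_counts=ref_counts, abundance=abundance, orfs=orfs
    )
    table.to_csv(OUT / "codon_index.tsv", sep="\t", index=False)

    ann = table[table.codon.str.startswith("A")]
    rest = table[~table.codon.str.startswith("A")]
    print(
        f"mean w_tai: ANN codons {ann.w_tai.mean():.3f} vs others "
        f"{rest.w_tai.mean():.3f}"
    )
    print(
        f"mean nTE:  ANN codons {ann.nte.mean():.3f} vs others "
        f"{rest.nte.mean():.3f}"
    )

    usage = rs.rank_arg_usage(orfs)
    usage.to_csv(OUT / "arg_usage.tsv", sep="\t", index=False)
    n_excl = int(usage.exclusive_t6a.sum())
    print(
        f"{n_excl}/{len(usage)} genes use exclusively t6A-dependent Arg codons"
    )
    print(usage.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
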