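#!/usr/bin/env python
"""Codon occupancy and ribosome residence time at the E/P/A sites.

Computes CO and RRT per codon per site for both samples, their log2
fold-changes (mutant over wild type), and annotates each codon with its
decoding category (Watson-Crick vs wobble class) and cognate-tRNA
abundance class.

Writes results/dwell/occupancy.tsv and prints the codons with the
strongest A-site changes plus per-category mean fold-changes.
"""

import pathlib

import pandas as pd

import riboscan as rs
from riboscan.codonmetrics import classify_decoding

SIM = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "sim"
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "dwell"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    genome = rs.load_genome(SIM / "genome.fa")
    orfs = rs.load_annotation(SIM / "orfs.gff3", genome)

    tables = {}
    for name in ("wt", "mut"):
        reads = rs.load_alignments(SIM / f"{name}.sam", fmt="sam")
        kept, _ = rs.filter_reads(reads)
        track = rs.assign_psites(kept, genome)
        tables[name] = rs.site_codon_table(track, orfs, name)

    trna = rs.load_trna_table()
    cats = pd.DataFrame(
        [
            {
                "codon": c,
                **dict(
                    zip(
                        ("decoding_category", "abundance_class"),
                        classify_decoding(c, trna),
                    )
                ),
            }
            for c in rs.SENSE_CODONS
        ]
    )
    cmp = rs.compare_samples(tables["wt"], tables["mut"], cats)
    cmp.to_csv(OUT / "occupancy.tsv", sep="\t", index=False)

    a = cmp[cmp.site == "A"].dropna(subset=["l2fc_co"]).set_index("codon")
    up = a["l2fc_co"].nlargest(5)
    down = a["l2fc_co"].nsmallest(5)
    print("A-site CO log2FC, strongest increases:")
    print(up.round(2).to_string())
    print("A-site CO log2FC, strongest decreases:")
    print(down.round(2).to_string())
    print("\nmean A-site l2fc by decoding category:")
    print(
        a.groupby("decoding_category")[["l2fc_co", "l2fc_rrt"]]
        .mean()
        .round(3)
        .to_string()
    )


if __name__ == "__main__":
    main()
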