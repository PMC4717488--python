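"""Shared fixtures: hand-built toy references and seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

import riboscan as rs
from riboscan.geometry import revcomp


@pytest.fixture(scope="session")
def toy_genome_files(tmp_path_factory):
    """A tiny hand-written genome + annotation on disk.

    chrT layout (1-based):
      ORF plus 'ORFP' : CDS 101..130 (ATG AAA CCC GGG TTT AAA CAG GAT TGC TAA)
      ORF minus 'ORFM': CDS 201..230, minus strand (same codons, revcomp'd)
      two-exon plus 'ORFX': CDS 301..315 + 321..335
    """
    tmp = tmp_path_factory.mktemp("toy")
    cds = "ATGAAACCCGGGTTTAAACAGGATTGCTAA"
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(0, 4, 400)]))
    seq[100:130] = cds
    seq[200:230] = revcomp(cds)
    exon1 = "ATGCCCAAAGGGTTT"
    exon2 = "ACGTACGTACGTTAA"
    seq[300:315] = exon1
    seq[320:335] = exon2
    fasta = tmp / "toy.fa"
    fasta.write_text(">chrT\n" + "".join(seq) + "\n")
    gff = tmp / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chrT\ttest\tgene\t101\t130\t.\t+\t.\tID=ORFP\n"
        "chrT\ttest\tCDS\t101\t130\t.\t+\t0\tParent=ORFP\n"
        "chrT\ttest\tgene\t201\t230\t.\t-\t.\tID=ORFM\n"
        "chrT\ttest\tCDS\t201\t230\t.\t-\t0\tParent=ORFM\n"
        "chrT\ttest\tgene\t301\t335\t.\t+\t.\tID=ORFX\n"
        "chrT\ttest\tCDS\t301\t315\t.\t+\t0\tParent=ORFX\n"
        "chrT\ttest\tCDS\t321\t335\t.\t+\t0\tParent=ORFX\n"
    )
    return fasta, gff, cds, exon1 + exon2


@pytest.fixture(scope="session")
def toy_refs(toy_genome_files):
    fasta, gff, cds, spliced = toy_genome_files
    genome = rs.load_genome(fasta)
    orfs = rs.load_annotation(gff, genome)
    return genome, {o.orf_id: o for o in orfs}, cds, spliced


@pytest.fixture(scope="session")
def frameshift_sim():
    """One seeded simulation with a full-penetrance +1 frameshift.

    ORF0002 carries the shift at codon 100 (transition after local
    nucleotide 300); ORF0001 and ORF0003 are clean controls.
    """
    spec = rs.SimulationSpec(
        orf_specs=[rs.OrfSpec(600), rs.OrfSpec(900), rs.OrfSpec(900, strand="-")],
        events=[
            rs.EventSpec("frameshift", "ORF0002", position=100, shift=+1, penetrance=1.0)
        ],
        depth=20,
        seed=11,
    )
    genome, orfs = rs.make_genome(spec)
    reads, truth = rs.simulate_footprints(genome, orfs, spec)
    kept, _ = rs.filter_reads(reads)
    track = rs.assign_psites(kept, genome)
    return genome, orfs, reads, truth, track


@pytest.fixture(scope="session")
def upstream_sim():
    """Simulation with a strong upstream UUG initiation event at -26."""
    spec = rs.SimulationSpec(
        orf_specs=[rs.OrfSpec(600), rs.OrfSpec(600)],
        events=[
            rs.EventSpec(
                "upstream_init", "ORF0001", position=26, penetrance=0.5, codon="UUG"
            )
        ],
        depth=20,
        seed=13,
    )
    genome, orfs = rs.make_genome(spec)
    reads, truth = rs.simulate_footprints(genome, orfs, spec)
    kept, _ = rs.filter_reads(reads)
    track = rs.assign_psites(kept, genome)
    return genome, orfs, truth, track
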