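#!/usr/bin/env python
"""Generate the paired synthetic profiling samples used by drivers 02-05.

One shared genome of 50 ORFs; two samples over it:

* ``wt``  — baseline: 18% off-frame noise, two programmed +1 frameshift
  ORFs (full penetrance, dual-frame coding paths, detected in both
  samples like the natural +1 site), twelve upstream near-cognate
  initiation loci at modest penetrance.
* ``mut`` — a t6A-deficient-like sample: slightly higher off-frame
  noise, six additional partial-penetrance frameshift ORFs, doubled
  upstream-initiation penetrance at every locus, and shifted dwell
  weights (slower AGG/CGG/AAU/AUA/ACG, faster AUC/ACC/AAG) mirroring
  the rare-tRNA / G34:U3-slower, abundant / I34:C3-faster pattern.

Writes scratch/sim/{genome.fa,orfs.gff3,wt.sam,mut.sam,*.truth.tsv}.
"""

import pathlib

import numpy as np

import riboscan as rs

OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "sim"
SEED = 20160925

MUT_DWELL = {
    "AGG": 1.6, "CGG": 1.5, "AAT": 1.4, "ATA": 1.5, "ACG": 1.4,
    "ATC": 0.7, "ACC": 0.75, "AAG": 0.8,
}


def build_events(rng):
    """(events_for_genome, events_wt, events_mut)"""
    shared_fs = [
        rs.EventSpec("frameshift", "ORF0001", 90, shift=+1, penetrance=1.0),
        rs.EventSpec("frameshift", "ORF0002", 120, shift=+1, penetrance=1.0),
    ]
    mut_only_fs = [
        rs.EventSpec(
            "frameshift",
            f"ORF{i:04d}",
            position=int(rng.integers(40, 80)),
            shift=int(rng.choice([1, -1])),
            penetrance=float(rng.uniform(0.3, 0.9)),
        )
        for i in range(3, 9)
    ]
    upstream_wt, upstream_mut = [], []
    for i in range(9, 21):
        k = int(rng.integers(8, 30))
        codon = str(rng.choice(["TTG", "ACG", "GTG"]))
        p = float(rng.uniform(0.05, 0.3))
        args = dict(kind="upstream_init", orf_id=f"ORF{i:04d}", position=k, codon=codon)
        upstream_wt.append(rs.EventSpec(penetrance=p, **args))
        upstream_mut.append(rs.EventSpec(penetrance=min(1.0, 2 * p), **args))
    genome_events = shared_fs + mut_only_fs + upstream_mut
    return genome_events, shared_fs + upstream_wt, genome_events


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    lengths = [int(rng.choice([300, 600, 900, 1200, 1800]))
               for _ in range(50)]
    orf_specs = [
        rs.OrfSpec(n, strand="-" if rng.random() < 0.2 else "+") for n in lengths
    ]
    genome_events, wt_events, mut_events = build_events(rng)

    base = dict(orf_specs=orf_specs, depth=20, seed=SEED)
    spec_genome = rs.SimulationSpec(events=genome_events, **base)
    genome, orfs = rs.make_genome(spec_genome)

    with open(OUT / "genome.fa", "w") as fh:
        for rec in genome.values():
            fh.write(f">{rec.chrom_id}\n{rec.sequence}\n")
    rs.write_annotation(orfs, OUT / "orfs.gff3")

    for name, events, dwell, noise, seed in (
        ("wt", wt_events, {}, 0.18, SEED + 1),
        ("mut", mut_events, MUT_DWELL, 0.22, SEED + 2),
    ):
        spec = rs.SimulationSpec(
            orf_specs=orf_specs,
            events=events,
            dwell_weights=dwell,
            offframe_rate=noise,
            depth=20,
            seed=seed,
        )
        reads, truth = rs.simulate_footprints(genome, orfs, spec)
        rs.write_alignments(reads, genome, OUT / f"{name}.sam", fmt="sam")
        rs.write_truth(truth, OUT / f"{name}.truth.tsv")
        n_off = (truth.true_frame != 0).sum()
        print(
            f"{name}: {len(reads)} reads over {len(orfs)} ORFs; "
            f"{n_off / len(truth):.1%} off-frame at the P-site; "
            f"{truth.event.str.startswith('upstream_init').sum()} extension reads"
        )


if __name__ == "__main__":
    main()
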