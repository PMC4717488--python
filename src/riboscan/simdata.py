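"""Synthetic ribosome-profiling data with known ground truth.

Generates a compact genome of well-separated ORFs, then places
ribosome footprints codon by codon with per-codon dwell weights keyed
on the A-site codon (the decoding site, where elongation speed acts).
Two event classes reproduce the fidelity signals the analyses look
for: programmed +/-1 frameshifts with a stated penetrance (the
TRM140-style dual-frame coding path) and upstream near-cognate
initiation producing N-terminally extended footprint coverage (the
ALA1/GRS1-style extension). Every emitted read is recorded in a truth
table, so recovery can be scored exactly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .geometry import P_SITE_OFFSET, SENSE_CODONS, STOP_CODONS, revcomp, to_dna
from .refio import AlignedRead, GenomeRecord, OrfModel

#: Codons that must not occur by accident in a sanitized upstream window:
#: the default near-cognate start set plus AUG and CUG.
_NEAR_COGNATES = frozenset({"TTG", "ACG", "GTG", "CTG", "ATG"})

_CHROM = "chrSim"


@dataclass
class OrfSpec:
    """Blueprint for one synthetic ORF (length includes start and stop)."""

    length_nt: int
    codon_weights: dict[str, float] | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length_nt % 3 or self.length_nt < 9:
            raise ValueError("ORF length must be a multiple of 3 and >= 9")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class EventSpec:
    """A programmed fidelity event.

    kind="frameshift": ``position`` is the 0-based codon index at which
    the stated fraction of ribosomes shifts by ``shift`` (+1 or -1).
    kind="upstream_init": ``position`` is the codon-unit distance of the
    near-cognate ``codon`` upstream of the annotated AUG (e.g. 26 for
    a start at codon offset -26); the stated fraction of initiating
    ribosomes starts there, in frame with the main AUG.
    """

    kind: str
    orf_id: str
    position: int
    penetrance: float
    shift: int = 0
    codon: str = "TTG"

    def __post_init__(self) -> None:
        if self.kind not in ("frameshift", "upstream_init"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        if self.kind == "frameshift":
            if self.shift not in (+1, -1):
                raise ValueError("frameshift shift must be +1 or -1")
            if self.position < 1:
                raise ValueError("frameshift position must be strictly inside the ORF")
        else:
            if self.position < 1 or self.position > 33:
                raise ValueError("upstream_init offset must be 1..33 codons")
            self.codon = to_dna(self.codon)


@dataclass
class SimulationSpec:
    """Full description of one synthetic profiling sample."""

    orf_specs: Sequence[OrfSpec]
    dwell_weights: dict[str, float] = field(default_factory=dict)
    events: Sequence[EventSpec] = ()
    depth: float = 20.0
    read_length_distribution: dict[int, float] = field(
        default_factory=lambda: {28: 1.0}
    )
    mismatch_rate: float = 0.0
    multimap_rate: float = 0.0
    offframe_rate: float = 0.0
    intergenic_nt: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.dwell_weights = {to_dna(c): w for c, w in self.dwell_weights.items()}
        if any(w <= 0 for w in self.dwell_weights.values()):
            raise ValueError("dwell weights must be positive")
        for p in (self.mismatch_rate, self.multimap_rate, self.offframe_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        total = sum(self.read_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("read length distribution must sum to 1")


def _sample_codons(
    n: int,
    rng: np.random.Generator,
    weights: dict[str, float] | None,
    forbid_shifted_stops: int | None = None,
    start_checking_at: int = 0,
) -> list[str]:
    """Draw ``n`` sense codons; optionally keep a shifted frame stop-free.

    When ``forbid_shifted_stops`` is +1 or -1, codons from index
    ``start_checking_at`` onward are re-drawn whenever they complete a
    stop triplet in the shifted reading frame (a dual-frame coding path).
    """
    codons = list(SENSE_CODONS)
    if weights:
        p = np.array([weights.get(c, 0.0) for c in codons], dtype=float)
        if p.sum() <= 0:
            raise ValueError("codon composition weights sum to zero")
        p /= p.sum()
    else:
        p = None
    out: list[str] = []
    for j in range(n):
        for _attempt in range(200):
            c = codons[rng.choice(len(codons), p=p)]
            if forbid_shifted_stops is None or j < start_checking_at:
                break
            seq = "".join(out) + c
            # check shifted-frame triplets completed by this codon
            shift = forbid_shifted_stops
            lo = max(3 * start_checking_at + shift, shift if shift > 0 else 2)
            bad = False
            for t in range(lo, len(seq) - 2, 3):
                if (t - shift) % 3 == 0 and seq[t : t + 3] in STOP_CODONS:
                    bad = True
                    break
            if not bad:
                break
        else:
            raise ValueError(
                "could not sample a shifted-frame stop-free codon after "
                "bounded retries; composition weights too restrictive"
            )
        out.append(c)
    return out


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _sanitized_upstream(
    k: int, codon: str, rng: np.random.Generator, window_codons: int = 34
) -> str:
    """Upstream window (mRNA orientation) with one planted near-cognate.

    The planted codon sits at codon offset -k; codons between it and
    the AUG are sense codons that are neither stops nor near-cognates;
    an in-frame stop immediately 5' of the plant terminates candidate
    enumeration so the planted codon is the only scoreable candidate.
    """
    neutral = [c for c in SENSE_CODONS if c not in _NEAR_COGNATES]
    picks = lambda m: [neutral[i] for i in rng.integers(0, len(neutral), m)]
    upstream = picks(window_codons)  # offsets -window_codons .. -1
    upstream[window_codons - k] = codon
    if k < window_codons:
        upstream[window_codons - k - 1] = "TAA"
    return "".join(upstream)


def make_genome(
    spec: SimulationSpec,
) -> tuple[dict[str, GenomeRecord], list[OrfModel]]:
    """Build a synthetic chromosome and its ORF catalog from ``spec``.

    ORFs are separated by at least ``spec.intergenic_nt`` (>= 200 nt by
    default) of random intergenic sequence, start with ATG, end with a
    stop, and contain no internal frame-0 stop. ORFs carrying a
    frameshift event are additionally stop-free in the shifted frame
    downstream of the event codon. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([spec.seed, 1])
    events_by_orf: dict[str, list[EventSpec]] = {}
    orf_ids = [f"ORF{i + 1:04d}" for i in range(len(spec.orf_specs))]
    for ev in spec.events:
        if ev.orf_id not in orf_ids:
            raise ValueError(f"event references unknown ORF {ev.orf_id!r}")
        events_by_orf.setdefault(ev.orf_id, []).append(ev)

    pieces: list[str] = []
    orfs: list[OrfModel] = []
    cursor = 0
    spacer0 = max(spec.intergenic_nt, 150)
    for orf_id, ospec in zip(orf_ids, spec.orf_specs):
        evs = events_by_orf.get(orf_id, [])
        fs = [e for e in evs if e.kind == "frameshift"]
        ups = [e for e in evs if e.kind == "upstream_init"]
        n_body = ospec.length_nt // 3 - 2  # codons between ATG and stop
        for e in fs:
            if not 1 <= e.position <= n_body:
                raise ValueError(
                    f"{orf_id}: frameshift position {e.position} not strictly "
                    "inside the ORF"
                )
        shift = fs[0].shift if fs else None
        check_from = fs[0].position - 1 if fs else 0
        body = _sample_codons(
            n_body,
            rng,
            ospec.codon_weights,
            forbid_shifted_stops=shift,
            start_checking_at=check_from,
        )
        cds = "ATG" + "".join(body) + "TAA"

        spacer = _random_nt(spacer0, rng)
        window = (
            _sanitized_upstream(ups[0].position, ups[0].codon, rng) if ups else ""
        )
        if ospec.strand == "+":
            # upstream window replaces the tail of the spacer, 5' of the ATG
            if window:
                spacer = spacer[: -len(window)] + window
            pieces.append(spacer)
            cursor += len(spacer)
            start = cursor + 1
            pieces.append(cds)
            cursor += len(cds)
            end = cursor
        else:
            # on the genome the mRNA-upstream window sits 3' of the CDS
            pieces.append(spacer)
            cursor += len(spacer)
            start = cursor + 1
            pieces.append(revcomp(cds))
            cursor += len(cds)
            end = cursor
            if window:
                pieces.append(revcomp(window))
                cursor += len(window)
        orfs.append(
            OrfModel(
                orf_id=orf_id,
                chrom_id=_CHROM,
                strand=ospec.strand,
                exons=((start, end),),
                spliced_cds=cds,
            )
        )
    pieces.append(_random_nt(spacer0, rng))
    genome = {_CHROM: GenomeRecord(_CHROM, "".join(pieces))}
    return genome, orfs


def _first_shifted_stop(cds: str, event: EventSpec) -> int | None:
    """Codon index of the first shifted-frame stop at/after the event, or None."""
    shift = event.shift
    for j in range(event.position, len(cds) // 3):
        t = 3 * j + shift
        if t < 0 or t + 3 > len(cds):
            continue
        if cds[t : t + 3] in STOP_CODONS:
            return j
    return None


def simulate_footprints(
    genome: dict[str, GenomeRecord],
    orfs: Sequence[OrfModel],
    spec: SimulationSpec,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Place ribosomes and emit footprint reads plus a truth table.

    P-site codon positions are drawn with probability proportional to
    the dwell weight of the codon in the A-site (one codon downstream).
    Each placement emits one read whose 5' end lies ``P_SITE_OFFSET``
    nucleotides 5' of the P-site (strand-mirrored). Frameshift events
    divert the stated fraction of ribosomes at/after the event codon
    into the shifted frame; upstream-initiation events add extension
    coverage between the near-cognate and the AUG at the stated
    fraction of the main-ORF loading rate.
    """
    rng = np.random.default_rng([spec.seed, 2])
    events_by_orf: dict[str, list[EventSpec]] = {}
    for ev in spec.events:
        events_by_orf.setdefault(ev.orf_id, []).append(ev)

    lengths = np.array(sorted(spec.read_length_distribution), dtype=int)
    length_p = np.array(
        [spec.read_length_distribution[l] for l in lengths], dtype=float
    )

    reads: list[AlignedRead] = []
    truth_rows: list[tuple] = []
    serial = 0

    def emit(orf: OrfModel, local_nt: int, frame: int, event_label: str) -> None:
        nonlocal serial
        if 0 <= local_nt < len(orf.spliced_cds):
            psite_g = orf.genomic_position(local_nt)
        elif orf.strand == "+":
            psite_g = orf.cds_start + local_nt
        else:
            psite_g = orf.cds_end - local_nt
        if orf.strand == "+":
            five_prime = psite_g - P_SITE_OFFSET
        else:
            five_prime = psite_g + P_SITE_OFFSET
        length = int(lengths[rng.choice(len(lengths), p=length_p)]) if len(lengths) > 1 else int(lengths[0])
        mism = int(rng.random() < spec.mismatch_rate)
        unique = bool(rng.random() >= spec.multimap_rate)
        read_id = f"r{serial:08d}"
        serial += 1
        reads.append(
            AlignedRead(
                chrom_id=orf.chrom_id,
                strand=orf.strand,
                five_prime_pos=five_prime,
                length=length,
                mismatches=mism,
                is_unique=unique,
                read_id=read_id,
            )
        )
        truth_rows.append(
            (read_id, orf.orf_id, frame, event_label, local_nt, psite_g)
        )

    for orf in orfs:
        evs = events_by_orf.get(orf.orf_id, [])
        fs = [e for e in evs if e.kind == "frameshift"]
        ups = [e for e in evs if e.kind == "upstream_init"]
        n = orf.n_codons
        # P-site positions with a sense codon in the A-site
        positions = np.arange(0, n - 2)
        w = np.array(
            [spec.dwell_weights.get(orf.codon(p + 1), 1.0) for p in positions]
        )
        n_reads = rng.poisson(spec.depth * len(positions))
        drawn = rng.choice(len(positions), size=n_reads, p=w / w.sum())
        shifted_stop = _first_shifted_stop(orf.spliced_cds, fs[0]) if fs else None
        if fs and shifted_stop is not None and shifted_stop <= fs[0].position + 1:
            warnings.warn(
                f"{orf.orf_id}: shifted path hits a stop immediately after the "
                "frameshift; shifted ribosome paths truncated"
            )
        for idx in drawn:
            p = int(positions[idx])
            frame = 0
            label = ""
            local_nt = 3 * p
            if fs and p >= fs[0].position and rng.random() < fs[0].penetrance:
                if shifted_stop is not None and p >= shifted_stop:
                    continue  # that ribosome terminated on the shifted path
                local_nt = 3 * p + fs[0].shift
                frame = fs[0].shift % 3
                label = f"frameshift@{fs[0].position}"
            elif spec.offframe_rate and rng.random() < spec.offframe_rate:
                d = int(rng.choice((-1, 1)))
                if 0 <= local_nt + d < len(orf.spliced_cds):
                    local_nt += d
                    frame = local_nt % 3
                    label = "noise"
            emit(orf, local_nt, frame, label)
        for e in ups:
            k = e.position
            n_ext = rng.poisson(spec.depth * e.penetrance * k)
            ext_pos = rng.integers(0, k, size=n_ext)
            for j in ext_pos:
                local_nt = -3 * (k - int(j))
                emit(orf, local_nt, 0, f"upstream_init@-{k}")

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "orf_id", "true_frame", "event", "psite_local_nt", "psite_genomic"],
    )
    return reads, truth


def write_alignments(
    reads: Sequence[AlignedRead],
    genome: dict[str, GenomeRecord],
    path: str | os.PathLike,
    fmt: str = "sam",
) -> None:
    """Write reads as SAM/BAM (or the 6+-column BED-like TSV dialect)."""
    path = str(path)
    if fmt in ("sam", "bam"):
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": rec.chrom_id, "LN": len(rec)} for rec in genome.values()
            ],
        }
        tid = {rec.chrom_id: i for i, rec in enumerate(genome.values())}
        mode = "wb" if fmt == "bam" else "w"
        with pysam.AlignmentFile(path, mode, header=header) as fh:
            for read in reads:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = read.read_id or "read"
                a.reference_id = tid[read.chrom_id]
                if read.strand == "+":
                    pos0 = read.five_prime_pos - 1
                else:
                    pos0 = read.five_prime_pos - read.length
                a.reference_start = pos0
                a.cigarstring = f"{read.length}M"
                a.flag = 16 if read.strand == "-" else 0
                seq = genome[read.chrom_id].sequence[pos0 : pos0 + read.length]
                a.query_sequence = seq if read.strand == "+" else revcomp(seq)
                a.mapping_quality = 42 if read.is_unique else 3
                a.set_tag("NM", read.mismatches)
                fh.write(a)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for read in reads:
                if read.strand == "+":
                    start0 = read.five_prime_pos - 1
                else:
                    start0 = read.five_prime_pos - read.length
                fh.write(
                    f"{read.chrom_id}\t{start0}\t{start0 + read.length}\t"
                    f"{read.strand}\t{read.mismatches}\t{int(read.is_unique)}\t"
                    f"{read.read_id}\n"
                )
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)
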