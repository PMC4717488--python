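"""Reference and alignment I/O: genomes, ORF annotations, aligned footprints.

All coordinate conversion between the 1-based closed convention of
GFF3/SAM and 0-based internal arithmetic is confined to this module.
External coordinates everywhere in the package are 1-based closed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import gffutils
import pysam
from Bio import SeqIO

from .geometry import STOP_CODONS, revcomp

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One reference sequence, upper-cased, alphabet {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class AlignedRead(NamedTuple):
    """A single aligned ribosome-protected fragment.

    ``five_prime_pos`` is the 1-based genomic coordinate of the read's
    biological 5' nucleotide: the lowest aligned coordinate on the plus
    strand, the highest on the minus strand.
    """

    chrom_id: str
    strand: str
    five_prime_pos: int
    length: int
    mismatches: int
    is_unique: bool
    read_id: str = ""


@dataclass
class OrfModel:
    """An annotated coding region with spliced sequence access.

    ``exons`` are 1-based closed genomic intervals in ascending genomic
    order; ``spliced_cds`` is the mRNA-orientation CDS (reverse-
    complemented for minus-strand ORFs).
    """

    orf_id: str
    chrom_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    spliced_cds: str
    non_canonical_start: bool = False
    truncated: bool = False

    @property
    def cds_start(self) -> int:
        return self.exons[0][0]

    @property
    def cds_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_codons(self) -> int:
        return len(self.spliced_cds) // 3

    def codon(self, index: int) -> str:
        """Codon at 0-based codon ``index`` of the spliced CDS."""
        return self.spliced_cds[3 * index : 3 * index + 3]

    def local_offset(self, pos: int) -> int | None:
        """0-based offset of genomic position ``pos`` within the spliced CDS.

        Returns None when ``pos`` falls outside the CDS (introns included).
        """
        if self.strand == "+":
            cum = 0
            for start, end in self.exons:
                if start <= pos <= end:
                    return cum + (pos - start)
                cum += end - start + 1
        else:
            cum = 0
            for start, end in reversed(self.exons):
                if start <= pos <= end:
                    return cum + (end - pos)
                cum += end - start + 1
        return None

    def genomic_position(self, offset: int) -> int:
        """Inverse of :meth:`local_offset` for in-CDS offsets."""
        if not 0 <= offset < len(self.spliced_cds):
            raise ValueError(f"offset {offset} outside CDS of {self.orf_id}")
        if self.strand == "+":
            for start, end in self.exons:
                span = end - start + 1
                if offset < span:
                    return start + offset
                offset -= span
        else:
            for start, end in reversed(self.exons):
                span = end - start + 1
                if offset < span:
                    return end - offset
                offset -= span
        raise AssertionError("unreachable")

    def has_internal_stop(self) -> bool:
        cds = self.spliced_cds
        return any(
            cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 3, 3)
        )


def load_genome(path: str | os.PathLike) -> dict[str, GenomeRecord]:
    """Read a FASTA file into an ordered ``{chrom_id: GenomeRecord}`` map.

    Sequences are upper-cased; duplicate ids and empty files are errors.
    """
    records: dict[str, GenomeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in sequence {rec.id!r}"
            )
        records[rec.id] = GenomeRecord(rec.id, seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _orf_from_cds_parts(
    orf_id: str,
    chrom_id: str,
    strand: str,
    exons: list[tuple[int, int]],
    genome: dict[str, GenomeRecord],
) -> OrfModel:
    if chrom_id not in genome:
        raise ValueError(f"{orf_id}: unknown chromosome {chrom_id!r}")
    chrom = genome[chrom_id]
    exons = sorted(exons)
    for start, end in exons:
        if start < 1 or end > len(chrom):
            raise ValueError(
                f"{orf_id}: CDS feature {start}..{end} exceeds bounds of "
                f"{chrom_id} (length {len(chrom)})"
            )
    parts = [chrom.sequence[s - 1 : e] for s, e in exons]
    cds = "".join(parts)
    if strand == "-":
        cds = revcomp(cds)
    truncated = False
    if len(cds) % 3 != 0:
        warnings.warn(
            f"{orf_id}: CDS length {len(cds)} not divisible by 3; "
            "flagging truncated"
        )
        truncated = True
    non_canonical = not cds.startswith("ATG")
    if not truncated and cds[-3:] not in STOP_CODONS:
        truncated = True
    return OrfModel(
        orf_id=orf_id,
        chrom_id=chrom_id,
        strand=strand,
        exons=tuple(exons),
        spliced_cds=cds,
        non_canonical_start=non_canonical,
        truncated=truncated,
    )


def load_annotation(
    path: str | os.PathLike, genome: dict[str, GenomeRecord]
) -> list[OrfModel]:
    """Load CDS features from a GFF3 file, grouped by parent, into OrfModels.

    Spliced CDS sequences are assembled in transcription order and
    reverse-complemented for minus-strand ORFs. ORFs whose translation
    contains an internal stop are reported with a warning (loader
    self-check) but still returned.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, dict] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ValueError(f"CDS feature at {feat.seqid}:{feat.start} lacks Parent/ID")
        key = parents[0]
        g = groups.setdefault(
            key, {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        g["exons"].append((feat.start, feat.end))
    orfs = []
    for orf_id, g in groups.items():
        orf = _orf_from_cds_parts(orf_id, g["chrom"], g["strand"], g["exons"], genome)
        if not orf.truncated and orf.has_internal_stop():
            warnings.warn(f"{orf_id}: internal stop codon in annotated frame")
        orfs.append(orf)
    return orfs


def write_annotation(orfs: Iterable[OrfModel], path: str | os.PathLike) -> None:
    """Write ORF models back to GFF3 (gene/mRNA/CDS per ORF)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                f"{orf.chrom_id}\triboscan\tgene\t{orf.cds_start}\t{orf.cds_end}"
                f"\t.\t{orf.strand}\t.\tID={orf.orf_id}\n"
            )
            for start, end in orf.exons:
                fh.write(
                    f"{orf.chrom_id}\triboscan\tCDS\t{start}\t{end}"
                    f"\t.\t{orf.strand}\t0\tParent={orf.orf_id}\n"
                )


BED_COLUMNS = ("chrom", "start0", "end0", "strand", "mismatches", "unique_flag")


def load_alignments(
    path: str | os.PathLike,
    fmt: str = "sam",
    min_mapq: int = 10,
) -> Iterator[AlignedRead]:
    """Stream aligned reads from SAM/BAM or a BED-like TSV.

    Uniqueness convention for SAM/BAM: mapping quality >= ``min_mapq``
    and not flagged secondary/supplementary. BED-like input must carry
    explicit ``mismatches`` and ``unique_flag`` columns
    (chrom, start0, end0, strand, mismatches, unique_flag[, read_id]).
    Minus-strand reads have their 5' end at the alignment's maximum
    coordinate.
    """
    if fmt in ("sam", "bam"):
        mode = "rb" if fmt == "bam" else "r"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for i, rec in enumerate(fh.fetch(until_eof=True)):
                if rec.is_unmapped:
                    continue
                if not rec.has_tag("NM"):
                    raise ValueError(
                        f"alignment record {rec.query_name or i!r} lacks an NM "
                        "mismatch tag"
                    )
                strand = "-" if rec.is_reverse else "+"
                five_prime = (
                    rec.reference_end if rec.is_reverse else rec.reference_start + 1
                )
                yield AlignedRead(
                    chrom_id=rec.reference_name,
                    strand=strand,
                    five_prime_pos=five_prime,
                    length=rec.query_length or rec.infer_query_length() or 0,
                    mismatches=int(rec.get_tag("NM")),
                    is_unique=(
                        rec.mapping_quality >= min_mapq
                        and not rec.is_secondary
                        and not rec.is_supplementary
                    ),
                    read_id=rec.query_name or f"read{i}",
                )
    elif fmt == "bed":
        with open(path) as fh:
            for i, line in enumerate(fh):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ValueError(
                        f"line {i + 1} of {path}: BED-like input needs >=6 "
                        f"columns {BED_COLUMNS}, got {len(parts)}"
                    )
                chrom, start0, end0, strand = parts[0], int(parts[1]), int(parts[2]), parts[3]
                mismatches = int(parts[4])
                unique = parts[5] in ("1", "True", "true")
                read_id = parts[6] if len(parts) > 6 else f"read{i}"
                five_prime = end0 if strand == "-" else start0 + 1
                yield AlignedRead(
                    chrom_id=chrom,
                    strand=strand,
                    five_prime_pos=five_prime,
                    length=end0 - start0,
                    mismatches=mismatches,
                    is_unique=unique,
                    read_id=read_id,
                )
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
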