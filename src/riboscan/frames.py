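"""Reading-frame fidelity: P-site assignment, windowed frame profiles,
ambiguity calls, frameshift localization, and between-sample comparison.

The operational definition of translational ambiguity used throughout:
a footprint whose inferred P-site falls in a frame other than the
annotated one. Only strict footprints contribute (28-mers, uniquely
mapped, no mismatches), mirroring conservative ribosome-profiling
practice for frame analysis.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .geometry import P_SITE_OFFSET, READ_LENGTH
from .refio import AlignedRead, GenomeRecord, OrfModel


@dataclass
class FilterReport:
    retained: int = 0
    dropped_length: int = 0
    dropped_mismatch: int = 0
    dropped_multimap: int = 0


def filter_reads(
    reads: Iterable[AlignedRead], length: int = READ_LENGTH
) -> tuple[list[AlignedRead], FilterReport]:
    """Keep reads of exactly ``length`` nt, uniquely mapped, mismatch-free.

    Each dropped read is counted once, against the first criterion it
    fails (length, then mismatches, then uniqueness).
    """
    report = FilterReport()
    kept: list[AlignedRead] = []
    for read in reads:
        if read.length != length:
            report.dropped_length += 1
        elif read.mismatches != 0:
            report.dropped_mismatch += 1
        elif not read.is_unique:
            report.dropped_multimap += 1
        else:
            kept.append(read)
            report.retained += 1
    return kept, report


class PSiteTrack:
    """Per-nucleotide counts of inferred ribosomal P-sites, stranded."""

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
        self.dropped_out_of_bounds = 0

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        self._counts[(chrom, strand)][pos] += n

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def positions(self, chrom: str, strand: str) -> Counter:
        return self._counts.get((chrom, strand), Counter())

    @property
    def total_psites(self) -> int:
        return sum(sum(c.values()) for c in self._counts.values())


def assign_psites(
    reads: Iterable[AlignedRead],
    genome: dict[str, GenomeRecord] | None = None,
    offset: int = P_SITE_OFFSET,
) -> PSiteTrack:
    """Build a P-site track: 5' end + ``offset`` nt (mirrored on minus strand).

    With a genome supplied, P-sites falling outside chromosome bounds
    are dropped and counted on ``track.dropped_out_of_bounds``.
    """
    track = PSiteTrack()
    for read in reads:
        if read.strand == "+":
            psite = read.five_prime_pos + offset
        else:
            psite = read.five_prime_pos - offset
        if genome is not None:
            if psite < 1 or psite > len(genome[read.chrom_id]):
                track.dropped_out_of_bounds += 1
                continue
        track.add(read.chrom_id, read.strand, psite)
    return track


def frame_of(chrom: str, strand: str, psite: int, orf: OrfModel) -> int | None:
    """Frame of a P-site relative to ``orf``: 0/1/2, or None if outside."""
    if chrom != orf.chrom_id or strand != orf.strand:
        return None
    local = orf.local_offset(psite)
    if local is None:
        return None
    return local % 3


def window_orf(orf_length: int) -> list[tuple[int, int]]:
    """Tile an ORF into 3-9 codon-aligned windows of ~300 nt.

    The window count is round(length/300) clamped to [3, 9]; the
    remainder of the codon division is spread over the leftmost
    windows, so window lengths differ by at most one codon. Bounds are
    ORF-local, 1-based closed nucleotide intervals.
    """
    if orf_length < 9:
        raise ValueError("ORF too short to window (< 9 nt)")
    k = int(np.floor(orf_length / 300 + 0.5))
    k = min(9, max(3, k))
    n_codons = orf_length // 3
    k = min(k, n_codons)
    base, rem = divmod(n_codons, k)
    bounds = []
    start = 1
    for i in range(k):
        codons = base + (1 if i < rem else 0)
        end = start + 3 * codons - 1
        if i == k - 1:
            end = orf_length  # absorb any sub-codon remainder
        bounds.append((start, end))
        start = end + 1
    return bounds


@dataclass
class WindowFrameProfile:
    orf_id: str
    window_index: int  # 1-based
    window_bounds: tuple[int, int]  # ORF-local 1-based closed nt
    counts: tuple[int, int, int]  # frames 0, +1, +2

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def offframe_fraction(self) -> float:
        t = self.total
        return (self.counts[1] + self.counts[2]) / t if t else 0.0


def orf_frame_counts(track: PSiteTrack, orf: OrfModel) -> list[tuple[int, int]]:
    """(local_offset, count) for every P-site inside the ORF's CDS."""
    hits = []
    counter = track.positions(orf.chrom_id, orf.strand)
    for start, end in orf.exons:
        for pos in range(start, end + 1):
            n = counter.get(pos, 0)
            if n:
                local = orf.local_offset(pos)
                hits.append((local, n))
    hits.sort()
    return hits


def frame_profile(
    track: PSiteTrack, orfs: Sequence[OrfModel]
) -> dict[str, list[WindowFrameProfile]]:
    """Per-ORF windowed frame counts; each in-CDS P-site lands in exactly
    one window (by its P-site position). ORFs shorter than 9 nt are
    skipped with a warning count left to the caller (they are simply
    absent from the result)."""
    profiles: dict[str, list[WindowFrameProfile]] = {}
    for orf in orfs:
        length = len(orf.spliced_cds)
        if length < 9:
            continue
        bounds = window_orf(length)
        counts = [[0, 0, 0] for _ in bounds]
        starts = np.array([b[0] for b in bounds])
        for local, n in orf_frame_counts(track, orf):
            w = int(np.searchsorted(starts, local + 1, side="right")) - 1
            counts[w][local % 3] += n
        profiles[orf.orf_id] = [
            WindowFrameProfile(orf.orf_id, i + 1, b, tuple(c))
            for i, (b, c) in enumerate(zip(bounds, counts))
        ]
    return profiles


@dataclass
class AmbiguityCall:
    orf_id: str
    ambiguous: bool
    offending_windows: list[int] = field(default_factory=list)
    dominant_offframe: int | None = None  # 1 (+1) or 2 (+2/-1)
    transition_nt: int | None = None


def call_ambiguities(
    profiles: dict[str, list[WindowFrameProfile]],
    min_window_reads: int = 32,
    offframe_fraction: float = 0.5,
) -> list[AmbiguityCall]:
    """Flag ORFs with at least one well-covered, majority-off-frame window.

    A window offends when it holds >= ``min_window_reads`` P-sites and
    its off-frame fraction is >= ``offframe_fraction``. The dominant
    off-frame is whichever of +1/+2 carries more reads over the
    offending windows.
    """
    calls = []
    for orf_id, windows in profiles.items():
        offending = [
            w.window_index
            for w in windows
            if w.total >= min_window_reads
            and w.offframe_fraction >= offframe_fraction
        ]
        if offending:
            f1 = sum(windows[i - 1].counts[1] for i in offending)
            f2 = sum(windows[i - 1].counts[2] for i in offending)
            calls.append(
                AmbiguityCall(orf_id, True, offending, 1 if f1 >= f2 else 2)
            )
        else:
            calls.append(AmbiguityCall(orf_id, False))
    return calls


def locate_transition(
    track: PSiteTrack, orf: OrfModel, dominant_offframe: int
) -> int | None:
    """Change-point between frame-0 and the dominant off-frame.

    Maximizes the two-segment Bernoulli likelihood of the ordered
    per-P-site frame indicators (frame 0 vs ``dominant_offframe``;
    other frames ignored). Returns the ORF-local 1-based nucleotide at
    which the off-frame segment begins, or None without off-frame reads.
    """
    obs: list[tuple[int, int, int]] = []  # (local_nt, n_total, n_offframe)
    for local, n in orf_frame_counts(track, orf):
        f = local % 3
        if f == 0:
            obs.append((local, n, 0))
        elif f == dominant_offframe:
            obs.append((local, n, n))
    if not obs or not any(k for _, _, k in obs):
        return None
    pos = np.array([o[0] for o in obs])
    n = np.array([o[1] for o in obs], dtype=float)
    k = np.array([o[2] for o in obs], dtype=float)

    def seg_ll(ktot: np.ndarray, ntot: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ntot > 0, ktot / np.maximum(ntot, 1), 0.0)
            a = np.where(ktot > 0, ktot * np.log(p), 0.0)
            b = np.where(ntot - ktot > 0, (ntot - ktot) * np.log(1 - p), 0.0)
        return a + b

    cn, ck = np.cumsum(n), np.cumsum(k)
    N, K = cn[-1], ck[-1]
    # split after position i: left = obs[:i+1], right = obs[i+1:]
    ll = seg_ll(ck[:-1], cn[:-1]) + seg_ll(K - ck[:-1], N - cn[:-1])
    best = int(np.argmax(ll))
    return int(pos[best + 1]) + 1  # first position of the right segment, 1-based


@dataclass
class FrameSummary:
    fractions_a: tuple[float, float, float]
    fractions_b: tuple[float, float, float]
    total_a: int
    total_b: int
    n_orfs: int
    statistic: float
    dof: int
    pvalue: float


def _per_orf_frames(
    track: PSiteTrack, orfs: Sequence[OrfModel]
) -> dict[str, np.ndarray]:
    out = {}
    for orf in orfs:
        c = np.zeros(3, dtype=int)
        for local, n in orf_frame_counts(track, orf):
            c[local % 3] += n
        out[orf.orf_id] = c
    return out


def global_frame_summary(
    track_a: PSiteTrack,
    track_b: PSiteTrack,
    orfs: Sequence[OrfModel],
    min_orf_reads: int = 32,
) -> FrameSummary:
    """Global frame fractions per sample and an unpaired two-sample
    t-test on per-ORF frame-0 fractions (ORFs with >= ``min_orf_reads``
    in-CDS P-sites in both samples)."""
    fa = _per_orf_frames(track_a, orfs)
    fb = _per_orf_frames(track_b, orfs)
    tot_a = sum(fa.values(), np.zeros(3, dtype=int))
    tot_b = sum(fb.values(), np.zeros(3, dtype=int))
    qual = [
        o.orf_id
        for o in orfs
        if fa[o.orf_id].sum() >= min_orf_reads and fb[o.orf_id].sum() >= min_orf_reads
    ]
    if len(qual) < 3:
        raise ValueError(
            f"only {len(qual)} ORFs pass min_orf_reads={min_orf_reads} in both "
            "samples; need >= 3"
        )
    f0a = np.array([fa[q][0] / fa[q].sum() for q in qual])
    f0b = np.array([fb[q][0] / fb[q].sum() for q in qual])
    if f0a.std() == 0 and f0b.std() == 0:
        # degenerate: no across-ORF variance; equal means are a perfect null
        stat = 0.0 if f0a.mean() == f0b.mean() else float("inf")
        res = type("R", (), {"statistic": stat, "pvalue": 1.0 if stat == 0 else 0.0})
    else:
        res = stats.ttest_ind(f0a, f0b)
    frac = lambda t: tuple((t / t.sum()).tolist()) if t.sum() else (0.0, 0.0, 0.0)
    return FrameSummary(
        fractions_a=frac(tot_a),
        fractions_b=frac(tot_b),
        total_a=int(tot_a.sum()),
        total_b=int(tot_b.sum()),
        n_orfs=len(qual),
        statistic=float(res.statistic),
        dof=2 * len(qual) - 2,
        pvalue=float(res.pvalue),
    )
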