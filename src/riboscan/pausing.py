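"""Per-codon ribosome dwell metrics at the E, P, and A sites.

Two complementary dwell proxies are computed from in-frame P-sites:

* Codon occupancy (CO): the frequency of a codon at a ribosomal site
  among all footprints, divided by that codon's background frequency
  among the CDS positions of expressed ORFs. CO = 1 under uniform
  dwell; CO > 1 marks slow decoding.
* Ribosome residence time (RRT): per-gene footprint density at
  positions presenting the codon at the site, normalized by the gene's
  mean density, averaged across well-covered genes, and rescaled to
  mean 1 over codons. Per-gene normalization removes expression-level
  confounding.

Off-frame P-sites are excluded (their site codons are undefined), and
the first and last few codons of each ORF are trimmed to keep
initiation/termination piling out of the dwell estimates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SENSE_CODONS, SITE_SHIFT
from .refio import OrfModel
from .frames import PSiteTrack, orf_frame_counts

SITES = ("E", "P", "A")

DEFAULT_TRIM_CODONS = 5
DEFAULT_MIN_GENE_READS = 100


@dataclass
class SiteCodonCounts:
    """Raw in-frame P-site counts per (site, codon), plus bookkeeping."""

    counts: dict[str, Counter]  # site -> codon -> count
    orf_psites: dict[str, int]  # in-frame, in-trim P-sites per ORF
    trim_codons: int


def _codon_positions(orf: OrfModel, trim: int) -> range:
    """P-site codon indices retained after end-trimming (stop excluded)."""
    return range(trim, orf.n_codons - 1 - trim)


def site_codon_counts(
    track: PSiteTrack,
    orfs: list[OrfModel],
    trim_codons: int = DEFAULT_TRIM_CODONS,
) -> SiteCodonCounts:
    """Tally E/P/A-site codons over all in-frame P-sites.

    A P-site at codon ``i`` contributes codon ``i`` at P, ``i+1`` at A,
    and ``i-1`` at E; a site whose codon leaves the retained span or is
    a stop codon is skipped for that site only.
    """
    sense = set(SENSE_CODONS)
    counts = {s: Counter() for s in SITES}
    orf_psites: dict[str, int] = {}
    for orf in orfs:
        span = _codon_positions(orf, trim_codons)
        if len(span) <= 0:
            continue
        total = 0
        for local, n in orf_frame_counts(track, orf):
            if local % 3:
                continue
            i = local // 3
            if i not in span:
                continue
            total += n
            for site, shift in SITE_SHIFT.items():
                j = i + shift
                if j < 0 or j >= orf.n_codons:
                    continue
                codon = orf.codon(j)
                if codon in sense:
                    counts[site][codon] += n
        orf_psites[orf.orf_id] = total
    return SiteCodonCounts(counts, orf_psites, trim_codons)


def codon_occupancy(scc: SiteCodonCounts, orfs: list[OrfModel]) -> pd.DataFrame:
    """CO per (site, codon): site-count frequency over background frequency.

    Background is the codon frequency among retained CDS positions of
    ORFs holding at least one counted P-site. Codons absent from the
    background have undefined CO (NaN, flagged).
    """
    expressed = [o for o in orfs if scc.orf_psites.get(o.orf_id, 0) > 0]
    if not expressed:
        raise ValueError("no ORF holds any in-frame P-site; cannot compute CO")
    bg = Counter()
    for orf in expressed:
        for i in range(scc.trim_codons, orf.n_codons - 1 - scc.trim_codons):
            codon = orf.codon(i)
            if codon in set(SENSE_CODONS):
                bg[codon] += 1
    bg_total = sum(bg.values())
    rows = []
    for site in SITES:
        site_total = sum(scc.counts[site].values())
        if site_total == 0:
            raise ValueError(f"all-zero counts at site {site}")
        for codon in SENSE_CODONS:
            n = scc.counts[site][codon]
            f_bg = bg[codon] / bg_total if bg_total else 0.0
            co = (n / site_total) / f_bg if f_bg > 0 else np.nan
            rows.append(
                {
                    "site": site,
                    "codon": codon,
                    "count": n,
                    "f_bg": f_bg,
                    "co": co,
                    "defined": f_bg > 0,
                }
            )
    return pd.DataFrame(rows)


def ribosome_residence_time(
    track: PSiteTrack,
    orfs: list[OrfModel],
    min_gene_reads: int = DEFAULT_MIN_GENE_READS,
    trim_codons: int = DEFAULT_TRIM_CODONS,
) -> pd.DataFrame:
    """RRT per (site, codon) from per-gene normalized densities.

    For each gene with >= ``min_gene_reads`` retained in-frame P-sites,
    the codon-level density vector is divided by the gene's mean
    density; per site and codon the normalized densities of positions
    presenting that codon are averaged within the gene, then across
    genes, then rescaled so the across-codon mean is 1 per site.
    """
    sense = set(SENSE_CODONS)
    per_codon: dict[str, dict[str, list[float]]] = {
        s: {c: [] for c in SENSE_CODONS} for s in SITES
    }
    n_genes = 0
    for orf in orfs:
        span = _codon_positions(orf, trim_codons)
        if len(span) <= 0:
            continue
        dens = np.zeros(len(span))
        for local, n in orf_frame_counts(track, orf):
            if local % 3:
                continue
            i = local // 3
            if i in span:
                dens[i - span.start] += n
        if dens.sum() < min_gene_reads:
            continue
        n_genes += 1
        mean = dens.mean()
        for site, shift in SITE_SHIFT.items():
            by_codon: dict[str, list[float]] = {}
            for idx, i in enumerate(span):
                j = i + shift
                if j < 0 or j >= orf.n_codons:
                    continue
                codon = orf.codon(j)
                if codon in sense:
                    by_codon.setdefault(codon, []).append(dens[idx] / mean)
            for codon, vals in by_codon.items():
                per_codon[site][codon].append(float(np.mean(vals)))
    if n_genes == 0:
        raise ValueError(
            f"no gene reaches min_gene_reads={min_gene_reads}; cannot compute RRT"
        )
    rows = []
    for site in SITES:
        raw = {
            c: (np.mean(v) if v else np.nan) for c, v in per_codon[site].items()
        }
        defined = [v for v in raw.values() if np.isfinite(v)]
        scale = np.mean(defined) if defined else np.nan
        for codon in SENSE_CODONS:
            rows.append(
                {
                    "site": site,
                    "codon": codon,
                    "rrt": raw[codon] / scale if np.isfinite(raw[codon]) else np.nan,
                    "n_genes": len(per_codon[site][codon]),
                }
            )
    return pd.DataFrame(rows)


def site_codon_table(
    track: PSiteTrack,
    orfs: list[OrfModel],
    sample_id: str = "sample",
    min_gene_reads: int = DEFAULT_MIN_GENE_READS,
    trim_codons: int = DEFAULT_TRIM_CODONS,
) -> pd.DataFrame:
    """Combined per-(site, codon) table: counts, background, CO, and RRT."""
    scc = site_codon_counts(track, orfs, trim_codons=trim_codons)
    co = codon_occupancy(scc, orfs)
    rrt = ribosome_residence_time(
        track, orfs, min_gene_reads=min_gene_reads, trim_codons=trim_codons
    )
    table = co.merge(rrt, on=["site", "codon"])
    table.insert(0, "sample_id", sample_id)
    return table


def compare_samples(
    table_wt: pd.DataFrame,
    table_mut: pd.DataFrame,
    categories: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-(site, codon) log2 fold-changes of CO and RRT, mutant over wild type.

    Codons undefined in either sample are flagged (NaN fold-changes).
    ``categories`` may supply per-codon decoding annotations (columns
    ``codon``, ``decoding_category``, ``abundance_class``).
    """
    merged = table_wt.merge(
        table_mut, on=["site", "codon"], suffixes=("_wt", "_mut")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["l2fc_co"] = np.where(
            (merged["co_wt"] > 0) & (merged["co_mut"] > 0),
            np.log2(merged["co_mut"] / merged["co_wt"]),
            np.nan,
        )
        merged["l2fc_rrt"] = np.where(
            (merged["rrt_wt"] > 0) & (merged["rrt_mut"] > 0),
            np.log2(merged["rrt_mut"] / merged["rrt_wt"]),
            np.nan,
        )
    cols = [
        "site",
        "codon",
        "count_wt",
        "count_mut",
        "co_wt",
        "co_mut",
        "rrt_wt",
        "rrt_mut",
        "l2fc_co",
        "l2fc_rrt",
    ]
    out = merged[cols]
    if categories is not None:
        out = out.merge(categories, on="codon", how="left")
    return out
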