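"""Codon-level translation-efficiency indices and decoding classification.

Implements the three standard codon indices — CAI (reference-set
relative synonymous usage), tAI (tRNA gene copies discounted by wobble
pairing penalties), and nTE (tAI supply over transcriptome-weighted
codon demand) — plus a wobble-rule classifier that assigns each codon
the decoding mode of its best available anticodon (Watson-Crick,
I34:C3/U3/A3, G34:U3, or U34:G3 wobble) and a rare/abundant class from
the summed gene copies of its decoders. A gene-level tally of
arginine-codon usage separates the AGA/AGG codons read by
t6A-containing tRNAs from the CGN codons read by tRNAs lacking t6A.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import CODON_TO_AA, FAMILIES, SENSE_CODONS, to_dna, to_rna
from .refio import OrfModel

#: Classical wobble-pairing penalties (selective constraints s); the
#: decoding contribution of an anticodon is (1 - s) * gene copies.
DEFAULT_S_PENALTIES: dict[str, float] = {
    "wc": 0.0,
    "I34:U3": 0.0,
    "I34:C3": 0.28,
    "I34:A3": 0.9999,
    "G34:U3": 0.41,
    "U34:G3": 0.68,
}

#: Anticodons with A at position 34 carry inosine in eukaryotes.
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

RARE_COPY_THRESHOLD = 4  # "rare" cognate tRNAs have <= 4 gene copies

T6A_DEPENDENT_ARG = ("AGA", "AGG")
T6A_INDEPENDENT_ARG = ("CGT", "CGC", "CGA", "CGG")


def load_trna_table(path: str | None = None) -> pd.DataFrame:
    """Load a tRNA gene-copy table (columns amino_acid, anticodon, gene_copies).

    Without ``path`` the bundled S. cerevisiae table is used. Derived
    columns: ``wobble34`` (anticodon position 34), ``inosine34`` (A34,
    edited to inosine), and ``t6a37`` (decodes ANN codons, anticodon
    position 36 = U).
    """
    if path is None:
        ref = importlib.resources.files("riboscan.data") / "trna_scer.tsv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    table["anticodon"] = table["anticodon"].str.upper().str.replace("T", "U")
    bad = table[~table["anticodon"].str.fullmatch("[ACGU]{3}")]
    if len(bad):
        raise ValueError(f"invalid anticodons: {bad['anticodon'].tolist()}")
    if (table["gene_copies"] < 0).any():
        raise ValueError("gene copies must be >= 0")
    table["wobble34"] = table["anticodon"].str[0]
    table["inosine34"] = table["wobble34"] == "A"
    table["t6a37"] = table["anticodon"].str[2] == "U"
    return table


def _pairing_options(codon: str) -> list[tuple[str, str]]:
    """(anticodon, pairing class) pairs able to decode ``codon``.

    The anticodon is read 34-35-36 and pairs the codon 3-2-1; positions
    35 and 36 must be Watson-Crick, position 34 may wobble.
    """
    rna = to_rna(codon)
    stem = _COMPLEMENT[rna[1]] + _COMPLEMENT[rna[0]]  # positions 35, 36
    third = rna[2]
    options = {
        "U": [("A", "I34:U3"), ("G", "G34:U3")],
        "C": [("G", "wc"), ("A", "I34:C3")],
        "A": [("U", "wc"), ("A", "I34:A3")],
        "G": [("C", "wc"), ("U", "U34:G3")],
    }[third]
    return [(w + stem, cls) for w, cls in options]


def compute_cai_weights(
    reference_counts: Mapping[str, int | float]
) -> dict[str, float]:
    """Relative-adaptiveness weights from reference-gene codon counts.

    w(codon) = count / max count within the synonymous family. Every
    amino acid must be observed in the reference set; codons unobserved
    within an observed family receive a 0.5 pseudo-count so weights
    stay positive.
    """
    counts = {to_dna(c): float(n) for c, n in reference_counts.items()}
    missing = [
        aa
        for aa, codons in FAMILIES.items()
        if not any(counts.get(c, 0) > 0 for c in codons)
    ]
    if missing:
        raise ValueError(
            f"amino acids absent from the reference set: {sorted(missing)}"
        )
    weights: dict[str, float] = {}
    for codons in FAMILIES.values():
        fam = {c: max(counts.get(c, 0.0), 0.5) for c in codons}
        top = max(fam.values())
        for c, n in fam.items():
            weights[c] = n / top
    return weights


def gene_cai(
    cds: str,
    weights: Mapping[str, float],
    exclude: Iterable[str] = ("ATG", "TGG"),
) -> float:
    """Geometric mean of CAI weights over a gene's codons.

    Single-codon families (Met, Trp by default) and stop codons are
    excluded from the mean.
    """
    skip = {to_dna(c) for c in exclude}
    logs = [
        np.log(weights[codon])
        for i in range(0, len(cds) - len(cds) % 3, 3)
        if (codon := cds[i : i + 3]) in weights and codon not in skip
    ]
    if not logs:
        raise ValueError("no scoreable codons in CDS")
    return float(np.exp(np.mean(logs)))


def compute_tai(
    trna_table: pd.DataFrame,
    s_penalties: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """tAI weights per sense codon from gene copies and wobble penalties.

    W(codon) = sum over decoding anticodons of (1 - s) * copies;
    w_tai = W / max W. Codons with W = 0 are assigned the geometric
    mean of the nonzero weights and flagged.
    """
    s = dict(DEFAULT_S_PENALTIES)
    if s_penalties:
        s.update(s_penalties)
    copies = dict(
        zip(trna_table["anticodon"], trna_table["gene_copies"].astype(float))
    )
    if sum(copies.values()) == 0:
        raise ValueError("tRNA table has all-zero gene copies")
    raw = {}
    for codon in SENSE_CODONS:
        W = 0.0
        for anticodon, cls in _pairing_options(codon):
            if cls not in s:
                raise ValueError(f"no penalty defined for pairing class {cls}")
            W += (1.0 - s[cls]) * copies.get(anticodon, 0.0)
        raw[codon] = W
    top = max(raw.values())
    w = {c: W / top for c, W in raw.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = float(np.exp(np.mean(np.log(nonzero))))
    rows = [
        {
            "codon": c,
            "capacity": raw[c],  # unnormalized decoding capacity W
            "w_tai": w[c] if w[c] > 0 else gm,
            "imputed": w[c] == 0,
        }
        for c in SENSE_CODONS
    ]
    return pd.DataFrame(rows)


def compute_nte(
    tai: pd.DataFrame,
    abundance: Mapping[str, float],
    orfs: Sequence[OrfModel],
) -> pd.DataFrame:
    """Normalized translational efficiency: tAI supply over codon demand.

    Demand for a codon is its transcript-abundance-weighted count over
    genes, normalized to frequencies; nTE = w_tai / demand, rescaled so
    the maximum is 1. Codons with zero demand are undefined (NaN).
    """
    if not abundance or all(v <= 0 for v in abundance.values()):
        raise ValueError("need at least one positive transcript abundance")
    demand = {c: 0.0 for c in SENSE_CODONS}
    for orf in orfs:
        a = float(abundance.get(orf.orf_id, 0.0))
        if a <= 0:
            continue
        for i in range(orf.n_codons):
            codon = orf.codon(i)
            if codon in demand:
                demand[codon] += a
    total = sum(demand.values())
    if total <= 0:
        raise ValueError("zero total codon demand")
    supply = dict(zip(tai["codon"], tai["w_tai"]))
    raw = {
        c: (supply[c] / (demand[c] / total)) if demand[c] > 0 else np.nan
        for c in SENSE_CODONS
    }
    top = np.nanmax(list(raw.values()))
    return pd.DataFrame(
        [
            {
                "codon": c,
                "demand": demand[c] / total,
                "nte_raw": raw[c],
                "nte": raw[c] / top,
                "defined": np.isfinite(raw[c]),
            }
            for c in SENSE_CODONS
        ]
    )


def classify_decoding(codon: str, trna_table: pd.DataFrame) -> tuple[str, str]:
    """Decoding category and cognate-abundance class of a codon.

    The category comes from the best available decoder under the wobble
    rules (lowest pairing penalty, ties broken by gene copies); the
    abundance class is that decoder's gene-copy count (<= 4 rare), so a
    codon whose dedicated tRNA is rare stays rare even when a wobble
    near-cognate is plentiful.
    """
    copies = dict(
        zip(trna_table["anticodon"], trna_table["gene_copies"].astype(float))
    )
    decoders = [
        (cls, copies[ac])
        for ac, cls in _pairing_options(codon)
        if copies.get(ac, 0) > 0
    ]
    if not decoders:
        raise ValueError(f"codon {codon} is undecodable under this tRNA table")
    order = {"wc": 0, "I34:U3": 1, "I34:C3": 2, "G34:U3": 3, "U34:G3": 4, "I34:A3": 5}
    cls, n_copies = min(decoders, key=lambda d: (order[d[0]], -d[1]))
    category = "Watson-Crick" if cls == "wc" else cls
    abundance = "rare" if n_copies <= RARE_COPY_THRESHOLD else "abundant"
    return category, abundance


def codon_index_table(
    trna_table: pd.DataFrame,
    reference_counts: Mapping[str, int | float] | None = None,
    abundance: Mapping[str, float] | None = None,
    orfs: Sequence[OrfModel] | None = None,
    s_penalties: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per sense codon: w_cai, w_tai, nte, decoding annotations."""
    out = compute_tai(trna_table, s_penalties)
    if reference_counts is not None:
        w_cai = compute_cai_weights(reference_counts)
        out["w_cai"] = out["codon"].map(w_cai)
    if abundance is not None and orfs is not None:
        nte = compute_nte(out, abundance, orfs)
        out = out.merge(nte[["codon", "nte"]], on="codon")
    cats = out["codon"].map(lambda c: classify_decoding(c, trna_table))
    out["decoding_category"] = cats.map(lambda t: t[0])
    out["abundance_class"] = cats.map(lambda t: t[1])
    out["amino_acid"] = out["codon"].map(CODON_TO_AA)
    return out


@dataclass
class ArgUsageRecord:
    gene_id: str
    n_aga: int
    n_agg: int
    n_cgn: int

    @property
    def n_t6a_dependent(self) -> int:
        return self.n_aga + self.n_agg

    @property
    def exclusive_t6a(self) -> bool:
        return self.n_t6a_dependent > 0 and self.n_cgn == 0


def rank_arg_usage(orfs: Sequence[OrfModel]) -> pd.DataFrame:
    """Per-gene arginine-codon usage, split by t6A dependence.

    AGA/AGG are decoded by t6A-containing tRNAs; CGN by tRNAs lacking
    t6A. Genes are sorted by their t6A-dependent fraction (descending);
    ``exclusive_t6a`` marks genes using only AGA/AGG for arginine.
    """
    rows = []
    for orf in orfs:
        tally = {c: 0 for c in T6A_DEPENDENT_ARG + T6A_INDEPENDENT_ARG}
        for i in range(orf.n_codons):
            codon = orf.codon(i)
            if codon in tally:
                tally[codon] += 1
        rec = ArgUsageRecord(
            orf.orf_id,
            tally["AGA"],
            tally["AGG"],
            sum(tally[c] for c in T6A_INDEPENDENT_ARG),
        )
        n_arg = rec.n_t6a_dependent + rec.n_cgn
        rows.append(
            {
                "gene_id": rec.gene_id,
                "n_AGA": rec.n_aga,
                "n_AGG": rec.n_agg,
                "n_CGN": rec.n_cgn,
                "n_arg": n_arg,
                "t6a_fraction": rec.n_t6a_dependent / n_arg if n_arg else np.nan,
                "exclusive_t6a": rec.exclusive_t6a,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["t6a_fraction", "gene_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
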