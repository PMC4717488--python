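# Methods

## Scope and model

The package analyses aligned ribosome-protected fragments (RPFs) to
quantify three aspects of translational fidelity in yeast: reading-frame
maintenance, initiation-site choice, and codon-specific elongation
speed. Read mapping itself is upstream of the package; inputs are a
genome (FASTA), an ORF annotation (GFF3), and alignments (SAM/BAM or a
BED-like TSV). All external coordinates are 1-based closed; conversion
to 0-based arithmetic happens only in `refio`.

The geometric model is the standard one for yeast 28-nt RPFs: the
P-site codon begins 12 nt 3′ of the footprint's 5′ end (the 5′
nucleotide itself being offset 0), mirrored on the minus strand; the A
site is one codon 3′ of the P site, the E site one codon 5′. The
simulator and the analyses share these constants (`riboscan.geometry`),
so a mis-specified offset is a testable failure, not a silent bias.

## Frame analysis

Only strict footprints enter frame statistics: length exactly 28 nt,
uniquely mapped, zero mismatches. Uniqueness is a configurable aligner
convention (mapping quality ≥ 10 and not secondary/supplementary for
SAM input; an explicit flag column for BED-like input) because
"uniquely aligned" is not a single well-defined property across
aligners.

Each ORF is tiled into k = clamp(round(L/300), 3, 9) codon-aligned
windows (round half up; the codon remainder spread over the leftmost
windows, so window lengths differ by ≤ 1 codon). A window "offends"
when it holds ≥ 32 P-sites of which ≥ 50% are off-frame; an ORF with
any offending window is called ambiguous. Both thresholds are exposed:
they are calibration choices, set so that a full-penetrance dual-frame
control separates cleanly from 20%-off-frame background noise, and
they are deliberately conservative — a 50% off-frame majority cannot
arise from the ~20% background by sampling noise at n ≥ 32
(P ≈ 10⁻⁵ per window).

Frameshift transitions are localized by an exact two-segment Bernoulli
change-point over the ordered per-P-site frame indicators (frame 0 vs
the dominant off-frame; the minority off-frame is ignored). The
reported coordinate is the first position of the right segment, so a
shift programmed at codon j is recovered at nucleotide 3j + 1
(1-based) up to the local density of informative P-sites.

The between-sample comparison is an unpaired two-sample t-test on
per-ORF frame-0 fractions over ORFs with ≥ 32 in-CDS P-sites in both
samples. The per-ORF unit was chosen over per-window because it keeps
ORFs as independent sampling units; a zero-variance degenerate case
(identical fraction in every ORF) returns t = 0, p = 1 by convention.

## Non-AUG initiation scanning

Candidates are UUG/ACG/GUG codons (configurable; GUC can be added) in
frame with the annotated AUG, within 100 nt upstream inclusive, with
no in-frame stop between candidate and AUG. Enumeration walks outward
from the AUG and stops at the first in-frame stop, which enforces the
stop-exclusion rule exactly. Distances are multiples of 3 by the
in-frame constraint, so the farthest admissible candidate starts 99 nt
upstream. Support is the P-site count in the extension region
(candidate start to AUG − 1): reads 5′ of the AUG cannot come from
AUG-initiated ribosomes, making the count specific to upstream
initiation. A candidate is reported at ≥ 128 supporting P-sites.
Offsets are reported in codon units (AUG = +1, nearest upstream codon
= −1) alongside nucleotide offsets.

## Codon dwell metrics

Only in-frame P-sites contribute (off-frame ribosomes have no
well-defined site codons), and the first and last 5 codons of each ORF
are trimmed (configurable) to keep initiation/termination piling out
of the dwell estimates. CO normalizes a site's codon frequency by the
background codon frequency over the trimmed CDS positions of ORFs with
at least one counted P-site; RRT normalizes within genes (≥ 100 reads,
configurable) before averaging across genes and rescaling to mean 1
per site. Both are invariant to uniform depth scaling by construction.
Log₂ fold-changes are computed per (site, codon) where both samples
are defined; undefined entries (zero background or no qualifying
positions) are flagged NaN and excluded from summaries.

## Codon indices

CAI weights are relative synonymous usage within each amino-acid
family over a user-supplied reference set; unobserved codons in an
observed family get a 0.5 pseudo-count so weights stay in (0, 1].
Gene-level CAI is the geometric mean excluding single-codon families
(Met, Trp). tAI uses gene copies from the bundled table with the
classical wobble penalties (G₃₄:U₃ 0.41, I₃₄:C₃ 0.28, U₃₄:G₃ 0.68,
I₃₄:A₃ 0.9999, I₃₄:U₃ 0); codons with zero decoding capacity are
imputed with the geometric mean of the defined weights and flagged.
Note that the max-normalized w_tai is *not* monotone in gene copies —
raising copies of a tRNA feeding the maximal codon deflates every
other normalized weight — so the unnormalized capacity W is also
reported and is the quantity with the monotonicity guarantee. nTE is
tAI supply over transcript-abundance-weighted codon demand, max-1
rescaled; both the demand frequency and the raw ratio are reported.

Decoding classification assigns each codon the pairing class of its
best available decoder (lowest penalty, ties to the higher-copy
anticodon); the rare/abundant class (≤ 4 vs > 4 gene copies) uses that
decoder's copies, not the sum over all wobble-capable anticodons, so
AGG (dedicated tRNA-Arg(CCU), 1 copy) classifies as rare even though
an abundant near-cognate exists. The bundled tRNA table is assembled
from the standard S. cerevisiae nuclear tRNA gene set (GtRNAdb-style
copy numbers, elongator Met only) and can be replaced by any TSV with
the same columns.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not raw sequencing: ORFs of specified lengths and codon composition
separated by ≥ 200-nt random intergenic spacers; ribosome placements
drawn per P-site position with probability proportional to the dwell
weight of the A-site codon (the decoding site); one read per
placement at the shared 12-nt offset. Events:

* **frameshift(j, ±1, p)** — a fraction p of ribosomes at or beyond
  codon j carries its P-site in the shifted frame; the ORF sequence is
  built to be stop-free in the shifted frame downstream of j (a
  dual-frame coding path), and shifted paths that do meet a stop are
  truncated with a warning.
* **upstream_init(−k, codon, p)** — extension coverage between the
  planted near-cognate and the AUG at p times the per-codon loading
  rate, in the main frame; the upstream window is sanitized (no
  accidental near-cognates or in-frame stops inside, one stop just 5′
  of the plant) so the planted candidate is the only scoreable one.

Read-level noise: length jitter via a read-length distribution,
mismatch and multimap flags as independent Bernoulli draws, and an
`offframe_rate` that displaces a placement's P-site by ±1 nt — the
knob that reproduces the ~20% background of off-frame P-site calls
seen in real profiling. Its default is 0 (clean geometry); the
analysis drivers set 0.18/0.22 to mirror the ~80% in-frame fraction of
real data. Everything is seeded; identical spec + seed gives
byte-identical truth tables.

What the generator does **not** emulate: base-level sequencing error,
rRNA contamination, ligation/PCR bias, coverage over-dispersion beyond
Poisson, 5′-offset heterogeneity across read lengths, and uORF or
stop-readthrough translation. Passing tests therefore certify the
analysis logic and its calibration against the generator's model of
the data, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Tests and drivers run at desk scale by design: recovery suites use 20
seeded genomes of 8 ORFs (600–900 nt) at depth 20 for ambiguity
sensitivity/FPR, one 40-ORF genome at depth 50 for CO/RRT parameter
recovery (Spearman ≥ 0.9 against log-normal dwell multipliers), and
10 seeds × 40 loci for the doubled-upstream-initiation comparison,
with per-locus penetrance drawn uniform on (0.03, 0.32) so the
128-read support threshold bisects the penetrance range — the regime
in which doubling penetrance doubles the number of loci crossing the
threshold. Headline dataset-scale numbers from deep libraries
(~10⁸ mapped reads) are out of desk-scale reach and are replaced by
these property and calibration checks.

Other numerics: window rounding is half-up; change-point likelihoods
use the MLE segment rates with 0·log 0 = 0; CO of a codon absent from
the background is NaN; RRT requires ≥ 1 qualifying gene and errors
otherwise; the t-test requires ≥ 3 qualifying ORFs. ORFs shorter than
9 nt are skipped by windowing; CDS lengths not divisible by 3 load
with a `truncated` flag and a warning.

## Known limitations

* The ambiguity-calling thresholds are calibration defaults, not
  derived quantities; different noise regimes need re-calibration.
* The change-point model assumes a single dominant off-frame per ORF;
  ORFs with both +1 and −1 events report only the dominant one.
* Dwell weights key on the A-site codon only; pair and context
  effects (P×A interactions, wobble-position stacking) are not
  simulated and would dilute CO/RRT recovery on real data.
* The bundled tRNA table is a curated snapshot; users with updated
  gene-copy counts should supply their own TSV.
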