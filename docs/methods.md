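# Methods

## The synthetic hybrid-embryo model

The generator produces all inputs the analysis consumes, with machine-readable
ground truth, under one seeded configuration (`SimConfig`).

**Genomes.** Each ortholog pair occupies its own chromosome, present in both
parental species at identical coordinates. An ancestral sequence is drawn
uniformly over ACGT; the second species substitutes each site independently
with a per-pair divergence sampled from Normal(0.143, 0.039) truncated to
(0.01, 0.5) — the observed orthologous divergence between the two *Ciona*
species. Substitutions only, no indels: this keeps ortholog coordinates
aligned, so window identities and k-mer diagnostics are exactly analyzable.
It is a deliberate simplification; real promoters also diverge by indels, and
the alignment-based identity option exists mainly for that case. Genes have 3
exons of 300 bp with 200-bp introns by default, alternate strands, and at
least 2.5 kb of flank (covering the 1-kb upstream window and 2-kb metagene
flanks). Species-biased ASE pairs receive extra substitutions (rate 0.25) in
the 100–300 bp window upstream of the CDS start of species B, emulating the
diverged cis-regulatory elements that the identity comparison is meant to
detect.

**Expression program.** Stage is ordinal time over the 11-stage series
(1-cell … late-neurula). Abundance of each allele decomposes into

- a maternal deposit (default 500 units) carried by the maternal allele of
  each cross and decaying geometrically at 10% per stage (the study gives no
  decay kinetics; geometric per stage is the simplest memoryless choice);
- a zygotic component switching on at the gene class's onset stage at a low
  initiation level (2 units) and plateauing at 10 units one stage later.

Classes and defaults: maternal-only 30%, early zygotic 5% (onset 8-cell),
minor wave 22% (onset 16-cell), housekeeping 37% (deposit plus reactivation
at 64-cell), and zygotic-only ASE 6% (onset mid-gastrula; the 6% matches the
observed 341/5,879 zygotic-only share). Allelic cis strengths implement the
quadrant composition (default 138/106/90/7 species-A/species-B/maternal/
paternal-dominant, apportioned by largest remainder when fewer ASE genes are
simulated) with a 4-fold allele ratio (log2 effect 2). Maternal- and
paternal-dominant pairs favor whichever allele was inherited from that
parent, so their favored allele switches between crosses; species-dominant
pairs favor the same allele in both.

Absolute magnitudes are calibrated only to reproduce the ordering and wave
structure of the system — zero paternal signal through the 4-cell stage,
first paternal expression at the 8-cell stage, a minor activation pulse into
the 16→32-cell transition and a major one into 64→112-cell — not any
particular printed percentage, which depends on unknowable absolute depths
and decay rates in the real data. The onset-level default (2 units) is set so
that a newly activated gene yields a handful of reads at the default
sequencing depth (20,000 reads per sample): first detection then coincides
with the true onset stage, which is what makes the wave labels well-defined.

**Reads.** Bulk reads sample (pair, allele) sources multinomially with weight
abundance × transcript length, uniform start positions, and independent
per-base substitution errors (default 0.5%). A configurable fraction of reads
is drawn from unspliced pre-mRNA instead of the spliced transcript, which is
what gives the intronic-read ratio its signal. The truth sidecar (TSV: read
id, pair, allele, class, template, start) is the oracle for assignment tests.

**Single cells.** Lineages are drawn from the 9-type composition observed at
the 64-cell stage (n = 40, 43, 32, 187, 259, 150, 70, 20, 43 from endoderm to
epidermis). The maternal pool is shared across lineages; housekeeping
reactivation is gated by a per-lineage onset stage (endoderm 32-cell,
notochord 64-cell, mesenchyme/nerve cord 112-cell, the rest early neurula)
and doubles each stage after onset, so endoderm leads notochord, which leads
the rest — the configured ordering the estimators must recover. Counts are
independent Poisson draws around expectations scaled to a lognormal library
size (mean 2,000 counts, σ = 0.3); a debug flag replaces the draw with the
expectation. One marker gene per lineage is expressed exclusively in that
lineage so that marker annotation is testable without graph clustering —
droplet chemistry, doublets, and ambient RNA are deliberately not modeled,
so passing tests say nothing about those failure modes in real data.

**Tracks and stiffness.** Coverage tracks put background-plus-activity signal
over gene bodies (activity = the gene's zygotic level at the stage), plain
background over 2-kb flanks. Stiffness decreases by 0.3 per onset rank with
±0.05 seeded jitter, placing endoderm and notochord on top, consistent with
the measured mechanics of early embryonic lineages.

## Analysis choices

**Read assignment.** Canonical (strand-collapsed) k-mers, k = 21, because
library strandedness is not assumed. Thresholds minDiagnostic = 2 and
margin = 2 trade a little recall for specificity; ambiguous reads are
excluded from both numerator and denominator of the paternal ratio (an
include-in-denominator variant is a one-line change in `counts_by_parent`
callers, since ambiguous totals are carried per stage). Reads whose species
is called but whose gene vote ties are excluded from per-gene counts.

**Wave detection.** A transition's activation score is the number of paternal
genes first expressed at its *left* stage: a gene switching on at 16-cell at
initiation level ramps to plateau across 16→32, which is exactly the
transition the wave labels name. The per-stage paternal-ratio change is
reported alongside as corroboration and used only to break ties. Fewer than
two positive transitions yields an explicit single-wave flag. The module
surrogate assigns each expressed paternal gene to the wave transition holding
its maximal consecutive-stage FPKM increase; this captures the minor/major
dichotomy without reproducing a full co-expression network analysis, whose
module count is dataset-specific.

**De-novo calling** uses the paternal copy's FPKM only, threshold 0.1, and
"all paternal genes ever expressed" as the per-stage ratio denominator (the
alternative, all annotated genes, only rescales the ratios).

**Timing classes.** First expression at 8/16/32-cell → early; 64/112-cell →
transition; later → late. The 112-cell stage belongs to both the transition
and late spans in the source material; first expression there is assigned to
transition (earlier-class rule) while the late evaluation window still spans
112-cell through late-neurula. δ = 1 (2-fold) and ε = 0.1 are stated defaults,
recorded in outputs, since no published values exist for either.

**Single-cell statistics.** The per-cell ratio is computed on raw counts —
it is scale-free, so library-size normalization is unnecessary. Pairwise
Welch t-tests with Bonferroni correction over all tested pairs (a pooled-
variance flag exists; the source states "Student's t-test" without a variance
assumption, and Welch is the safer default). Housekeeping stability uses
cvMax = 1.0 on the maternal FPKM profile; no published value exists.
Stage-specific detected-gene windows: 1000–7000 (64-cell), 2000–7000
(112-cell), 500–4500 (early neurula), after the global ≥ 3 cells / ≥ 250
genes floor; gene filter first, each filter applied once (idempotent).
Spearman correlation against stiffness uses an exact permutation p-value for
n ≤ 8 lineages.

**Upstream identity.** Windows of 100 bp indexed from the start codon
outward, so "100–300 bp upstream" means windows 2–3. Identity is computed
from a needle-style global alignment (match 5, mismatch −4, gap open 10,
extension 0.5; the first gap base costs 10.5) as identities / alignment
columns; an ungapped columnwise mode is available behind a flag (with
substitution-only simulated data the two agree closely). Windows that are
more than half N are reported missing. Group comparisons use the one-tailed
Wilcoxon rank-sum test (exact for combined n ≤ 20 without ties, otherwise
the tie-corrected normal approximation), alternative: the species-biased
group is lower.

**Motif scanning.** PWMs are pseudocount-smoothed (0.1 × background) count
matrices; scores are log2 odds against a 0-order background. P-values are
exact tail probabilities of the discretized score distribution computed by
dynamic programming at 10⁻³-bit resolution (discretization shifts p-values by
far less than the 10⁻⁴ emission threshold for widths ≤ 20); the test suite
checks the DP against exhaustive 4^w enumeration. Both strands are scanned;
hits are emitted strictly below the threshold. JASPAR PFM text is the only
motif input format parsed.

**Metagene matrices.** Flanks are binned at fixed 100-bp width, gene bodies
rescaled to 100 mean-per-bin values, rows oriented TSS-left (minus-strand
rows reversed); genes not covered by the track yield all-NaN rows.

## Problem sizes and numerics

Default simulations use 120 ortholog pairs, 900-bp transcripts, and 20,000
reads per bulk sample — sizes at which every distributional property the
tests assert (3-SE calibration bands, 9-of-10 replicate recoveries) is
comfortably identifiable while the full suite runs in minutes. Binomial SE
bands are evaluated at the larger of the true and estimated proportion, since
the SE at a truth of exactly zero is degenerate; under the default 0.5%
per-base error rate roughly one read in 20,000 from a pre-ZGA sample is
misassigned (the >99.99% regime), and error-free assignment is exact.
Determinism: all randomness derives from the single config seed through
named, independent RNG streams, so identical configurations give
byte-identical outputs regardless of call order; results are independent of
the CLI `--threads` value, which exists for interface compatibility.

## Known limitations

- No indels, isoforms, trans-splicing, or UMI/barcode chemistry; coverage
  tracks are a scalar activity proxy, not a chromatin-state model.
- The k-mer classifier stands in for dual-genome spliced alignment; at low
  per-pair divergence (near the 1% truncation floor) reads carry few
  diagnostics and the ambiguous class grows.
- The wave detector assumes de-novo counts are informative at the simulated
  depth; at very low depth first detection slips past the onset stage and
  transitions blur.
- Marker-based annotation replaces graph clustering; it is deterministic and
  testable but cannot discover unannotated cell states.
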