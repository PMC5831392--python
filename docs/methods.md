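# Methods

This note documents the models implemented in `srnapipe`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that were genuinely open.

## Read cleaning

The filter cascade assigns each read to the first failing test, in the
order missing 3' adapter → empty insert → 5' adapter contamination →
short insert (< `min_len`, default 18 nt) → poly-A → clean.  The order
matches the order in which sequencing summaries conventionally tabulate
removals; because the categories are evaluated as a cascade, every read
lands in exactly one bucket and the accounting identity
`clean = high_quality − Σ removed` holds by construction.  Two further
operational definitions the upstream literature leaves unstated:

* **3' adapter detection** — the longest prefix of the adapter (≥ 6 nt,
  ≤ 1 mismatch) found in the read, preferring longer prefixes and then
  leftmost occurrences.  The insert is everything before the match.
* **poly-A** — an insert with ≥ 70% adenine.  Any threshold between the
  A content of real mature miRNAs (bounded well below 0.7) and 1.0
  behaves identically on the generator's reads; 0.7 is a conventional
  low-complexity cutoff.

The raw → high-quality step (base-calling QC) happens on image-level
data that no reusable artifact can reproduce; the pipeline treats its
FASTQ input as high-quality reads and reports raw = high-quality.

Genome mapping is exact substring search of collapsed unique reads over
both strands.  Mismatch-tolerant alignment would only admit reads that
the downstream zero-mismatch quantification rule discards anyway, at
considerable cost in complexity.  Coordinates are 0-based half-open
internally and 1-based inclusive in every report and GFF3 file.

## miRNA identification

A read counts toward a mature miRNA iff (a) it occurs within the
annotated precursor with zero mismatches and (b) its precursor interval
overlaps the mature interval by at least 16 identical bases.  Offsets
("dislocation") are otherwise unrestricted — the 16-base identical
overlap is the operative constraint.  Matures with fewer than 10 reads
in a library are zeroed in that library; the floor is applied per
library, reading "in each sample" in its plain sense.  A read matching
k matures contributes 1/k to each (count conservation); a
count-to-each mode is available behind a flag and marks its count
matrix as non-conserving.

Small-RNA classification assigns each unique read to one class by fixed
priority (known miRNA > rRNA > tRNA > snRNA > snoRNA > repeat >
unannotated), so class tallies always sum to the clean-read total.

### Folding model

`fold_rna` minimizes a deliberately simple, fully documented energy
function over pseudoknot-free structures: each canonical pair
contributes G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol, and each maximal
single-stranded run enclosed by at least one pair costs +0.5 kcal/mol;
exterior bases are free.  Hairpin loops of ≥ 3 nt are enforced by
forbidding pairs spanning < 5 positions.  The dynamic programme tracks,
besides the usual paired-interval table, whether the current interior
position extends an open single-stranded run, which makes the per-run
penalty exact.  The model is coarse next to nearest-neighbour parameter
sets, but it is exactly checkable: the test suite proves DP =
exhaustive enumeration on hundreds of short random sequences, something
no black-box folding engine offers.  An external engine can be
substituted at the call site; all shipped thresholds were chosen for
the built-in model.

The hairpin acceptance threshold is MFE ≤ −18 kcal/mol.  (A positive
bound on a folding energy would be vacuous; the sign convention is
energy-like throughout.)  Novel-candidate discovery uses read clusters
with inter-read gap ≤ 10 nt, 20 nt excision flanks, precursor length
≤ 300 nt and candidate matures of 18–26 nt — repository defaults chosen
once for this artifact, since the original discovery tool's internal
defaults are not published.  The candidate mature (most abundant
supporting read) must lie on a single arm with ≥ 16 bases inside the
stem.  Because a hairpin's reverse complement is also a hairpin, each
locus surfaces on both strands; candidates are deduplicated on the
mature sequence.  Cross-study comparison of novel matures reports a
pair when some ungapped alignment window of ≥ 18 bases has ≤ 1
mismatch; a database E-value criterion is meaningless at desk scale
(no database size to condition on) and the coverage/mismatch rule is
the operative filter.

## Differential expression

Expression is TPM = count / total clean reads × 10⁶ — the denominator
is the library's clean-read total, not the miRNA-mapped total
(switchable).  The Audic–Claverie conditional probability

    p(y|x) = (N₂/N₁)^y (x+y)!/(x!y!) (1+N₂/N₁)^−(x+y+1)

is the negative binomial with x+1 successes and success probability
N₁/(N₁+N₂); the final exponent must be negative for the distribution
to normalize, and the normalization Σ_y p(y|x) = 1 is asserted to 1e−9
in the tests.  All terms go through log-gamma; raw factorials never
appear.  Tails include the observed count on both sides
(C = P(Y ≤ y|x), D = P(Y ≥ y|x)); the small tail is summed directly so
it never suffers cancellation.  The default p-value is two-sided
(doubled smaller tail, capped at 1) with a one-sided mode behind a
flag; the tail-combination convention is not fixed by the formula
itself, and the two-sided choice is the conservative one.  Note that
with these x-fixed (negative binomial) tails the test is not exactly
symmetric under exchanging the two libraries; the package follows the
printed tail definition rather than imposing symmetry.

Bonferroni multiplies by the number of miRNAs actually tested in the
pair (rows with any nonzero count after the 10-read floor).  Calls
require |log₂ fc| ≥ 1 and corrected p < 0.01.  The fold-change
pseudocount is 0.01 TPM, used only to keep zeros finite; planted-effect
recovery is insensitive to it across two orders of magnitude.

A small 2^−ΔΔCt helper converts qPCR Ct values to relative expression
for cross-platform comparisons; the wet-lab assay itself is out of
scope.

## Target prediction

A gene is a candidate target of a miRNA iff it carries at least one
canonical seed site (7mer-A1, 7mer-m8 or 8mer on miRNA positions 2–8,
no G:U in the seed) *and* at least one site with duplex hybridization
energy ≤ −20 kcal/mol under the shared pair constants (G:U allowed in
the duplex body, single bulges permitted at +0.5).  This is the
intersection of a seed-based and an energy-based prediction.  Trained
context-score percentiles require feature weights that cannot be
reproduced from published material; site-type classification replaces
them, and that substitution is deliberate and visible in the API.
Whole transcripts are scanned rather than annotated 3' UTRs.  A
permissive "any 7 contiguous complementary bases in positions 1–8"
mode exists behind a flag.

## Enrichment

Term over-representation uses the exact hypergeometric upper tail
P(X ≥ k) (scipy's survival function, checked against exact rational
combinatorics for all population sizes ≤ 60).  Multiple testing is
Benjamini–Hochberg within each namespace at FDR < 0.1, switchable to
Bonferroni; the upstream tooling this models does not state its
correction, and BH is the field default for enrichment.  The
background defaults to the supplied expressed-gene list (FPKM > 1)
when given, else all annotated genes.  Terms annotating fewer than two
background genes are skipped as degenerate.

## Network

Interaction edges below combined score 0.4 are dropped; only candidate
target genes with a surviving interaction edge enter the network,
together with the miRNAs that regulate them.  Hub genes are the
ceil(0.05 × gene count) nodes of highest total degree — ceiling, so 92
genes yield 5 hubs — with ties broken lexicographically for
determinism; degree counts both edge types by default
(interaction-only behind a flag).  Hub miRNAs are exactly the
regulators of hub genes.

## Synthetic data

The generator is the package's study stand-in, with defaults fixed
once: three tissue libraries (duodenum, cecum, colon), 30 known miRNA
loci and 6 novel hairpin loci, 20,000 nominal reads per library,
contamination rates proportioned like a typical accounting table
(0.94% missing 3' adapter, 0.07% empty insert, 0.03% 5' contamination,
2.45% short, 0.05% poly-A), mature lengths peaking at 22 nt, Poisson
counts with mean 200, and 20% of known miRNAs planted at 4-fold in one
library.  Counts are Poisson because that is the sampling model the
conditional test assumes; a gamma-Poisson overdispersion knob exists
and defaults off.  Depth and locus counts are desk-scale choices — the
statistical structure, not the magnitude, of a real study.

Construction guarantees replace post-hoc filtering wherever a
downstream check must be exact:

* every emitted read is verified against the actual QC classifier at
  generation time, so the generator's per-category ledger equals the
  filter tallies identically;
* precursor loci are perfect inverted repeats (stem = the full mature,
  non-pairing A/C loop ≤ 10 nt), bounding their MFE far below −18;
* star-arm (3p) reads are emitted at 15% of the guide strand so read
  clusters bridge the loop and the whole precursor is excised — as in
  real libraries, where the passenger strand is sequenced at a minor
  fraction;
* planted target sites are full reverse complements (8mer sites with
  strong duplex energy); accidental canonical seed matches of
  differential miRNAs elsewhere are scrubbed, and matures are drawn so
  that no miRNA's seed motif occurs inside another's planted site,
  making predicted target sets equal planted sets exactly;
* planted enriched terms cover ~80% of the target pool against a large
  background; planted hubs receive dominant interaction degree, and
  the expected network arithmetic is recorded by set algebra
  independent of the network module.

What the generator does **not** emulate: sequencing error and quality
variation, isomiR heterogeneity, expression correlation across miRNAs,
overdispersion (by default), genomic repeat structure, and realistic
genome or transcript content.  Passing tests therefore demonstrate the
correctness of the algorithms and their statistical calibration under
the stated sampling model — not robustness to the noise sources of
real libraries.

## Problem sizes and determinism

The default test suite and the acceptance script run the full pipeline
at 12–30 miRNA loci and a few thousand reads per library, sizes chosen
so a complete run finishes in seconds while every planted effect is
still recoverable with high power (a 4-fold change at mean count 200
has an Audic–Claverie p-value many orders below the Bonferroni
threshold).  All randomness flows from one integer seed through
`numpy.random.default_rng`; a fixed seed gives byte-identical FASTQ,
reports and summaries, and the pipeline is a pure function of
(inputs, config, seed).

## Known limitations

The energy model ignores stacking context and loop-size dependence, so
its MFEs are not comparable to nearest-neighbour engines; thresholds
are calibrated to the built-in model.  Known-miRNA assignment ignores
isomiR ends beyond the 16-base rule.  The Audic–Claverie test models
single libraries without biological replication; replicate-aware
models (negative binomial GLMs) are out of scope.  Enrichment takes
term sets as given with no ontology-graph propagation.  The network
stage consumes a static interaction table; no live database access.
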