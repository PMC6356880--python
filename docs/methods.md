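# Methods

## Sequence model and conventions

All sequences are held internally in an uppercase RNA alphabet (T is
normalized to U on input), because mature miRNAs, variant tables and
precursor sequences circulate in mixed alphabets.  Genomic intervals are
0-based half-open internally — which keeps the 10-kb cluster-gap arithmetic
unambiguous — and are converted to 1-based inclusive coordinates only when
writing GFF3.  The miRNA *seed* is bases 2–8 of the mature sequence
(1-based), the primary determinant of target specificity.

## Erroneous sequence variants (ESVs)

The error model distinguishes three position classes inside a read: the
first `window` bases (5'-terminal), the last `window` bases (3'-terminal)
and everything between (internal).  `window` defaults to 2: the terminal
bias of library-preparation artifacts concentrates in the outermost bases,
and a two-base window keeps all three classes populated on 18–25-nt reads.
The width is configurable because the biological statement "last bases at
the 3' end" has no canonical width.

The class error ratio is defined as the ratio of variant-carrying reads to
perfectly matching reads, count-weighted, measured by ungapped alignment of
collapsed reads against two abundant control RNAs (1750 nt and 540 nt) that
are not expected to be RNA-edited.  A read whose mismatches touch several
classes contributes to each class it touches.  Reads needing more than 3
mismatches anywhere are treated as not control-derived and ignored; indels
are not modeled (such reads simply fail to align), which matches the
ungapped visual-alignment procedure the estimate emulates.  Alignment is an
exact all-offset scan (vectorized over reference windows); ties go to the
smallest offset, and reads aligning equally well to both controls are
assigned to the first reference in input order.

The estimator fails loudly (rather than returning zeros) when no read
aligns, or when no read aligns perfectly — a ratio with an empty denominator
is meaningless.

### The isomiR/ESV count threshold

The verbal rule "use the canonical read count and the error ratio to set a
lower threshold" is realized as

    threshold(class) = max(min_count, ceil(alpha * r_class * canonical_count))

with `alpha = 2` and `min_count = 10`.  `alpha * r_class * canonical_count`
is (twice) the expected number of artifact reads of that class under the
parent's sequencing depth; the factor 2 buffers noise in the estimated
ratio, and the floor of 10 reads guards low-depth parents where the
expectation is meaningless.  Both knobs are exposed (`FilterParams`).

## IsomiR classification

Reads are anchored to canonical matures by an exact occurrence of the
canonical's seed; the anchor fixes the alignment register, after which the
category is forced: identical → canonical; shifted start or first-base
substitution → 5' variant; substitutions confined to the 3'-terminal window
(same terminal window as the error model, so variant classes and error
classes correspond) → 3' substitution variant; length change at the 3' end →
3' length variant; any other substitution → internal mismatch.  Seed-exact
anchoring means a read whose only edit lies in the seed will not anchor to
its true parent — a deliberate property shared with seed-extension aligners:
a seed-changed molecule is functionally a different miRNA.  When several
canonicals anchor the same read, the fewest-edit call wins, ties broken by
canonical id order (determinism).

Two exclusion rules precede threshold filtering, both reflecting what
short-read data cannot distinguish rather than what biology forbids:

- reads *shorter* than their canonical are dropped (degradation products
  produce identical prefixes);
- length/5' variants whose extra bases match the genomic context
  (precursor plus 30-nt flanks) are dropped as *templated* — they are
  expected from imprecise processing or precursor degradation and cannot be
  attributed to post-transcriptional modification.  Substitutions are never
  templated by definition, so only non-templated 5' variants, 3' variants
  and 3' length variants are reportable.

Allelic variants are internal single-substitution calls that pass the
internal-class threshold and whose read fraction among variant + canonical
reads is strictly greater than 0.40.  The fraction uses only the two-allele
pool (not all isoforms), matching the two-allele framing of polymorphic
miRNA tables.

## Novel-miRNA validation

Hairpin structure is computed by maximum-cardinality nested base pairing
(Nussinov-style dynamic programming; AU, GC and GU pairs; minimum hairpin
loop 3; deterministic traceback preferring the closing pair, then the
smallest split point).  This is a deliberate simplification: the evidence
rule is a *pairing fraction*, not an energy, so a thermodynamic folder is
unnecessary; the trade-off is that the fold is an upper bound on pairing and
carries no stability information.

The five evidence rules are quantified as: (1) ≥ 2 distinct sample ids;
(2) ≥ 10 count-weighted zero-mismatch reads overlapping a mature arm;
(3) both arms pair with each other in the fold and each arm's 3' end
extends 0–4 nt past the base paired with the partner arm's 5'-most paired
base; (4) the modal 5'-start fraction on the dominant (most-read) arm is
≥ 0.9 — the homogeneity notion is inherently qualitative, so the 0.9
default is exposed; (5) strictly more than 60 % of each mature's bases are
paired.  Rule evaluation raises, naming the unevaluable rules, when no read
evidence is attached.

Repeat-likeness is exact occurrence counting of the precursor on both
strands of the supplied genome (flag at > 15 loci); on synthetic genomes
exact counting reproduces the intent of a homology search without one.
Clustering is single-linkage chaining of same-contig, same-strand loci with
inter-gene gap (closest ends) ≤ 10 kb — the gap-wise reading is the stricter
of the possible anchor conventions; cluster ids are named after the leftmost
member so output is order-invariant.

## Target prediction

A site is an exact Watson–Crick reverse complement of seed bases 2–8 on the
UTR; requiring an exact motif match *is* the "no G:U in seed" constraint.
The duplex-stability filter extends the seed duplex base by base in both
directions while Watson–Crick or G:U pairing holds — internal loops and
bulges terminate extension, so the score covers the perfect-complement run
only — and sums nearest-neighbor stacking energies from a bundled table.
The Watson–Crick stack values are the standard Turner ΔG°37 set; stacks
involving a G:U wobble are approximated by a single weak constant (−0.5
kcal/mol; 0.0 for the destabilizing 5'GU/3'UG motif), clamped at ≤ 0 so
duplex energy is monotone non-increasing under extension.  The default
acceptance threshold is −18 kcal/mol.  This model ranks seed-plus-
supplementary complementarity sensibly but does not reproduce the
minimum-free-energy values of a full hybridization folder; absolute energies
should not be compared against such tools.  Set comparisons are
transcript-level (a transcript counts once regardless of site multiplicity).

## Expression and qPCR

RPM = count / library total × 10⁶; replicates of a tissue are averaged
*after* normalization.  A miRNA is *ubiquitous* when its max/min tissue RPM
ratio is ≤ 3 (all tissues nonzero) and *enriched* in the smallest
abundance-ordered tissue prefix whose every member exceeds 10× the mean RPM
of the remaining tissues — the mean-of-others baseline matches the reporting
convention of the qPCR enrichment table, and the prefix construction lets a
miRNA be enriched in "one or a few" tissues (e.g. muscle + heart).
Enrichment against an all-zero outside group is not called (undetected
elsewhere is "neither", not infinite enrichment).  Diversity counts miRNAs
with ≥ 1 raw read per stage (`detect_min` exposed); proportions are per-stage
count fractions.

ΔCt normalizes each Cq against the arithmetic mean of the two reference
miRNAs (the combination rule is not dictated by the ΔΔCt method itself;
the mean is the symmetric choice); ΔΔCt subtracts the pooled mean ΔCt of
all non-focal samples; fold change is 2^(−ΔΔCt), rounded to the nearest
integer for reporting.  Significance uses Student's two-sample t-test on
per-sample ΔCt values with Bonferroni correction over the batch; with fewer
than two samples in a group the p-value is reported as unavailable rather
than fabricated.

## Synthetic data: what it emulates, and what it does not

The generator designs hairpins as 5'-arm + loop + reverse-complement arm
(arms 21–24 nt, loops 13–22 nt, total 55–70 nt) embedded in plus-strand
contigs with recorded 30-nt flanks; a configurable number of leading gene
pairs are placed 8 kb apart to create known clusters.  The loop's first base
is fixed to C so a planted 3' U-addition on the 5p arm is non-templated by
construction; planted substitutions and 5' extensions likewise avoid their
templated base.  Libraries mix canonical matures (log-normal abundances,
σ = 0.3), planned variants, allelic variants at 50 % fraction, 5'-intact
degradation fragments, templated precursor fragments, and control-derived
reads (default 20 % of the library — the real fraction of control-RNA reads
in a total-RNA library is not knowable a priori; 20 % keeps the estimator
well-fed without dominating), all on a 36-cycle single-end read with 3'
adapter read-through and constant Phred symbols.

Substitution errors are injected with at most one substitution per read,
the class drawn with probability proportional to its configured ratio
(P(class c) = r_c / (1 + Σr)).  This parameterization makes the configured
value exactly the quantity the estimator measures — the ratio of class-c
variant reads to perfect reads — so parameter recovery is a meaningful
closed loop.  Default planned-variant abundances (2.5× canonical for
3'-class variants, 0.5× for the 5' variant) sit about six-fold above their
class thresholds, and default polymorphisms sit at internal position 12
(outside both the seed and the terminal window).

What the generator does **not** emulate: quality-score variation coupled to
errors, indels, PCR duplication, multi-error reads, RNA editing beyond the
planted edits, minus-strand genes, and expression correlation structure
across tissues.  Passing recovery tests therefore demonstrates that the
pipeline's logic is correct under its own assumptions — not that those
assumptions hold for any particular real platform, where error rates must
be re-estimated from that library's own control alignments (which is the
point of the method).

## Problem sizes and determinism

Recovery tests and the acceptance script use 100,000-read libraries
(20 genes, or control-only for rate estimation); at this depth the binomial
uncertainty on the 3'-terminal ratio is ≈ 0.002, comfortably inside the
3-standard-deviation recovery bands the tests assert.  Every stochastic
component takes an explicit seed, and independent generator stages use
distinct seed-derived streams so that, e.g., control references never share
subsequences with the miRNAome generated from the same seed.

## Known limitations

- Ungapped alignment only; indel-bearing reads are invisible to both the
  error model and the classifier.
- Seed-exact anchoring cannot assign reads whose only edit is in the seed;
  in-seed allelic variants are detectable from explicit reference/variant
  pairs but not discovered de novo from reads.
- The duplex model ignores loops, bulges, dangling ends and initiation
  terms; wobble stacking is a constant approximation.
- Maximum-base-pairing folds over-pair relative to thermodynamic structures;
  the 60 % pairing rule is evaluated on an optimistic structure.
- The tissue classifier assumes tissues are comparable after RPM scaling;
  no between-library composition correction is applied.
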