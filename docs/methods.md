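# Methods

This note documents the models, rules and numerical choices behind
`stressmir`, and what the synthetic-data experiments do and do not
demonstrate.

## Read processing

Reads are cleaned by removing the 3′ sequencing adapter at its leftmost
full occurrence, or at a terminal partial match of ≥6 nt (shorter
terminal matches are indistinguishable from genomic sequence).  After
trimming, a read is dropped if it falls outside 18–30 nt, contains an
ambiguous base, or has any base below Q20.  The Q20 floor is our
definition of "low quality": it is simple, testable, and exercised by
the generator, which writes errored bases at Q10 and everything else at
Q40.  Drops are logged by reason.

Cleaned libraries are collapsed to unique sequences with exact
per-library counts.  Categorization excludes structural RNAs first: a
read exactly contained in any rRNA/tRNA/snRNA/snoRNA/repeat catalog
entry takes that class (priority in that order on ties) and is never
considered a miRNA.  Remaining reads are assigned to a known miRNA when
their distance to a catalog entry is ≤3.  Distance is the Hamming
distance over the best ungapped offset alignment with read overhang
positions counted as mismatches — an ungapped model, because the
mismatch rule speaks of substitutions, never gaps.  Contaminant
matching is exact containment rather than an aligner heuristic, which
keeps the rule reproducible.

Reference matching is exact full-length substring containment: both
strands for genome-style references, sense only for transcript sets;
the union flag ("A") is the OR over all sets.  Library similarity is
the Jaccard index over the top-5000 most abundant unique reads of each
library, with ties broken lexicographically so the top set is
deterministic.

### Worked-example arithmetic

Mean percentages over the three libraries (e.g. mean rRNA fraction) are
computed by rounding each library's percentage to two decimals before
averaging, which is how such means are derived from a printed
categorization table; averaging raw ratios differs in the second
decimal for one category (unique rRNA: 1.35 vs 1.34).

## miRNA discovery

Candidate reads must have ≥3 copies in at least one library (guarding
against sequencing errors), match the reference, and not be
contaminant-classed.

Hairpin structure is assessed by nested base-pair maximization over
Watson–Crick and G:U pairs with a minimum loop of 3 nt — an O(n³)
dynamic program with an exhaustive-enumeration oracle in the tests —
rather than thermodynamic folding.  Two numerical choices make the
optimum well-behaved:

* among equal-pair-count structures, the DP prefers stacked pairs
  (score = 1000·pairs + stacks), so contiguous helices win ties;
* the traceback is deterministic, breaking bifurcation ties toward the
  window center.

Pure pair maximization on a 200-nt window still has degenerate optima
that can trade a genuine miRNA stem for flanking structure.  Discovery
therefore evaluates, per read occurrence: the two fixed 200-nt window
placements (read with a 20-nt 5′ flank, and mirrored), plus
*duplex-anchored* minimal windows — the best antiparallel complement
diagonals for the read (loop 3–120 nt either side) define minimal
windows spanning read + loop + implied star arm, folded with a pair
mask that keeps mature positions on the anchored diagonal band.  Among
accepted geometries the largest duplex wins, with Watson–Crick purity
as tie-break (wobble-riddled junk diagonals can otherwise tie on pair
count).

A locus is accepted when (a) ≥60% of mature positions pair, (b) the
pairs sit on one arm (the duplex is read off the majority arm as the
longest run whose step-wise bulge asymmetry stays within 4 nt — a few
stray pairs from degenerate optima are tolerated rather than fatal),
and (c) the star is computable inside the window.  The star follows
the 2-nt 3′ overhang rule; its coordinates come from the median duplex
diagonal, which is robust to a single slipped pair at a duplex end.
The reported precursor is trimmed to the hairpin extent so redundancy
removal compares precursors rather than arbitrary windows.

Conserved/novel calling: a mature within 3 mismatches of the known
catalog is conserved and kept even without star reads (well-known
miRNAs often lack a sequenced star).  An unmatched mature is novel only
if mature and star co-exist in a sequencing library; we use the
stricter same-library reading by default and expose it as the
`same_library` flag.  Precursors ≥95% identical over the shorter
length (ungapped sliding identity, inclusive boundary) merge, keeping
the locus with the highest summed mature count.  Families: conserved
loci inherit their catalog family; novel matures link single-linkage at
≤3 mismatches and are named `ghr-n1, ghr-n2, …` in discovery order.
Genomic clusters are maximal runs of ≥2 loci with start gaps ≤10 kb
(the distance is configurable; no canonical value exists).

## Differential expression

Counts are normalized to reads per million of each library's clean-read
total.  A zero raw count is reported as 0.01 RPM — the adjustment
applies to the normalized value, and only to exact zeros.  Fold change
is log₂(treatment 1 / treatment 2) of the adjusted RPMs; when both raw
counts are zero the comparison is flagged not-testable and the fold
change set to 0.  Per comparison, a Pearson χ² test (df = 1, no
continuity correction) is run on [[c₁, t₁−c₁], [c₂, t₂−c₂]] where the
tᵢ are total clean reads — the same denominator as the RPM.  Both-zero
tables return (χ²=0, p=1).  Tiers: `**` for |log₂FC| ≥ 1 and p ≤ 0.01,
`*` for |log₂FC| ≥ 1 and 0.01 < p ≤ 0.05, `ns` otherwise, boundaries
inclusive.  A Benjamini–Hochberg FDR column is emitted for modern use
but never enters the classification, which intentionally reproduces
the fixed-cutoff raw-p scheme.  Family-level expression sums member
raw counts before normalization (the only order-independent choice).
Fold changes are exactly antisymmetric and transitive
(FC(D,C) + FC(S,D) = FC(S,C)) because they derive from a single RPM
value per condition.

## Target analysis

Ungapped complementarity scoring over windows equal to the miRNA
length: Watson–Crick 0, G:U 0.5, mismatch 1, penalties doubled over
miRNA positions 2–13; sites pass with score ≤4.0, ≤2 consecutive
mismatches, and ≤1 mismatch inside positions 2–13.  These constants
follow standard plant target-prediction practice and are all exposed
as arguments.  The cleavage position is the transcript nucleotide
paired to miRNA position 10 (first nucleotide of the 3′ fragment).
Degradome validation uses an explicit, calibratable null: each of the
transcript's tags falls uniformly on one position, and the p-value is
the upper-tail binomial probability of the observed pile-up at the
cleavage position; validation requires p ≤ 0.05 plus perfect matches
at miRNA positions 10 and 11.  Because the binomial is discrete, the
achieved level sits slightly below the nominal 5% and approaches it as
tag density grows; the calibration test computes the exact achieved
level and checks the Monte-Carlo fraction against it.

## CitationRank

Documents from non-plant species are removed.  Genes join clusters by
single-linkage over a pairwise-similarity table at a configurable
threshold (connected components; cluster ids named after the smallest
member, making the output permutation-invariant).  The co-existence
matrix counts, per cluster pair, documents mentioning members of both;
the diagonal holds document frequencies.  The rank vector starts at
the document-frequency prior and iterates
r ← d·T·r + (1−d)·prior with d = 0.85 and T the column-normalized
off-diagonal matrix (zero columns teleport to the prior), for up to
1000 iterations with early stop at L1 change < 10⁻¹².  Damping and the
frequency prior are conventions of the PageRank family — the prior
encodes "frequently mentioned genes matter" — and both are arguments.
Target linkage uses a pluggable similarity (default: k-mer Jaccard
identity, k = 8) in place of an external aligner; the E-value-style
cutoff becomes a similarity threshold.

## Synthetic data

The generator emulates the study design at desk scale.  Defaults: 30
contigs × 2 kb; 24 known + 8 novel planted miRNAs (21-nt matures, 15-nt
loops, ≤2 arm mismatches placed away from duplex ends); read lengths
18–30 nt weighted toward the 21- and 24-nt classes; contaminant classes
at roughly the fractions seen in plant seedling libraries (rRNA 6.6%,
tRNA 1%, sn/snoRNA trace); 10⁵ reads per condition; a fixed 36-nt
machine read built as insert + adapter, truncated, with substitution
errors at 10⁻³ (errored bases at Q10); three libraries drawn with
generators seeded `seed + {0,1,2}`.  Planted matures are resampled if
their own fold exceeds 6 pairs — random 21-mers reach 4–8 pairs under
pair maximization, while real matures are essentially unstructured —
and planted precursors are spaced ~300 nt apart so two hairpins never
share a fold window.  Mappable background reads are sampled from
contig regions outside the planted hairpins: a background read landing
on a star arm would add abundance that masquerades as star expression
and corrupt the truth bookkeeping.  Expression follows a Zipf profile over a
permuted locus order; condition expectations are control weight ×
2^(planted log₂FC); per-source expectations sum exactly to the library
size before the multinomial draw (the background complement absorbs
the remainder).  The default fold-change plan cycles: a quarter of
loci +2 in drought, a quarter +2 in salt, one in eight −2 in both,
the rest null.  Degradome tags put 80% of 200 tags per transcript on
the planted cleavage position, the rest uniform; decoy transcripts get
uniform tags only.  The corpus plants fully-connected gene families
(similarity 0.9 within, 0.1 across) and a hub family co-mentioned with
every other family — the expected top rank.  Documents mention one to
three clusters so the co-existence matrix is not trivially stationary
at the prior.

What the generator does **not** emulate: indels and quality decay,
strand-specific sampling (reads are sense-only), A/D-subgenome
structure, genome-scale reference sizes, realistic PubMed text.
Passing tests therefore demonstrate correctness of the rules and
calibration of the statistics under the planted model, not performance
on real libraries — in particular, real hairpins fold under
thermodynamics, not pair maximization, and real degradome noise is not
uniform.

## Problem sizes

Unit and recovery tests run at 2×10⁴ reads per library (12 known + 4
novel loci, 10 contigs); the end-to-end acceptance run uses the full
default of 10⁵ reads per library.  Calibration suites use 20 seeds ×
200 miRNAs (χ² type I) and 1000 random sites (degradome null), drawn
through the generator's count-matrix fast path, which shares the
expectation model and sampling with the full read simulation.  These
sizes were chosen so every planted effect is comfortably detectable
while the whole suite stays interactive.

## Known limitations

* Pair-maximization folding is a structural proxy; loci whose true
  precursors have long loops (>120 nt) or large asymmetric bulges
  (>4 nt) fall outside the anchored-window search and the duplex
  budget.
* The χ² test inherits the single-library-per-condition design: it
  tests sampling error, not biological variance, and p-values on real
  replicates would be anticonservative.
* The degradome binomial null ignores position-specific degradation
  bias; on real PARE data the validated fraction under the null would
  exceed the nominal level.
* CitationRank's constants (damping, iteration count, similarity
  threshold) shape the ranking; only the hub-recovery behaviour is
  validated.
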