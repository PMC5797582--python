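# Methods

This note documents the models and algorithms behind each stage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Repeat detection and assembly-difficulty classes

**Model.** A "repeat pair" is two distinct loci on a replicon whose
alignment spans at least `min_length` bp (default 500) at identity at
least `min_identity` (default 0.95), in either orientation. k copies of
one element therefore contribute C(k, 2) pairs. The trivial full-length
self-alignment is excluded; pairs are reported with canonical ordering
(locus A starts at or before locus B) and inverted repeats once, not
twice.

**Algorithm.** Exact k-mer seeds (k = 21, below the shortest reportable
repeat) nominate diagonals of the self-comparison dot plot; each
nominated diagonal's match vector is processed by *anchor chaining*:
maximal exact-match runs of ≥ 8 bp are chained left to right, a chain
absorbing the next run iff the spanned window keeps overall identity ≥
`min_identity`, followed by a re-merge pass over adjacent chains (a
cumulative dip near a window's start can break the first pass even when
the full window qualifies). Windows shorter than `min_length` are
dropped; windows whose both loci are contained in a longer reported
window of the same locus pair are discarded.

The detector is deliberately *ungapped*: biological repeat copies
(IS transposition, rDNA operons) diverge mostly by substitutions, so
copies stay on one diagonal; an indel inside a repeat splits it into two
reported windows, which is also how the pair count is affected in
practice by nucmer-style tools when extension breaks. The chain criterion
(overall window identity ≥ threshold) was chosen over maximal-scoring
segments (Ruzzo–Tompa with match 1−p / mismatch −p): scoring-maximal
segments require near-threshold identity in every prefix and suffix and
therefore split a 600 bp copy pair with a local mutation cluster into
sub-threshold fragments, losing the pair. Anchors of ≥ 8 bp cannot arise
from random sequence near a window (P ≈ 0.25⁸ per position), so chains
cannot creep into flanking sequence: absorbing random-sequence runs
dilutes window identity below threshold immediately.

**Sensitivity.** A window at identity p contains an exact 21-mer unless
mismatches are spaced pathologically; at the planted mutation rates
(pairwise divergence ≤ 4%) the expected gap between mismatches is ≥ 25
bp, so seeding misses nothing (verified against the exhaustive-diagonal
oracle in the test suite). Runs of ≥ 10 Ns force a window break, and N
never matches anything.

**Classification.** `classify_complexity(n_pairs, max_len)` returns III
if `max_len` > `rdna_ceiling` (default 7,000 bp — the rDNA operon, a
bacterial genome's usual longest repeat, is 6–7 kb), else II if
`n_pairs` > `count_threshold` (default 100), else I. Both thresholds are
exposed. Circular replicons are scanned as deposited (linear); the
`rotate` option virtually doubles the sequence to catch origin-spanning
repeats and de-duplicates images modulo the replicon length.

## Gap audit

Coverage is accumulated per reference base from primary alignments only
(secondary/supplementary records would double-count contigs);
reference-consuming CIGAR operations — including deletions — count as
covered by the spanning alignment. Gaps are maximal zero-coverage runs
(gaps shorter than `min_gap_len`, default 1, are dropped). A gene is
"missed" iff it overlaps at least `min_overlap` bp (default 1) of some
gap; genes absent from the category map are "unassigned". rRNA/tRNA
features are listed but tallied outside the headline CDS/pseudogene
counts. Coordinates are 0-based half-open internally; GFF3 I/O converts
from 1-based inclusive. A BED-like per-base coverage file may substitute
for SAM.

## Pan-genome

**Clustering.** Greedy representative-based single pass in the CD-HIT
tradition, standing in for the full Roary pipeline (CD-HIT + blastp +
MCL): proteins sorted by length descending (gene-id tie-break); each
joins the first cluster whose representative it matches at ≥ 95%
identity over ≥ 90% of the longer sequence, else founds a cluster.
Identity is 1 − editDistance/max(length) from a global (NW) alignment —
a lower bound on column identity, exact for substitution-only
divergence. No paralog splitting: several members of one genome may
share a cluster. Pseudogenes are excluded from clustering. Divergence
from Roary on real data is expected; a Roary `gene_presence_absence.csv`
(full 14-metadata-column layout or slim layout) can be imported to
bypass the internal clusterer for full-scale runs.

**Partition & curves.** Row sums of the presence/absence matrix split
clusters into core (= n), unique (= 1, attributed to its genome) and
accessory (else). Accumulation curves average pan[k] (clusters in ≥ 1 of
the first k genomes) and core[k] (in all first k) over `n_iterations`
(default 10) uniformly random orderings from one seed; the k = n
endpoints are order-independent and exact.

**COG cross-tabulation.** Per gene, the best (smallest e-value,
first-row tie-break) hit with e ≤ 0.001 supplies the category letters; a
cluster is categorized via its representative. A multi-letter assignment
counts once per letter (the alternative — once per gene — changes column
totals but not the ranking of categories); "none" rows collect clusters
without a qualifying hit.

## Pseudogene GO enrichment

Six-frame translation uses the bacterial genetic code (table 11), keeps
internal stops as `*`, and translates alternative start codons as their
table-11 amino acid (transeq behavior). Domain hits are kept at
e-value **strictly below** 10⁻¹⁰; the same (query, domain) found in
several frames collapses to one record. Domain→GO mapping accepts
pfam2go-format lines or 2-column TSV; terms are restricted to one
namespace (BP by default) and propagated to all is_a ancestors
(true-path rule).

Each term is tested with the one-sided Fisher exact test — the
hypergeometric tail P(X ≥ k) for k of the term's K annotated genes
falling in the n interest genes out of N universe genes. Genes with no
annotation stay in the universe denominator. The published *elim*
decorrelation is provided instead of topGO's weight01 (whose weighting
scheme is not exactly specified): terms are processed children before
parents, and a term significant at `elim_alpha` (default 0.01) has its
annotated genes removed from all ancestors before those are tested.
Exact p-value agreement with weight01-based analyses is therefore not
expected. Raw p-values are ranked (no multiple-testing correction, since
biologically suggestive terms can sit near p ≈ 0.1 on small universes);
a Benjamini–Hochberg column is emitted for information only. Underflowed
tails are clamped to the smallest positive double so p ∈ (0, 1] always
holds.

## Metagenome read attribution

Unmapped and supplementary SAM records are dropped; secondary alignments
are kept because a report-all aligner encodes multi-target information
in them. Per read, the *set* of distinct panel genomes is formed
(duplicate hits to one genome collapse). "Proportional" attribution is
an equal 1/m split over the m genomes hit, summed per species — the
minimal reading when cross-species multi-mapping is rare; species
fractions include an "unmapped" slice. No genome-size or genome-count
correction is applied at species level. Group-exclusive counts (every
target in one group) are divided by the group's genome count to compare
groups of unequal size; uniquely mapping reads (target-set cardinality
1) give the per-strain signal. MAPQ is ignored (meaningless in
report-all mode). Mates are independent reads unless `by_fragment`
intersects their target sets.

## Synthetic generators

All randomness flows from one integer seed per spec; outputs are
byte-identical across runs. The mutation model is substitution-only,
keeping expected identities analytic (two copies mutated at rate m from
one template diverge ≈ 2m); pseudogenes are made by deleting one base at
a random internal codon — the frameshift class that dominates real
pseudogene annotations. What is *not* emulated: indel divergence,
quality-score/error profiles beyond i.i.d. substitutions, operon
structure, GC skew, mobile-element nesting, and real aligner behavior
(the toy aligner matches a read's error-free sequence exactly, so
mapping ambiguity reflects true sequence sharing only). Passing the
synthetic suite therefore demonstrates correctness of the counting,
clustering, testing and attribution logic under controlled identity
structure — not robustness to indel-rich or low-quality real data.

Default study-scale conditions: strain families of 5 strains at ~200
genes each (150 core / 50 accessory / 8 unique per strain; gene lengths
≈ N(900, 150²) bp, ≥ 90), read mixtures of 10,000 × 151 bp single-end
reads at 0.5% error. The default within-cluster mutation rate is 0.01
per copy; note that at this rate pairwise *protein* identity of cluster
members sits at ≈ 95.5%, i.e. at the clustering threshold, so partition
recovery is exercised at 0.002 (protein identity ≈ 99%), satisfying the
"within-cluster identity ≥ 95%" precondition with margin. Planted GO
inputs attach the enriched term to 80% of pseudogenes vs 10% of CDSs
(design odds ratio 36) over 12 null terms at 5–30% background rates.

## Numerical choices and degenerate inputs

* Identity comparisons use a 10⁻¹² epsilon so windows at exactly the
  threshold qualify.
* Empty inputs raise (`no sequences`, empty protein sets, empty interest
  sets); non-ACGTN characters name the offending record; malformed COG
  rows name the line.
* Tie-breaks are deterministic everywhere: clustering order (length
  desc, gene-id asc; clusters scanned in creation order), COG best-hit
  (first row at equal e-value), enrichment ranking (term id at equal p).
* Repeat pair lists are sorted by (replicon, a_start, b_start); gap and
  attribution outputs are independent of SAM record order.

## Known limitations

* The repeat detector reports indel-containing repeats as split windows;
  a gapped extension stage would merge them but is unnecessary under the
  substitution-only model the generators implement.
* The greedy clusterer is order-deterministic but, like CD-HIT, not
  transitive-closure clustering: a chain A~B~C with identity(A,C) < 95%
  follows the representative, not the chain.
* `elim` is the published decorrelation, not topGO's default weight01;
  p-values differ from weight01 output by design.
* The full-scale reproduction path (12 deposited genomes, Roary matrix
  import) is implemented but requires downloading the public accessions.
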