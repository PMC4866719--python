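# Methods

This note records the models, rules and numerical choices behind
`mitocomp`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Genome model and coordinates

Internally all coordinates are 0-based half-open; GenBank I/O converts from
the 1-based inclusive interchange convention. A feature spanning the origin
of a circular genome is stored as one contiguous feature with
`wraps_origin=True` (and emitted as a `join()` location on write) rather
than split in two, because the control region and the curation rules both
need a single contiguous span; lengths are computed modulo the genome
length. Gene labels come from a controlled vocabulary (13 protein-coding
genes, 22 tRNAs with the Leu/Ser paralogs `trnL1/trnL2/trnS1/trnS2`, two
rRNAs, `pCR`); a shipped, user-extensible synonym table absorbs the usual
GenBank annotation chaos (`COX1`/`COI`, `CYTB`/`cob`, `tRNA-Asp`, …).
Leu/Ser paralogs are resolved by anticodon when one is annotated (trnL1
decodes with tag, trnL2 with taa, trnS1 tct, trnS2 tga), otherwise by
coordinate order following the reference template. A second copy of an
isotype is suffixed in coordinate order (`trnD`, `trnD2`); because the
canonical paralog names already end in digits, duplicate copies of those
four use an underscore (`trnL1_2`).

## Curation rules

*Start assignment.* Scan consecutive triplets beginning at the first base
after the upstream gene's 3' end (or at the annotated start when the
upstream gene overlaps it, as happens downstream of an overlapping gene),
over a window of W codons. The first candidate from {ATG, GTG, TTG} wins,
except that an ATG anywhere in the window is preferred over an earlier
non-ATG candidate. W defaults to 10: large enough to cover the observed
alternative-start shifts, small enough to bound ambiguity; both W and the
candidate set are configurable. No open-reading-frame discovery is
attempted — annotations are inputs.

*Stop classification*, in fixed order:

1. **canonical** — the final in-frame triplet is TAA or TAG and does not
   overlap a tRNA;
2. **partial_T / partial_TA** — the coding span leaves one or two trailing
   in-frame bases that read `T`/`TA` and the downstream feature is a tRNA
   abutting at gap exactly 0 ("tRNA-adjacent"); noted as completed to UAA
   by post-transcriptional 3' adenylation of the mRNA — adenine residues,
   the standard polyadenylation mechanism;
3. **overlap** — otherwise; the overlap length into the downstream feature
   is recorded (the *nad4L*→*nad4* arrangement).

Decisions are deterministic and rotation-invariant; minus-strand genes are
rejected (the clitellate genomes in scope are entirely single-strand).

## Gene-order comparison

Orders are signed circular sequences anchored by rotating `cox1` first
(reversing and strand-flipping when the anchor lies on the minus strand) —
every genome in scope encodes cox1 exactly once. The breakpoint distance
counts signed cyclic adjacencies of one order absent from the other,
reading-direction-free; duplicated labels are rejected rather than paired
arbitrarily (resolve copy numbers first). Event detection is deliberately a
greedy description heuristic, not a rearrangement-distance optimizer,
because comparative studies annotate arrangements by parsimony of
description: (1) label multiset differences become duplications/losses;
(2) elements off a signed longest-common-subsequence scaffold are grouped
into maximal runs; a run that is a reversed, strand-flipped contiguous
reference block is an inversion, a single element displaced past its
reference neighbour is an adjacent swap, anything else a translocation.
Single events are recovered exactly (the synthetic round-trip holds in
1000/1000 seeded trials); composite events are best-effort and may be
described differently than they were applied. Syntenic blocks are maximal
runs contiguous and co-oriented in both orders (cyclic-aware; a block read
from the other strand still counts); when shared labels are duplicated the
computation degrades to singleton blocks rather than guessing a pairing.

## Exact R×2 conditional test

Probability-ordering two-sided Fisher test: with row totals $r_i$ and
column total $c_1$ fixed, $P(a)=\prod_i\binom{r_i}{a_i}/\binom{N}{c_1}$,
and $p=\sum\{P(\text{table}) : P \le P_{obs}(1+\varepsilon)\}$ with
relative tie tolerance $\varepsilon=10^{-7}$, the prevailing convention for
float-valued probability ties.

The enumeration is exact but implicit. Rows are split into a *left* half,
materialized per row-sum $s$ as sorted log-probability arrays with running
cumulative masses, and a *right* half whose tuples are streamed (an inner
vectorized grid plus, for the largest problems, one or two python-level
outer rows); each streamed tuple contributes the left cumulative mass below
its threshold via a single binary search, so every margin-consistent table
is counted exactly once without being visited. The split is chosen to
balance the materialized and streamed sides (cost ≈ max of the two
products) under a ~4×10⁷-element memory cap. A depth-first search with
per-suffix min/max completion bounds was considered and rejected: for the
9×658 table the bounds span ~170 orders of magnitude, so essentially every
prefix is undecidable and the search degenerates to ~10¹² visits — the same
wall that makes the classical network algorithm fail on this table at any
workspace size.

Numerics: log-binomials via `gammaln`; all masses in float64 (the largest
intermediate, $\binom{700}{350}$, is ~10²⁰⁹, far below overflow); monotone
cumulative sums keep relative error near $10^{-13}$. Agreement with a naive
full-enumeration oracle is ~$10^{-13}$ relative over hundreds of random
tables in every split regime, and ~$10^{-12}$ against an independent
network-algorithm implementation on every medium table that algorithm can
handle. Degenerate inputs: one-sided margins give $p=1$; empty rows are
dropped; results are cached per table (row order is irrelevant). Grouped
arrays are built incrementally per row sum (never as one product-sized
array), and the per-call working set is collected eagerly — the recursive
streaming closure is cyclic — so long runs of large tables hold ~1 GB
resident.

The subgroup search enumerates row subsets from largest to smallest,
calling a subset homogeneous iff its exact p-value exceeds α (default 0.05,
configurable); only maximal homogeneous subsets are reported, and subsets
of an already-accepted group are skipped (they cannot be maximal). All
maximal groups are reported, not just the expected ones: on the packaged
nine-genome aspartate table the search finds three, two corresponding to
the natural taxonomic groupings and one borderline mixed group at
p = 0.051.

The Kruskal–Wallis operation wraps the tie-corrected rank test
(df = k−1, chi-squared upper tail), provided generically because the
grouping unit for proteome-composition comparisons is a user choice.

## Codon usage

Codons are counted per CDS in frame from the curated start under the
invertebrate mitochondrial code (transl_table 5, configurable); incomplete
terminal `T`/`TA` bases are excluded by construction and stop codons are
tallied separately. GAC/GAT ratios are rounded half-up to two decimals for
presentation. The nine-genome aspartate counts ship as package data with a
loader; row subsets, group annotations and single-row augmentation
(`augment_pvalue`) support the subgroup analyses.

## Synthetic-data generator

The generator emulates the *annotation-level structure* the analyses
consume, with full ground truth:

- the 38-element single-strand circular template satisfying every stated
  clitellate constraint (pCR between trnR and trnH; trnM–rrnS–trnV–rrnL–
  trnL1 with the mid-rRNA trnV; cox2–trnD–atp8; nad4L immediately before
  nad4; atp6 immediately before trnR); the remaining placements are this
  package's fixed, editable choice, shipped as data;
- CDSs drawn codon-wise from a configurable per-amino-acid codon bias
  (default: uniform synonymous usage except aspartate at θ_GAT = 0.8, the
  leech-like bias; an `aa_weights` knob skews amino-acid composition when a
  test needs many aspartate sites), with planned start codons and stop
  classes realized exactly — partial stops only before directly abutting
  tRNAs, overlaps implemented by letting the downstream feature overwrite
  the CDS tail (with a guard so the shared bases never fake a canonical
  stop; overlaps into a CDS therefore need length ≥ 5, default 7);
- tRNAs of 60–72 nt with the isotype's standard anticodon at a fixed
  internal offset of 30 nt (no folding — structure prediction is out of
  scope); a duplication spec inserts a second copy at a stated junction
  with a stated spacer and optional anticodon substitution, the second copy
  otherwise identical to the first;
- rRNAs (742/1232 nt), an AT-rich control region (default 200 bp at 85%
  A+T), and configurable intergenic spacers (spacers upstream of a CDS must
  be codon multiples and are filled with start-codon-free sequence so the
  start scan stays unambiguous);
- default stop-class plan mirroring the published clitellate pattern: most
  genes end in partial stops at tRNA junctions, nad4L overlaps nad4 by
  7 bp.

Everything is deterministic per seed. What the generator does **not**
emulate: sequence evolution, tRNA/rRNA secondary structure, read-level
noise, strand asymmetries, or realistic nucleotide composition outside the
controlled codon bias. Passing recovery tests therefore demonstrates that
the analysis rules are implemented correctly and are mutually consistent
with the generator's realization of the same conventions — not that they
would resolve every ambiguity in real, messier annotations.

For gene-order round-trip tests the event sampler draws unambiguous single
events: the cox1 anchor is never involved, inversion spans do not cross the
anchor, and translocations move a gene by at least two positions, because a
displacement-one move *is* an adjacent swap and "recover the applied kind"
would otherwise be ill-posed.

## Problem sizes used

The shipped analyses run at the sizes the data dictates: the full
nine-genome table (N = 658) exactly, the complete subgroup search over all
502 subsets, 200 seeded round-trips per event kind, 100 random-plan
curation-recovery genomes, and a 500-table oracle sweep (R ≤ 4, N ≤ 40).
On one CPU the whole test suite runs in minutes; the nine-row exact test
itself takes on the order of 90 seconds.

## Known limitations

- Event inference is not parsimony-optimal for composite rearrangements;
  it names single events exactly and describes stacks greedily.
- Curation assumes plus-strand, single-strand genomes (true for the clade
  in scope).
- The pCR call is operational (longest non-gene span, with a positional
  flag for the trnR/trnH arrangement); length and position are the only
  criteria, with no motif or structure analysis.
- `breakpoint_distance` requires duplicate-free label sets by design.
- The exact test's memory ceiling (~1 GB working set) is tuned for tables
  up to 9×2 with N ≈ 700; much larger problems would need a smaller
  left-half cap and correspondingly more streaming time.
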