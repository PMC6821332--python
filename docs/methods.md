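# Methods

## Model and assumptions

`kmerpolish` treats the read set's k-mer spectrum as the ground truth a
draft assembly should agree with. A draft base is suspect when the k-mers
covering it are absent from the set of *solid* read k-mers, and a candidate
correction is credible when the k-mers containing the corrected sequence
are present. This works under three assumptions:

- errors in the draft are **homozygous** relative to the reads (the reads
  and the assembly represent the same haploid sequence, or a haploid
  sequence source such as megagametophyte tissue is used for a diploid
  assembly); heterozygous sites are out of scope by design and no
  allele-aware logic exists;
- read coverage is deep enough (≳15×) that genomic k-mers recur and can be
  separated from sequencing-error k-mers by a multiplicity threshold;
- errors are locally sparse: each error can be judged within a ±k window.
  Errors closer than ~2k to each other interact and may be repaired
  partially or not at all.

## Canonical hashing

Every k-mer is reduced to a strand-symmetric pair of 64-bit hashes. For a
window, polynomial hashes of the forward sequence and of its reverse
complement are computed over two independent odd 64-bit bases; the
numerically smaller forward/reverse pair is selected consistently and
finalized with a splitmix64 mixer. All windows of a sequence are hashed at
once with modular prefix sums (numpy `uint64` arithmetic is exact mod 2⁶⁴),
which is what makes counting and scanning fast in pure Python + numpy; a
scalar per-window re-hash exists independently and a test property pins
the two paths equal. Windows containing any non-ACGT character are flagged
invalid and treated as evidence-free everywhere: never counted, never
inserted, never used for or against an edit. Input is uppercased first, so
softmasking is ignored.

The string-level canonical form (lexicographic min of a k-mer and its
reverse complement) is exposed for inspection and testing; the pipeline
itself only ever compares hash pairs.

## Bloom filter

Standard bit-array Bloom filter with double hashing: probe i uses index
(h1 + i·h2) mod m, with m and the probe count h from the usual optimal
formulas for the target false-positive rate p (default 5×10⁻⁴). An
inserted k-mer can never query absent, and strand symmetry of `contains`
is inherited from the hash pair. In memory the bit array is one numpy bool
byte per bit so that insert/query are vectorized fancy-indexing; on disk
it is packed to 1 bit per bit with a small self-describing header (layout
in the README). `ExactKmerIndex` implements the same query protocol with
exact membership (zero false positives) and serves as the editing oracle
in tests.

## Counting and the coverage threshold

Counting is exact, keyed by the 128-bit hash pair: all window hashes are
collected (in ~4 Mb batches to bound memory) and reduced with `np.unique`.
The collision probability between two distinct k-mers is ~2⁻¹²⁸·(pairs),
i.e. irrelevant below ~10¹⁵ distinct k-mers; tests verify agreement with a
literal string-dictionary count. Reads are concatenated with `N`
separators so no window spans a read boundary. Qualities and pairing are
ignored.

The automatic threshold picks the first interior minimum of the
multiplicity histogram (first m ≥ 2 with h[m] ≤ h[m−1] and h[m] < h[m+1]),
the valley between the error mode at multiplicity 1–2 and the coverage
mode near read depth. The upstream tool this emulates does not publish its
selection rule, so this heuristic is our own; with no interior minimum
(single-mode histograms, e.g. error-free reads) it falls back to c_min = 2
with a logged warning.

## Editing procedure

One 5'→3' pass per contig. Window presence is evaluated in vectorized
blocks of 8192 windows; a block is re-evaluated from the edited sequence
after each accepted edit, so stale evidence is never used. At an absent
window, the window's 3'-end base i is scrutinized:

- **attempt threshold**: among the d valid windows covering base i
  (clipped at contig ends), at least ⌈d/x⌉ must be absent (default x = 5,
  i.e. 5 of 25 at k=25). The divisor semantics mean *larger* x attempts
  more edits.
- **candidates**: the three alternate bases at i (fixed A<C<G<T order);
  deletions of 1..5 original bases at i; insertions of 1..5 bases before
  i. Insertion strings are enumerated exhaustively for lengths 1–2 and by
  prefix extension beyond (only anchored prefixes grow — a correct partial
  insertion always makes the k-mer ending at its last inserted base
  genomic, so the correct string is always reachable while the search
  stays near-linear).
- **anchor**: a candidate is only scored if the k-mer ending at the
  changed base, with the change applied, is itself present. Without this,
  regions where many genomic k-mers fall below the coverage threshold
  (most visibly the first/last ~read-length bases of a linear replicon,
  which uniform read sampling under-covers) let arbitrary candidates
  reach the lax support threshold, and the scan can keep inserting junk.
- **accept threshold**: ≥ ⌈d'/y⌉ of the d' valid windows containing the
  change must be present (default y = 9, i.e. 3 of 25 at k=25).
  Substitutions are scored on the k covering windows, deletions on the
  k−1 junction-spanning windows, insertions on the k+L−1 windows touching
  inserted bases.
- **ranking**: qualifying candidates are compared on support *fraction*
  (n_support / d', since the classes have different window counts), ties
  going to substitution, then deletion, then the shorter edit, then
  lexicographic bases. Strict class precedence (substitutions always
  pre-empting indels) was tried first and rejected: at true indel
  junctions a wrong substitution with exactly-threshold support (~3 of 25)
  regularly pre-empted the correct indel repair (support ~24), splitting
  one error into a wrong-substitution + compensating-indel pair at ~5% of
  indel sites at k=25. Fraction ranking removed essentially all of these
  while leaving unambiguous sites untouched.
- **resume**: after an accepted edit the scan continues so that the next
  scrutinized base is the one following the edit; edits are emitted at
  strictly increasing original-draft coordinates, which guarantees the
  change log applies deterministically and contains no duplicate
  positions.

Edit positions are 1-based on the *original* draft (maintained through a
running indel offset); internal coordinates are 0-based half-open.

## Synthetic data

The generator emulates the controlled benchmarks this kind of tool is
validated on: a uniform-random genome at a chosen GC (default 0.5);
substitution and indel site counts Binomial(L, rate) with rates up to
0.01; indel lengths uniform on 1..5, insertions and deletions equally
likely; an optional minimum spacing between sites (the experiments here
use > 2k so errors are isolated); Illumina-like reads of fixed length
drawn uniformly from both strands with substitution errors only. It does
not model real-data features: coverage is uniform (no GC bias), the genome
has no repeats, errors carry no quality signal, and reads have no indel
errors. Passing tests therefore demonstrate the algorithm's correctness
under its own assumptions, not performance on repeat-rich or biased real
genomes, where recall on repeated sequence and threshold selection under
uneven coverage would both degrade.

## Evaluation

An edit is a true positive only if (a) an unmatched truth mutation of the
compatible class lies within a positional window (0 for substitutions, 5
for indels; a truth insertion is reverted by an edit deletion and vice
versa) and (b) applying that single edit to the draft locally reproduces
the truth sequence (15 bp of flank on each side). The apply-and-compare
criterion accepts position-shifted but sequence-equivalent indels (e.g.
inside homopolymers) and rejects coordinate coincidences. Matching is
greedy nearest-first; unmatched edits are false positives, unmatched truth
mutations false negatives; recall = TP/(TP+FN), FDR = FP/(TP+FP) (0 when
no edits). Repairs split across two adjacent edits (possible for >5 bp
events) are not credited, so reported recall is conservative.

## Problem sizes and defaults

The headline numbers (`scripts/acceptance.py`, mirrored by the acceptance
tests) use the package's standard study conditions: 1 Mb genomes,
substitution and indel rates 0.001 with > 2k spacing, 150 bp reads with
0.5% base error at 20× (k=25) and 30× (k=45), filter FPR 5×10⁻⁴, leniency
defaults x=5, y=9, max indel 5. A 1 Mb genome carries ~2000 planted errors
— enough for percent-level recall/FDR estimates — and one polishing run
completes in about 1.5–2 minutes on a single CPU; the script averages
three runs per quantity. The Bloom FPR measurement inserts 10⁶ distinct
canonical 25-mers into a filter sized for 10⁶ at p=5×10⁻⁴ and probes 10⁶
disjoint ones.

## Known limitations

- Bases within k−1 of a contig's 5' end are never scrutinized (the
  scanner only edits 3'-end bases of complete windows), and contig-edge
  regions under-covered by reads are effectively uneditable; both effects
  are negligible at chromosome scale but visible on very short contigs.
- Errors spaced ≤ 2k apart interact; the single-pass scanner may repair
  only one of a close pair. Iterative multi-k runs (chaining `polish`
  outputs) recover some of these.
- Heterozygous variants, gap filling, misassembly detection and variant
  genotyping are out of scope.
- The counting stage holds all distinct k-mer hashes in memory (~16 bytes
  per distinct k-mer plus transient sort buffers), which is fine to a few
  hundred million k-mers but is not a streaming sketch.
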