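# Methods

## Model

An S-gene allele is modelled as a linear cassette

```
flank5 – x – TRD1 – y – central – x – [z –] TRD2 [– z] – y – flank3
```

over {A,C,G,T}. The x/y (optionally z) classes are short direct repeats
(defaults 37/49/14 bp; alternative presets 27/53/14 and 21/19 bp) acting as
recombination substrates; the central region is a tandem repeat
(12-bp unit `CACAGAATTAAA`, copies 2–6, or 24-bp unit
`CAGTGTCGGCTCGCCGAACTTGAG`, copies 0–4). Six event classes operate on this
architecture: TRD substitution, cross-position movement, deletion to one
TRD, duplication to three TRDs, central-copy-number change, and inter-locus
sharing. All coordinates are 0-based half-open internally; GFF3 output is
the single 1-based seam. Alleles are analysed in their given orientation —
no reverse-complement search.

## Direct-repeat detection

Hamming model, no indels: a window (i, j, L) is *valid* when
`hamming(s[i:i+L], s[j:j+L]) <= frac*L` and `L >= min_len` (defaults
`min_len=12`, `frac=0.1`), *maximal* when no other valid window contains
both of its copies, and *reported* when the copy gap is at least
`min_separation=50` (near-tandem runs belong to the tandem detector).
Implementation is seed-and-extend on exact k=6 seeds: a minimal valid
window (L=12, one mismatch allowed) is only guaranteed to contain an exact
run of ceil(11/2)=6, so k=6 is the longest seed that cannot miss a valid
window; k=8 could. The binding contract is equality with a brute-force
all-pairs oracle, which the suite checks on 100 random sequences.

`min_len=12` admits the smallest repeat class in scope (14 bp) with margin
while keeping the expected count of chance ≥12-bp exact pairs in 1 kb of
random DNA far below one. With a nonzero mismatch budget, maximal windows
legitimately absorb a few flanking context bases (the budget grows with L);
analyses that need exact repeat boundaries therefore run the detector at
`frac=0`.

## Tandem repeats

Exhaustive period/phase scan over unit lengths 6–60: copies accrete while
each stays within `frac*unit` mismatches of the first copy; score =
copies × unit length, ties to the smaller unit then the leftmost start;
the reported unit is the column consensus of the copies. When a flank base
happens to extend the phase, the reported unit is a cyclic rotation of the
planted one — unit *length* and copy number are rotation-invariant, and
those are the quantities consumed downstream.

## Family-level architecture inference

Per-allele pair detection cannot segment every allele: a deletion product
contains single x and y copies (nothing pairs within the gene), and an
allele whose two TRDs are identical merges its x and y pairs into one long
repeat. The family annotator therefore (1) detects and classifies pairs per
allele at zero mismatch tolerance, (2) takes the modal copy sequence per
class, requiring support from ≥ 2 alleles (chance pairs are
allele-private), and (3) locates exact copies of each class consensus in
every allele. The ordered class string is matched against the recognized
layouts (X Y X Y; X Y X Z Z Y; X Y X Z Z Z Y; X Y; X Z Z Y) — a
table that is data, not code, and extensible. TRD slots are the intervals
strictly *between* flanking repeat copies: repeat bases belong to the
repeat. Unmatched class strings raise a typed error carrying the pair list
so callers can fall back to the dotplot screen.

## Domain clustering

Global alignment (match +1, mismatch −1, gap open −2, gap extend −0.5,
Biopython PairwiseAligner; a length-L gap costs 2 + 0.5(L−1)); identity =
identical columns / alignment length; symmetry is enforced by aligning the
lexicographically sorted pair, since co-optimal alignments can differ in
identity. Single-linkage at 0.8 identity: movement copies domains
near-verbatim (≈1.0 at zero noise, ≈0.98 at the 1% decay the suite
exercises), while distinct domains sit ≤ ~0.75. Single linkage is the
faithful choice for verbatim copying; chaining is monitored by a
min-intra/max-inter identity diagnostic in the pipeline manifest. Labels
are assigned in order of first appearance after a canonical (seq_id,
position) sort, so the labelling is permutation-invariant. Partial TRDs
below half the median length are excluded and reported.

## Event calling

From the label–position matrix (rows = alleles, columns = slot indices):

- **MOVEMENT**: a label at both positions 1 and 2 among ≥2-TRD alleles of
  one locus. Single-TRD alleles and third slots are excluded — a deletion
  product re-indexed to slot 1, or a duplicated slot 3, would otherwise
  fake cross-position sharing that its own call class already explains.
- **INTER_LOCUS_SHARING**: a label at ≥ 2 loci. Reported separately from
  MOVEMENT; the caller does not adjudicate whether cross-position sharing
  arose as one intra-locus event or two inter-locus ones.
- **SUBSTITUTION**: ≥ 2 labels at one position after setting aside labels
  already explained as movement (cross-position) or sharing (cross-locus).
- **DELETION**: a single-TRD allele whose domain recurs in 2-TRD alleles at
  the locus — distinguishing a collapse product from a genuinely
  single-TRD family.
- **DUPLICATION**: any three-TRD allele.
- **CENTRAL_COPY_CHANGE**: ≥ 2 distinct central copy numbers at a locus.

The spacer model maps central copies c to a recognition-site spacer
`ref_spacer + (c − ref_copies) * spacer_per_copy`; the EcoR124I
calibration (2 copies → N6, +1 N per copy) is the only experimentally
anchored instance, and predictions beyond the observed copy range are
extrapolations.

## Tree mixing statistic

Distances d = 1 − alignment identity; neighbor joining (scikit-bio, taxa
canonically sorted, negative branch estimates clamped to zero); position
states (slot indices) on the leaves; the statistic is the minimum number of
state changes by Hartigan's small-parsimony algorithm, exact for arbitrary
node degrees. Score 1 ⇔ the positions form two clean clades; ≥ 2 ⇔ mixing.
Zero-length internal branches are collapsed into polytomies before scoring:
distance data cannot order splits along a zero-length edge, and an
arbitrary binary resolution can make a moved (identical) copy look like a
clean clade boundary. This replaces Bayesian tree estimation deliberately:
the downstream readout is the qualitative separated/mixed contrast, not
posterior support, and NJ keeps the pipeline deterministic and fast.
Bootstrap values and posteriors are out of scope.

## Dotplot screen

Maximal exact diagonal runs ≥ `word_size=10` (forward strand only), all
allele pairs. A pair is flagged when ≥ 50 bp of a run lies inside TRD slot
i of one allele and slot j ≠ i of the other at the same alignment offset —
the automatable core of a manual dotplot curation; it corroborates, rather
than replaces, the matrix-based caller.

## The simulator and what passing tests mean

`simulate_family` emulates the study conditions, not population genetics:
no coalescent, no selection, no within-repeat divergence by default.
Choices that matter:

- **Clonal start per locus.** Each locus begins as identical copies of one
  ancestral allele (ancestral TRD pairs disjoint across loci); all
  diversity is injected, so every signature in the output is attributable
  to a logged event, which is what makes precision/recall exactly
  computable.
- **Substitution as import.** Under a clonal start, copying a TRD between
  identical alleles is a no-op, so SUBSTITUTION installs a pool domain not
  yet present at the locus (donor logged as `pool:<label>`) — the minimal
  mechanism giving the observed standing diversity at a position.
- **Position-structured pool.** Pool domains descend from a TRD1-type or a
  TRD2-type subfamily ancestor (~0.72 identity within a subfamily,
  rejection-capped below 0.78; < 0.60 across; 400 bp each — a typical
  Type I TRD scale, as no canonical length exists). Real repertoires are
  position-structured in exactly this way, and it is what makes
  substitution-only trees separate TRD1 from TRD2: with a fully unrelated
  pool, singleton imports at opposite positions attract each other under
  NJ at saturated distances. `pool_subfamilies=False` restores the fully
  unrelated pool (every pair < 0.60).
- **Maximal repeat embedding.** Boundary bases are fixed (x starts G/ends
  T, y starts T/ends G, z starts/ends T; TRD edges cycle A/C/G; flank
  edges avoid the central unit's edges) so that a repeat copy's neighbour
  base always differs between copies and a zero-tolerance detector reports
  exactly the class lengths, for any seed.
- **Signature-preserving planner.** Event placement respects constraints
  (structural events only hit alleles with no prior event; a moved or
  shared ancestral label is not also the background of a substitution at
  its home position) so that injected events remain individually
  recoverable. Replay of the logged plan reproduces the emitted FASTA
  byte-identically.
- **Mutations last.** Point mutations (default rate 0) are applied after
  all events and, with `preserve_repeats` (default), never inside repeat
  copies, the central region, or the bases adjacent to them; disabling it
  exercises near-exact matching instead.

Consequently, green recovery tests show the inference machinery is exact
under its own model's assumptions — near-identical repeat copies, verbatim
domain copying, pre-oriented alleles. They do not certify performance on
decayed natural repeats, indel-containing copies, or partially deleted
genes beyond the half-length exclusion rule.

## Problem sizes and numerical choices

The validation suites use 2 loci × 6 alleles (~1.3–1.7 kb per allele),
100 seeded replicates for event recovery and for the mixing signature, and
100 random ≤300-bp sequences for detector/oracle equivalence — sizes at
which the brute-force oracles are exhaustive yet the whole suite runs in
about a minute. Ties are broken deterministically everywhere (documented
per operation); floating-point mismatch budgets use a 1e-9 slack;
`evaluate_calls` reports undefined ratios as null rather than zero, and
translates cluster labels (an arbitrary bijection of pool labels) through
the truth log before matching.
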