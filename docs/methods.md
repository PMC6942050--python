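# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `acrodj`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and sequence conventions

All coordinates are 0-based half-open, everywhere; BED is written natively in
that convention.  Sequences are uppercase over {A,C,G,T,N}.  N marks
gap-filled or unresolved bases: columns opposite an N are excluded from both
numerator and denominator of every identity and distance, in both identity
modes, because an N column carries no information about variation.

## Pairwise alignment

`global_align` minimises unit-cost edit distance exactly (bit-parallel
Myers DP via edlib) when the query×target cell area is at most
`DEFAULT_DIRECT_AREA` (2 kb × 2 kb).  Larger inputs are aligned by
anchor-chain-then-fill:

1. **Anchors** are k-mers (k = 21) occurring exactly once in each sequence,
   merged along diagonals into maximal exact segments.
2. **Chaining** maximises total anchored length over collinear segments
   (quadratic DP over merged segments, leftmost tie-break, deterministic on
   repeat-rich input).  Segments overlapping by a few bases — chance
   extension of an anchor across an indel edge — remain chainable, scored
   net of the overlap, and are trimmed on emission.
3. **Gap fill** between consecutive anchors uses an affine-gap Gotoh DP
   (match 0, mismatch 2, gap open 3, gap extend 2 in doubled units) up to
   64 M cells, and exact unit-cost DP beyond that.

The affine fill is a deliberate departure from strict parsimony: a unit-cost
optimal path *provably* scatters a long indel through coincidental matches
whenever a substitution falls near its breakpoint (the scattered and the
contiguous placement are co-optimal or the scattered one is cheaper), which
destroys breakpoint identity between carriers of the same event.  The light
affine penalty keeps near-unit-cost behaviour while preferring one contiguous
gap.  Consequently `edit_distance` of an *anchored* alignment can slightly
exceed the true minimum; the exactness guarantee holds for the direct (small
input) regime, which is what the DP-oracle equivalence test checks.

Alignments are computed in a canonical orientation of the two inputs and
transposed as needed, so substitution and indel counts are symmetric in the
pair by construction (co-optimal paths otherwise allow
substitutions(a,b) ≠ substitutions(b,a)).

Two identity modes: `substitution_only` = 100·m/(m+x) (the default — a
"k nucleotide differences over L" statement corresponds to this convention)
and `blast_like` = 100·m/(m+x+indel bases).

`window_identity` tiles the reference with non-overlapping windows by default
(step configurable; a final partial window is kept when at least half a
window wide) and reads per-window identities off **one** global alignment per
query rather than re-aligning every window: for collinear contigs this is
equivalent, much faster, and deterministic.  Windows with no aligned columns
for a query are recorded as missing (NaN), never zero.

Anchorless pairs fall back to exact DP while the problem fits in memory
(≤ 256 M cells); beyond that `UnalignableError` distinguishes a failed
localisation from a low-identity success.

## Satellite, inverted-repeat and insert annotation

**Period estimation**: for every position whose k-mer (k = 12) recurs
downstream within `max_period` (2000 bp), the distance to the nearest
recurrence is recorded; the period is the mode of that distribution, accepted
when it covers ≥ 30% of recorded distances and at least 10 of them (the
count floor stops a handful of chance recurrences in aperiodic sequence from
looking periodic).  The estimator is exact on perfect arrays, robust to 1–2%
monomer divergence, invariant to rotation, and returns an integer period
directly — the reasons it is preferred over FFT autocorrelation here.

**Satellite blocks** are maximal runs of periodic positions (merged across
gaps ≤ 500 bp, minimum block 1 kb, end extended by k to cover the final
k-mer's width).  Each block carries a majority-vote monomer consensus and the
mean monomer identity to it.  The trailing ~one monomer of an array is
inherently unmarked (its k-mers have no downstream copy), so block ends
undershoot by up to about one period.

**Inverted repeats** come from k-mers (k = 21, odd, so no k-mer is its own
reverse complement) whose reverse complement also occurs uniquely in the
contig; pairs merge along anti-diagonals and chain with arm 1 increasing and
arm 2 decreasing.  Satellite blocks are masked (N) before anchoring —
palindromic monomer content otherwise litters the anti-diagonal — and arm
identity is then computed on the *unmasked* sequence by aligning arm 1
against the reverse complement of arm 2.

**Foreign inserts** are structural, not homology-based: (a) a gap between two
same-period blocks (a long insert splits the array during block finding),
reported with the merged outer block as host; (b) an aperiodic or
low-monomer-identity (< 60%) run ≥ 500 bp strictly inside a block.  An insert
that is itself tandemly repetitive with period ≤ `max_period` is not
detected — a known limitation.  Identity between inserts of different
contigs (the "identical integrations within a group" check) is delegated to
ordinary pairwise alignment of the insert sequences.

## Indel markers and exchange inference

Indel calls (default minimum 50 bp — below that, alignment ambiguity in
repeat-rich sequence makes breakpoint identity unreliable) are
left-normalized: a deletion shifts left while `ref[pos-1] == ref[pos+len-1]`,
an insertion rotates its inserted string; normalization is idempotent.
Reference flanks (30 bp each side) are extracted after normalization.

Markers require **exact** agreement of type, length and both flank strings;
near-identical flanks are reported separately as candidates
(`candidate_matches`), never merged silently.  Absence in the presence matrix
is verified (the query aligns across the locus), otherwise the entry is
missing and excluded pairwise — never imputed.

The exchange argument is formalised as the four-gamete condition under an
infinite-sites-style assumption (each indel arises once, no recurrence):
all four joint patterns across non-missing chromosomes ⇒ at least one
exchange between the loci.  Adjacent-marker intervals are classified
exchange_required/linked; the minimum number of exchanges is the greedy
left-to-right disjoint-interval count (a valid lower bound); and an exchange
adjoined by a homogeneous shared block > 1 kb (the conventional upper limit
of noncrossover gene-conversion tracts) is classed CO, else NCO_possible.
The adjoining block is measured as the longest run of linked intervals
immediately left or right of the exchange.

Indel scanning is a proximal-region analysis: the shared indels of interest
live in the conserved proximal ~300 kb, while the satellite array aligns
ambiguously between divergent groups and yields noise calls there.  The
pipeline calls indels genome-wide but ground-truth comparisons (and sensible
use) restrict markers to reference positions before the satellite array.

## Grouping

Distances are substitutions per aligned site over a region — whole contigs or
the terminal tail (default 100 kb, the region where windowed identity drops
below ~90%); contig ends coincide, so terminal mode aligns the two suffixes
directly.  The published analysis used an MSA-based relationship tree; here
pairwise distances + average linkage (UPGMA) replace it because the distances
are already computed and the tree method is then fully specified.  Labels are
sorted before clustering, making the partition invariant to input order.
k is a user choice (no automatic model selection: the three published groups
are explicitly not a definitive population description).  A threshold cut is
cross-checked against single-linkage connected components of the distance
graph; disagreement signals non-ultrametric structure and raises rather than
silently picking one answer.  Neighbor joining (dendropy) is offered for
display only; a k-cut is not well defined on an unrooted NJ topology.

## rDNA/DJ junction

The junction is defined operationally as the end of the maximal ≥ 99%
identity terminal match between a contig end and a user-supplied rDNA
reference segment; its reference-side coordinate is reported as an offset
into that reference, never hard-coded, because rDNA coordinate systems
differ between references.  Numerically, edit-optimal infix alignment cannot
pin the junction — with non-rDNA sequence in the window, co-optimal paths
smear stub-tail matches into the junk — so the implementation anchors with
unique shared 21-mers, takes the rightmost anchor's diagonal (a chance
21-mer match beyond the junction has probability ~4⁻²¹ per position), and
walks that diagonal with +1/match, −3/mismatch; the score peak is the
junction.  When the terminal stub base itself is substituted, the reported
junction retreats to the last matching base — the true boundary is then
unknowable from sequence.  Contigs are tried in both orientations; reverse
calls report mirrored coordinates.

Far-distal homology blocks cluster unique-k-mer anchors by diagonal
(tolerance 200 bp, chain gap ≤ 5 kb) on both strands, re-align each cluster's
spans for an identity estimate, and report reverse-strand blocks in forward
target coordinates.  Gaps on the target between consecutive collinear blocks
in excess of the query-side gap are candidate internal deletions.  The
default `min_identity` of 85% is chosen to admit the weakest reported
far-distal homology class (~86–87%) while excluding noise.

## Synthetic cohort generator

The generator emulates the study conditions, not their mutational history:

* **Architecture** (desk scale, ~62 kb): 4-kb rDNA stub copied from the end
  of a bundled *synthetic* IGS-like segment (no real rDNA sequence is
  bundled; the segment's end defines the junction), 15-kb unique, 5-kb IR
  arm, 2-kb spacer, reverse-complement arm, 14-kb unique, 5 040-bp satellite
  of a random 48-bp monomer, 12-kb tail.  The paper-scale preset uses 100-kb
  arms, a ~40-kb satellite and a ~400-kb total, with the three shared
  deletions at the 110/161/172-kb reference positions.
* **Substitutions** are per-site Bernoulli with a uniform choice among the
  three alternative bases (no transition/transversion bias: only percent
  identity is modelled).  The proximal rate (default 0.005/bp per member,
  applied over the whole contig) reproduces the ~99% proximal pairwise
  identity; the distal rate (default 0.05/bp) is drawn **once per group
  lineage** over the distal region (satellite start onward), reproducing
  both the below-90% between-group distal identity and the high
  within-group tail identity.  Drawing distal substitutions independently
  per member could not produce group structure at all, since distances count
  substitutions only; the rates are tuned to the qualitative identity
  gradient, not to any published mutation rate.
* **Shared indels and inserts** are applied on the ancestor coordinate
  system before substitutions, guaranteeing identical breakpoints and
  identical insert sequences within a group by construction — mirroring the
  observation rather than simulating its origin.
* **Exchanges** are single-crossover suffix transfers between realized
  lineages, represented as piecewise source mosaics.  The default preset's
  recombinant lineage uses two sequential transfers (into a group-1 lineage
  between markers A and B, back to a group-3 lineage after marker C) because
  a carrier of all three markers that still groups with group 3 by its tail
  is not reachable with one crossover.
* **Determinism**: one `SeedSequence` spawns independent streams per group,
  member and event, so identical (spec, seed) gives byte-identical cohorts;
  preset seeds are fixed (fig2d: 42, minimal: 7).  The manifest records
  every realized event and the mosaic structure; replaying it on the
  ancestor reproduces each member exactly, and post-exchange marker carriers
  and group identities are derived from the mosaic.

What the generator does **not** emulate: read-level errors and coverage,
coalescent genealogies, satellite higher-order repeat structure,
transition/transversion bias, indel formation mechanisms, and mutation of
inserted sequence after insertion.  Passing tests therefore demonstrate
correct recovery of planted structure under these idealised conditions, not
performance on raw sequencing data.

## Problem sizes and defaults

The test suite and the worked example run the ~62-kb desk-scale preset
(seven members; full pipeline in a few seconds per stage); the ~400-kb
paper-scale preset exercises 100-kb arms and printed marker positions and is
used for spot checks.  Alignment thresholds: direct exact DP ≤ 2 kb × 2 kb,
affine gap fill ≤ 64 M cells, anchorless fallback ≤ 256 M cells.  The
acceptance script's exchange-interval computation is exact and runs in
seconds.

## Known limitations

* Identity from anchored alignments inherits the anchor chain: on extremely
  repetitive input with no unique k-mers the pair is unalignable rather than
  approximately aligned.
* Marker matching demands exact flank equality; a substitution inside a
  30-bp flank of one carrier splits a marker into a candidate pair rather
  than merging it.
* Between-group alignment of satellite arrays is inherently ambiguous;
  indel calls inside satellites are noise and should be excluded by
  position (see above).
* `estimate_period` reports a single dominant period per block; nested or
  higher-order periodicities are not decomposed.
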