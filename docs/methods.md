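# Methods

## Consensus assignment model

Each mapped pseudoread carries a set of distinct database hits; repeated
placements within one entry collapse, because entry identity is what
carries taxonomy, and no alignment-score weighting is applied. Lineages are
canonicalized onto the seven classical ranks (domain, phylum, class, order,
family, genus, species) by position: the first seven lineage segments fill
the ladder top-down, overflow segments are joined into the species slot,
and lineages shorter than seven ranks simply leave the deep ranks absent.
Absent ranks are never padded with placeholders, so a placeholder can never
win a consensus; they do remain in the denominator at every rank, diluting
the vote of the hits that are present.

Assignment scans species → domain and stops at the first rank where one
term's hit fraction strictly exceeds the threshold θ (default 0.60). The
strict inequality matters: a 3-of-5 agreement (exactly 60%) escalates.
`ConsensusParams.strict=False` switches to ≥ for sensitivity analyses.
Single-hit reads bypass the scan and take their entry's taxonomy directly;
this is identical to the general rule for any θ < 1 and remains well
defined at θ = 1. If θ < 0.5 several terms can pass at one rank; the most
frequent wins, ties breaking lexicographically. The reported ancestry above
the winning rank is the most frequent full ancestor tuple among the
supporting hits, ties again lexicographic on the ';'-joined string, so the
whole pipeline is deterministic.

Reads with no consensus at any rank are reported in the reserved `unknown`
domain. The per-batch rank summary is cumulative (fraction assigned at a
rank *or deeper*); by construction the domain-or-deeper fraction plus the
unknown fraction is 1.

## Abundance, filters, background subtraction, CV

A read contributes to taxon *t* at rank *r* iff it was assigned at *r* or
deeper with term *t* at *r*. The relative-abundance denominator is the
total number of mapped reads (assigned at any rank plus unknown), constant
across ranks, which keeps abundances comparable across ranks and across
profiling methods; this is a deliberate design choice where alternatives
(per-rank denominators) exist.

The detection filter keeps taxa with ≥ 2 reads **and** relative abundance
≥ 0.01%, both bounds inclusive. Background subtraction operates on
relative abundances, not counts, because sequencing depths differ between
samples; differences are floored at zero by default (negative abundances
are meaningless; an `allow_negative` flag exposes the raw differences).
Sample taxa floored to zero are kept — they were detected — while
background-only taxa are dropped. Adjusted read counts are bookkeeping
only: the adjusted fraction re-scaled to the sample's depth, rounded
half-up.

CV analysis filters every table first, restricts to taxa surviving in all
tables, and reports sample standard deviation (n−1) over mean. Identical
values short-circuit to exactly 0 rather than accumulating float noise.
Welch's unpaired t-test (Welch–Satterthwaite degrees of freedom, two-sided
p) compares CV sets between methods; the degenerate case of zero variance
in both groups is defined as p = 1 for equal means and p → 0 otherwise.

## Diversity and sequencing cost

The Shannon–Wiener index is computed in bits (log base 2, matching the
implementation convention of the tools this workflow descends from; the
base is a parameter since the classical definition uses ln). Counts are
sorted before summation so the same count multiset always yields a
bit-identical index.

Rarefaction subsamples the mapped-read (assignment) records without
replacement — not taxa — at each depth, with k = 5 independent draws per
depth by default; reads assigned shallower than the tabulation rank, or
unknown, occupy subsample slots but contribute no taxon. Richness may
optionally be filtered at the rarefied depth with the detection filter.
The default depth grid is log-spaced with ten points per decade starting at
10; the final depth is the total mapped-read count rounded *down* to two
significant digits. The saturation depth is the smallest tabulated depth
whose mean richness reaches 95% (inclusive) of the mean richness at the
deepest point — normalization is to the curve's own endpoint, so the
endpoint always qualifies. Estimated sequencing cost divides a mapped
depth by the method's mapping rate (mapped/sequenced).

All subsampling uses numpy's seedable PCG64 generator; the seed and k are
echoed in the rarefaction output.

## Pre-processing contracts

Pair merging, end trimming and length filtering implement documented,
deterministic contracts with the workflow's parameter values (maximum
overlap 250 bp, Q30, minimum 50 bp) rather than replicating any external
tool bit-for-bit; downstream consensus assignment does not depend on
tool-exact trimming. Merging reverse-complements the second mate, scores
every candidate overlap by mismatch fraction (N positions are not counted
as mismatches; the denominator is the overlap length), accepts ratios
≤ 0.25, and prefers the lowest ratio, ties to the longest overlap. Merged
qualities take the max (capped at 41) at agreements; disagreements take
the higher-quality base with its own quality, the first mate winning ties.
Trimming strips sub-threshold bases from both ends only, leaving interior
dips untouched — a simpler rule than windowed trimmers, chosen because it
is idempotent and easily verified. Pairs with no acceptable overlap are
dropped by default (`keep_unmerged` carries both mates forward singly).

## Synthetic data: what it emulates, what it does not

The simulator reproduces the *statistical structure* of a Latin-square
spike-in experiment, not its sequences. A fixture taxonomy nests genera
two-per-family (two families per order, and so on) in contiguous blocks
per domain, so clades never straddle domains. Spike-in designs place six
species (three per domain by convention) at decade-spaced concentrations,
default 1e4–1e9 cells per gram as in the benchmark this workflow targets,
with each row and column of the square a permutation of the dose indices,
plus one un-spiked background sample. Reads are simulated at the
*alignment level*: a read's source species is drawn with probability
proportional to cells × rRNA copy factor, and its hit set is the true
entry plus up to `max_extra` same-genus (then same-family) entries, each
accepted with probability `p_extra`, plus optionally one cross-domain hit.
The per-cell copy factor default for the eukaryotic domain in the examples
is 5, a stand-in for the observation that fungal cells carry more rRNA
than bacterial cells — it is a parameter, not a measured claim.

Because no sequence-level error, chimera or alignment-ambiguity model is
attempted, passing tests demonstrate the correctness of the consensus,
filtering and diversity machinery under controlled multi-mapping — they do
not certify recovery accuracy on real stool data against a real reference
database. The read-length specificity analysis is likewise a
property-level analogue: fixture sequences are conserved/genus/species
block mosaics (120/60 bp), "mapping" is exact substring containment, and
only the qualitative rise of genus-assignability with fragment length is
meaningful, not any particular length threshold.

## Problem sizes and numerical choices

Default test and example sizes — 48-entry reference fixtures, 10⁴–10⁵
simulated reads, 5 rarefaction iterations — are chosen so every analysis
that matters statistically (binomial recovery bounds, rarefaction SDs) is
comfortably resolved while the whole suite runs in seconds to a couple of
minutes on one core. Ground-truth recovery is asserted within 3 binomial
standard deviations at 10⁵ reads. All randomness flows from explicit
seeds; batch assignment, table construction and all writers are fully
deterministic, with every tie-break defined above.

## Known limitations

* No alignment-score weighting, Bayesian reassignment or per-base
  placement; hit identity is the only evidence used.
* Positional lineage canonicalization is a pragmatic choice for
  variable-depth taxonomies; rank-map-aware parsing of real SILVA exports
  is out of scope.
* Background subtraction and CV operate on relative abundances and are
  sensitive to compositional effects; no CLR or other compositional
  transform is offered.
* Rarefaction richness at small depths is biased low by sampling, as
  always; only comparisons at matched depths are meaningful.
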