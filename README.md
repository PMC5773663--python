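# metrs

Consensus taxonomy profiling of total-RNA (rRNA) shotgun sequencing data.

Shotgun sequencing of total RNA from a microbiome sample yields reads that
are mostly ribosomal RNA from every domain of life — bacteria, archaea and
eukaryotes (fungi) alike, with no PCR amplification step to bias the
composition. The catch is that rRNA is heavily conserved, so a read aligned
against a full-length rDNA reference (e.g. SILVA) typically matches many
entries at once, and standard metagenomics or amplicon classifiers either
discard such reads or place them arbitrarily. This package is for
microbiome researchers who want to turn those multi-mapped rRNA reads into
kingdom-agnostic taxonomic profiles, and to benchmark how well a profiling
protocol recovers a known community.

## The consensus assignment algorithm

Let a read have $n$ distinct database hits with lineages over the ordered
ranks domain $\prec$ phylum $\prec \dots \prec$ species. Scanning from
species up to domain, the read is assigned the first (deepest) rank $r$ at
which some taxonomic term $t$ satisfies

$$\frac{\#\{\text{hits with term } t \text{ at rank } r\}}{n} > \theta,
\qquad \theta = 0.60 \text{ by default,}$$

together with the majority ancestry of the supporting hits. Hits whose
lineage is truncated above $r$ count in the denominator but can never win.
A read mapping to a single entry takes that entry's taxonomy directly, and
a read with no consensus even at domain is assigned to the reserved
`unknown` domain. The threshold is strict: exactly 60% agreement escalates
to the next rank.

Around this core the package provides the full benchmarking workflow:

* `metrs.taxonomy` — SILVA-style taxonomy parsing (TSV or FASTA headers)
  onto the canonical 7-rank ladder;
* `metrs.preprocess` — merging read pairs into long pseudoreads, Q30 end
  trimming, 50 bp length filtering;
* `metrs.iolib` — SAM / TSV hit ingestion (multi-hit records included),
  tabular writers/readers;
* `metrs.profile` — abundance tables, the ≥2 reads & ≥0.01% detection
  filter, background subtraction, coefficient-of-variation (CV)
  reproducibility analysis with Welch's t-test;
* `metrs.diversity` — Shannon–Wiener index (bits), rarefaction with
  repeated subsampling, 95%-saturation depth, mapping-rate-scaled
  sequencing-cost estimates;
* `metrs.simulate` — Latin-square spike-in designs, fixture taxonomies and
  an alignment-level read simulator with ground truth.

## Worked example

`examples/consensus_assignment.py` assigns four reads over a toy two-domain
taxonomy:

```
unique_hit         (1 hits) -> species: Lactobacillus rhamnosus
species_majority   (5 hits) -> species: Lactobacillus rhamnosus
exact_60_percent   (5 hits) -> genus: Lactobacillus
cross_domain       (2 hits) -> unknown domain

genus-or-deeper fraction: 0.75
unknown fraction:         0.25
```

The single-hit read is assigned directly; 4/5 hits agreeing on
*L. rhamnosus* clears the 60% threshold at species; 3/5 (exactly 60%) does
not, but all five hits share the genus, so the read escalates to
*Lactobacillus*; and a 50/50 split between domains can never reach a
consensus, so the read lands in the unknown domain. The rank summary says
75% of mapped reads were assigned at genus level or deeper.

The other examples run the full synthetic benchmark:
`spikein_benchmark.py` (6×6 Latin-square spike-in, background subtraction,
CV analysis), `rarefaction_cost.py` (rarefaction to 95% richness
saturation, then sequenced-read costs at a 10.6% vs 0.5% mapping rate) and
`read_preprocessing.py` (pair merging into a 427 bp pseudoread).

A thin CLI wires the same stages for shell use
(`metrs preprocess|assign|profile|cv|rarefy|simulate|demo`); alignment
itself is external — map pseudoreads with a multi-hit reporting aligner
(e.g. `bowtie -a -v1 --best --strata`) and feed the SAM to `metrs assign`.
`metrs demo --seed 7` runs the whole pipeline on generated fixtures.

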