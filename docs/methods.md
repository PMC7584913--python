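# Methods

This note documents the models and procedures implemented in `cosegmap`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data tests do and do not demonstrate.

## Genetic model and study design

The pipeline targets a fully penetrant recessive single-locus trait mapped
in a single cross: an affected father (homozygous for the causal allele), a
carrier mother, and two pooled sequencing libraries of offspring — one of
affected (homozygous) and one of carrier (heterozygous) animals, 20 each by
default. Extended mapping adds unrelated individuals: carriers, which must
be heterozygous at a truly linked site, and wild types, which must be
homozygous for the non-causal allele.

Because the reference assembly comes from an unrelated individual, the
trait-linked allele at a non-causal linked site may coincide with the
assembly base. The cosegregation rule is therefore symmetric in REF/ALT:
a site cosegregates iff *some* allele X satisfies the expected genotype
pattern (affected hom-X, carriers het, unrelated wild types hom-other).
Relabeling REF↔ALT with remapped genotype indices leaves every verdict
unchanged (property-tested).

## Filter chain

Five conjunctive, order-independent conditions select usable sites:

| # | condition | default | bound |
|---|-----------|---------|-------|
| 1 | caller site quality | > 100 | strict |
| 2 | caller FILTER | PASS | — |
| 3 | repeat overlap | none | REF footprint vs BED track |
| 4 | per-library depth | > 8 | strict |
| 5 | per-library genotype quality | ≥ 20 | inclusive |

Depth and GQ are applied per library (the stricter reading of "coverage
greater than eight … for each library"); a missing genotype fails any
positive GQ bound. Repeat overlap is judged on the variant's REF footprint,
anchor base included for indels. Multiallelic records are dropped, not
decomposed. Family mapping admits {SNP, MNP}; extended mapping adds INDEL.
Raising any threshold can only shrink the surviving set (tested).

## Interval statistics

**Run rule.** Operating on the position-sorted parentally informative
sites of one scaffold, a reported interval must (a) start and end on a
cosegregating variant, (b) contain no gap of more than `max_mismatch` (2)
consecutive non-cosegregating variants, and (c) contain at least `min_run`
(3) cosegregating variants. Maximal such segments are unique and disjoint;
the implementation splits at every over-long mismatch gap and trims each
block to its terminal cosegregating variants. It is verified exhaustively
against a brute-force enumeration for every pattern up to length 16 and by
a randomized property test up to length 40 with varied parameters.

**Sliding windows.** Windows are anchored at position 1 (window 1 Mb, step
100 kb by default) on scaffolds longer than `min_scaffold_len` (100 kb
default; some analyses restrict plots to scaffolds > 1 Mb — that is the
same parameter). Only full-length windows are emitted, except that a
scaffold shorter than one window contributes a single whole-scaffold
window. Each window reports n_cosegregating / n_informative; windows with
no informative site are undefined and excluded from ranking. Ties at the
top are broken by input scaffold order, then coordinate, and all tied
windows are reported.

**Bins.** Non-overlapping 500-kb bins [1, 500000], [500001, 1000000], …
count cosegregating variants; bins partition each scaffold, so bin totals
equal scaffold totals. With step = window and `min_scaffold_len` 0 the
window counts coincide with bin counts (tested).

**Recombinant refinement.** Family members individually genotyped at
markers inside the interval imply an expected trait-allele dosage
(affected 2, carrier 1, wild type 0); a discordant marker marks a
recombinant. The interval is trimmed to the longest contiguous block of
universally concordant markers, bounded on each side by the nearest
flanking discordance; without recombinants it is unchanged. *Resolution
caveat:* bounds are reported at concordant-marker positions, so with a
subsampled marker panel the true locus can lie up to one marker spacing
outside the reported bound (the crossover occurred somewhere between the
discordant marker and the first concordant one). Downstream gene triage in
the orchestrated pipeline therefore annotates the full cosegregating set,
not only the refined interval.

**Density** is reported as variants per kb at full precision; rounding is
the caller's concern.

## Consequence annotation

Gene models are stranded exon/CDS structures (GFF3, 1-based inclusive,
phase column honored). The spliced CDS is the concatenation of CDS
segments in transcription order, reverse-complemented for minus-strand
genes; models not starting with ATG, not ending in a stop, with internal
stops or length ≢ 0 (mod 3) raise a model-integrity warning rather than an
error, since draft annotations contain such models.

Substitutions inside the CDS are applied in spliced coordinates and the
mutant CDS re-translated (standard nuclear code; stops TAA/TAG/TGA):
identical protein → synonymous; altered start codon → start_lost; earlier
stop → stop_gain; lost terminal stop → stop_loss; otherwise missense. For
a stop-gain at spliced-CDS position p on a codon boundary, the mutant
protein length is ⌈p/3⌉ − 1 — the arithmetic behind the package's
reference worked example: a C→T on a glutamine codon at CDS position 9,508
of a 3,772-residue protein yields a 3,169-residue product, a truncation of
603 residues.

Indels are classified by net length change mod 3 (frameshift vs in-frame);
in-frame indels are re-translated and promoted to stop_gain when the
mutant ends earlier than the net length change alone predicts. Variants in
the two canonical intronic bases at each junction are splice_site (an MNP
spanning a junction is splice_site — severity dominates). Variants within
3,000 bp of a gene (strand-aware upstream/downstream) are located but
carry no coding consequence. The candidate report counts consequences per
gene and flags genes with stop_gain, frameshift or splice_site variants,
ordered by severity then coordinate. Indels are assumed left-normalized
with the edited bases inside a single CDS segment; an edit spanning a
CDS/intron boundary outside the splice bases is classified by length
arithmetic alone.

## Synthetic study generator

`simdata` emulates the mapped study's design, not its genome scale.
Defaults (all exposed on `SimConfig`):

| parameter | default | meaning |
|-----------|---------|---------|
| scaffold_lengths | 2.0, 1.5, 0.3 Mb | three scaffolds, 3.8 Mb total |
| variant_density | 1.25e-3 /bp | heterozygous-site rate between founder haplotypes (≈1.25/kb) |
| linked_block_bp | 500 kb | block fully linked to the causal allele in the family founders |
| n_offspring_per_pool | 20 | affected and carrier pool sizes |
| recomb_rate | 1 /scaffold/meiosis | Poisson crossover count, uniform placement, no interference |
| depth_mean | 30 | Poisson mean per-library coverage |
| indel_fraction / mnp_fraction | 0.10 / 0.05 | variant-class mixture |
| repeat_fraction | 0.40 | fraction of each scaffold under random repeat segments |
| genotype_error | 0.005 | probability a sampled read carries the wrong allele |
| decoy_fraction | 0.10 | extra low-quality sites (QUAL ≤ 100) injected for the filters |

The density, pool sizes, depth and repeat coverage match the scales
reported for the study the design emulates; scaffold lengths and the
linked-block size are scaled down ~450-fold so a full replicate runs in
about 1.5 s, which is what lets the recovery test repeat over 20 seeds.

Generation details that matter:

* Gene models are written *into* the scaffold sequence (ATG, non-stop
  internal codons, terminal stop), ≥ 3 multi-exon genes per scaffold on
  both strands; the causal gene sits mid-scaffold on the plus strand with
  a CAG codon at the configured CDS position, so the planted C→T yields
  TAG. Repeats never overlap the causal gene's CDS.
* Founder haplotypes share one trait-linked haplotype across the father's
  two copies and the mother's carrier copy throughout the linked block;
  unrelated founders are independent except for the causal allele carried
  by the unrelated carrier. This makes extended mapping strictly shrink
  the family cosegregating set.
* Variants falling in coding sequence are restricted to substitutions
  whose ALT creates no stop codon, and none are placed in the 2-bp splice
  regions or as CDS indels. The planted stop-gain is therefore the unique
  disruptive coding variant, giving the candidate report a well-defined
  right answer. Real data contain background nonsense variants; on real
  input the candidate report may legitimately flag several genes.
* Pools are genotyped as single diploid columns, as pooled libraries often
  are in practice: reads are drawn binomially from the pooled allele
  frequency at Poisson depth, and a naive caller assigns hom/het at allele
  fractions 0.1/0.9 with a phred-scaled binomial likelihood-ratio GQ
  (capped at 99). This is a deliberate stand-in for a production variant
  caller, not a model of one; at default depth and error the pool-genotype
  miscall rate is below 1% (Monte-Carlo tested). Its ploidy treatment is a
  design decision of this package, not a claim about any particular
  caller.
* Every output byte is a deterministic function of `SimConfig` (seed
  included); reference construction, the cross and VCF emission draw from
  independent seeded substreams.

What passing tests show — and do not. Recovery at zero genotype error over
20 seeds demonstrates the *logic* of the filter → cosegregation → run /
window → annotation chain on data with the assumed statistical structure.
It does not exercise alignment artifacts, allele-balance bias, segmental
duplication, population structure among the unrelated animals, or
assembly errors, all of which degrade real mapping-by-sequencing signals.

## Shape metrics

Roundness is 4A/(π·a²) with a the major axis of the ellipse sharing the
polygon's normalized second central moments (exact shoelace-based moment
formulas; a = 4√λ_max). The moment-equivalent ellipse matches the "fitted
ellipse" convention of common image-analysis tools; the maximum Feret
diameter was deliberately not used. Solidity is area over convex-hull
area (hull from shapely). Vertices are pre-centered before any moment or
area computation so both metrics are stable (≤ 1e-9 relative drift) under
rotation, scaling and translation far from the origin; closed rings that
repeat the first vertex are detected relative to the polygon's extent.
`group_compare` is descriptive: medians, the Hodges–Lehmann shift (median
of pairwise differences) and a two-sided Mann–Whitney rank-sum statistic —
no significance model is imposed. Synthetic outline fixtures
(parallelepiped-like vs rounded/ragged) stand in for digitized microscopy
outlines, which are not distributed with the package.

## Numerical and degenerate-input choices

* Strict vs inclusive filter bounds follow the wording documented above;
  boundary values (qual 100, depth 8, GQ 20) are pinned by tests.
* Windows with zero informative variants report a missing proportion and
  never rank.
* `detect_runs` rejects unsorted input; empty input yields no intervals.
* Zero-length intervals in `density`, degenerate polygons in `shapes`, and
  BED intervals with end ≤ start raise errors naming the offense.
* GQ computation floors the error rate at 1e-4 so a zero-error
  configuration keeps finite likelihood ratios.
* The seed is the only source of randomness anywhere; derived stream seeds
  stay below 2^31.

## Known limitations

* Pools are modeled as diploid columns; true pooled allele-frequency
  calling (and its variance at low depth) is out of scope.
* Indel representation is assumed normalized; equivalent indel encodings
  are not canonicalized.
* Refinement bounds are marker-resolution (see caveat above).
* One transcript per gene; isoform choice and NMD prediction are out of
  scope, as are protein-domain annotations.
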