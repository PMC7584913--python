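# cosegmap

A mapping-by-sequencing toolkit for localizing recessive single-locus traits
in a pedigree with pooled offspring sequencing, and for triaging candidate
genes by coding consequence. It is aimed at groups mapping Mendelian color
(or other monogenic) variants in non-model vertebrates, where the study
design is typically: an affected parent, a carrier parent, pooled libraries
of affected and carrier offspring, and a handful of unrelated individuals —
all genotyped against a draft genome assembly.

## What it computes

Given a multi-sample VCF, a repeat track (BED), gene models (GFF3), the
reference (FASTA) and a sample-role sheet, the pipeline:

1. **Filters sites** with the five-step chain: caller site quality > 100,
   all caller FILTERs passed, site outside repetitive elements, per-library
   depth > 8, per-library genotype quality ≥ 20; family mapping keeps
   biallelic SNPs/MNPs, extended mapping adds biallelic indels.
2. **Classifies cosegregation.** A site cosegregates with a recessive locus
   iff some allele X ∈ {REF, ALT} has every affected library homozygous
   X/X, every obligate-carrier library heterozygous, and (in extended mode)
   every unrelated wild type homozygous for the other allele. A site is
   *parentally informative* when the affected parent is homozygous and the
   carrier parent heterozygous.
3. **Detects candidate intervals** as maximal runs of ≥ 3 consecutive
   cosegregating variants tolerating at most 2 consecutive mismatches, and
   complements the run rule with a sliding-window scan (1 Mb window, 100 kb
   step, scaffolds > 100 kb) of the proportion
   n_cosegregating / n_informative per window, plus 500-kb bin counts.
4. **Refines the interval** with individually genotyped family members:
   a snake whose marker genotype is discordant with the genotype its
   phenotype implies is a recombinant, and the interval shrinks to the
   region of universal marker concordance.
5. **Annotates consequences** of cosegregating variants on gene models
   (synonymous / missense / stop-gain / frameshift / splice-site / …) by
   splicing and translating each CDS, and flags genes carrying disruptive
   variants. For a stop-gain at spliced-CDS position p (first base of a
   codon), the mutant protein has ⌈p/3⌉ − 1 residues.

A first-class synthetic-data module (`cosegmap.simdata`) generates a
complete study — reference scaffolds, multi-exon gene models, repeat track,
recombining pedigree, pooled libraries emitted as single diploid VCF
columns, and a planted glutamine→stop causal variant inside a fully linked
haplotype block — so the whole pipeline is testable end to end against
known ground truth.

A small auxiliary module (`cosegmap.shapes`) computes the particle-shape
descriptors used to compare pigment-organelle crystals between morphs on
digitized outlines: roundness 4A/(π·a²) of the moment-equivalent fitted
ellipse, and solidity A/A_hull.

## Worked example

Simulate a study and run every stage with one command:

```sh
cosegmap -v run-all --seed 1 --out demo_run
```

Log (stderr) and manifest counts for seed 1:

```
cosegmap INFO simulate: 47 individuals, truth at scaffold_1:1001136
cosegmap INFO filter: 5292 -> 2259 variants
cosegmap INFO classify: 242 cosegregating of 2259
cosegmap INFO annotate: 1 candidate gene(s): ['scaffold_1.g2']
```

```json
{
 "variants_read": 5292,
 "variants_surviving_filters": 2259,
 "variants_cosegregating": 242,
 "run_intervals": 6,
 "interval_bp": 649158,
 "refined_interval_bp": 122856,
 "candidate_genes": ["scaffold_1.g2"]
}
```

Reading: of 5,292 VCF records (true sites plus low-quality decoys), 2,259
pass the filter chain and 242 cosegregate with the trait. The top sliding
windows (`windows.tsv`) peak at proportion 0.83 over
scaffold_1:300,001–1,400,000, bracketing the planted causal site at
1,001,136; the longest cosegregation run spans 649 kb around it and the
recombinant panel trims it to 123 kb. The candidate report flags exactly
one gene, `scaffold_1.g2` — the gene that received the planted stop-gain.
In the consequence table, the planted C→T sits on a glutamine codon and is
annotated `stop_gain` with the truncated protein length.

The same stages are available as `simulate`, `filter`, `map-family`,
`map-extended`, `windows`, `refine`, `annotate` and `shapes` subcommands,
and as plain library calls (see `docs/methods.md`).

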