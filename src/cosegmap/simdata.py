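"""Synthetic mapping-by-sequencing study generator.

Emulates the study design used to map a recessive color locus in a snake
breeding colony: an affected father homozygous for the causal allele, a
carrier mother, one pooled sequencing library of 20 affected offspring and
one of 20 carrier offspring, plus unrelated carrier and wild-type
individuals.  The generator produces a reference genome (FASTA), gene models
(GFF3), a repeat track (BED), a multi-sample VCF with pooled libraries
genotyped as single diploid columns, a sample-role sheet, and a ground-truth
record for parameter-recovery tests.

A premature stop codon (glutamine CAG/CAA -> TAG/TAA via a C->T substitution)
is planted in one gene; a configurable block of surrounding sequence is fully
linked to the causal allele in the family founders, giving the downstream
cosegregation scan a well-defined signal to recover.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .effects import (
    GeneModel,
    START_CODON,
    STOP_CODONS,
    spliced_cds,
    translate,
)
from .variantio import Genotype, Variant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

# Sub-streams of the master seed, so each stage draws from an independent
# deterministic stream regardless of call order.
_STREAM_REFERENCE = 0
_STREAM_CROSS = 1
_STREAM_VCF = 2

FATHER = "father"
MOTHER = "mother"
POOL_AFFECTED = "pool_affected"
POOL_CARRIER = "pool_carrier"


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the mapped study's design: two parents plus two pools of
    20 offspring, ~1.25 heterozygous sites per kb between founder haplotypes,
    ~30x mean depth, 40% repeat coverage, one expected crossover per scaffold
    per meiosis, and a 500-kb block fully linked to the causal allele.
    """

    seed: int = 0
    scaffold_lengths: tuple[int, ...] = (2_000_000, 1_500_000, 300_000)
    variant_density: float = 1.25e-3
    causal_gene: str = "scaffold_1.g2"
    causal_cds_len: int = 3_600  # nt, incl. terminal stop codon
    causal_cds_pos: int = 1_801  # first base of the glutamine codon to mutate
    linked_block_bp: int = 500_000
    n_offspring_per_pool: int = 20
    n_unrelated_carriers: int = 1
    n_unrelated_wildtype: int = 4
    recomb_rate: float = 1.0
    depth_mean: float = 30.0
    indel_fraction: float = 0.1
    mnp_fraction: float = 0.05
    repeat_fraction: float = 0.4
    genotype_error: float = 0.005
    decoy_fraction: float = 0.1
    genes_per_scaffold: int = 3

    def __post_init__(self) -> None:
        if not self.scaffold_lengths or any(l <= 0 for l in self.scaffold_lengths):
            raise SimConfigError("scaffold lengths must be positive")
        for name in ("variant_density", "indel_fraction", "mnp_fraction",
                     "repeat_fraction", "genotype_error", "decoy_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.indel_fraction + self.mnp_fraction > 1.0:
            raise SimConfigError("indel_fraction + mnp_fraction must be <= 1")
        for name in ("linked_block_bp", "n_offspring_per_pool", "depth_mean",
                     "causal_cds_len", "genes_per_scaffold"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.recomb_rate < 0:
            raise SimConfigError("recomb_rate must be non-negative")
        if self.causal_cds_len % 3 != 0:
            raise SimConfigError("causal_cds_len must be divisible by 3")
        if not 1 <= self.causal_cds_pos <= self.causal_cds_len:
            raise SimConfigError("causal_cds_pos outside the causal CDS")
        if (self.causal_cds_pos - 1) % 3 != 0:
            raise SimConfigError("causal_cds_pos must be the first base of a codon")
        codon_index = (self.causal_cds_pos - 1) // 3
        if codon_index == 0 or codon_index >= self.causal_cds_len // 3 - 1:
            raise SimConfigError("causal codon must be internal (not start/stop)")

    @property
    def scaffold_names(self) -> tuple[str, ...]:
        return tuple(f"scaffold_{i + 1}" for i in range(len(self.scaffold_lengths)))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class ReferenceBundle:
    config: SimConfig
    sequences: dict[str, np.ndarray]  # base codes 0..3 per scaffold
    genes: tuple[GeneModel, ...]
    repeats: dict[str, list[tuple[int, int]]]  # 0-based half-open

    def sequence_str(self, scaffold: str) -> str:
        return self.sequences[scaffold].tobytes().decode()

    @property
    def sequence_map(self) -> dict[str, str]:
        return {name: self.sequence_str(name) for name in self.sequences}

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class SimTruth:
    causal_scaffold: str
    causal_pos: int
    causal_ref: str
    causal_alt: str
    causal_gene: str
    causal_cds_pos: int
    linked_interval: tuple[int, int]
    individual_haplotypes: dict[str, dict[str, tuple[list[int], list[int]]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        lo, hi = self.linked_interval
        if not lo <= self.causal_pos <= hi:
            raise ValueError("causal position outside linked interval")

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            return list(obj)

        return json.dumps(dict(self.__dict__), indent=1, default=default)


# ---------------------------------------------------------------------------
# reference construction


def _random_cds(rng: np.random.Generator, n_nt: int,
                forced_codons: Mapping[int, str] | None = None) -> str:
    """Random CDS: ATG, non-stop internal codons, one terminal stop."""
    n_codons = n_nt // 3
    codons = [START_CODON]
    picks = rng.integers(0, len(_SAFE_CODONS), n_codons - 2)
    codons.extend(_SAFE_CODONS[p] for p in picks)
    codons.append(sorted(STOP_CODONS)[rng.integers(0, 3)])
    if forced_codons:
        for idx, codon in forced_codons.items():
            codons[idx] = codon
    return "".join(codons)


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` positive chunks at random cut points."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [total]))
    return list(np.diff(bounds).astype(int))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def build_reference(config: SimConfig) -> ReferenceBundle:
    """Generate scaffolds, multi-exon gene models and a repeat track.

    Each scaffold carries ``genes_per_scaffold`` non-overlapping multi-exon
    genes on alternating strands, centered as a group on the scaffold; the
    causal gene sits at the middle index of its scaffold's gene list and is
    placed on the plus strand with a glutamine (CAG) codon at the configured
    CDS position.  Repeats are random non-overlapping segments covering
    approximately ``repeat_fraction`` of each scaffold and never overlapping
    the causal gene's CDS.
    """
    rng = config.rng(_STREAM_REFERENCE)
    sequences: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    repeats: dict[str, list[tuple[int, int]]] = {}

    causal_scaffold = None
    for name in config.scaffold_names:
        if any(config.causal_gene == f"{name}.g{k + 1}"
               for k in range(config.genes_per_scaffold)):
            causal_scaffold = name
    if causal_scaffold is None:
        raise SimConfigError(
            f"causal_gene {config.causal_gene!r} does not name a generated gene "
            f"(expected '<scaffold>.g<k>' with k <= genes_per_scaffold)"
        )

    for name, length in zip(config.scaffold_names, config.scaffold_lengths):
        seq = _BASES[rng.integers(0, 4, length)].copy()

        # -- gene layout -----------------------------------------------------
        plans = []
        for k in range(config.genes_per_scaffold):
            gene_id = f"{name}.g{k + 1}"
            is_causal = gene_id == config.causal_gene
            if is_causal:
                cds_len = config.causal_cds_len
                forced = {(config.causal_cds_pos - 1) // 3: "CAG"}
                strand = "+"
            else:
                cds_len = 3 * int(rng.integers(150, 601))
                forced = None
                strand = "+" if k % 2 == 0 else "-"
            n_exons = int(rng.integers(3, 9))
            n_exons = min(n_exons, cds_len // 3)  # keep every exon non-empty
            exon_lens = _split_lengths(rng, cds_len, n_exons)
            intron_lens = [int(rng.integers(200, 2001)) for _ in range(n_exons - 1)]
            plans.append((gene_id, strand, cds_len, forced, exon_lens, intron_lens))

        spans = [sum(el) + sum(il) for _, _, _, _, el, il in plans]
        gaps = [int(rng.integers(5_000, 20_001)) for _ in plans]
        total = sum(spans) + sum(gaps[:-1])
        if total > length - 2_000:
            raise SimConfigError(
                f"scaffold {name} ({length} bp) too short for its gene models "
                f"({total} bp)"
            )
        cursor = max(1_000, (length - total) // 2)
        for (gene_id, strand, cds_len, forced, exon_lens, intron_lens), gap in zip(
            plans, gaps
        ):
            cds = _random_cds(rng, cds_len, forced)
            exons: list[tuple[int, int]] = []
            pos = cursor + 1  # 1-based genomic start of the gene
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + el - 1))
                pos += el
                if i < len(intron_lens):
                    pos += intron_lens[i]
            # write the CDS into the scaffold
            payload = cds if strand == "+" else _rc(cds)
            off = 0
            for s, e in exons:
                chunk = payload[off : off + (e - s + 1)]
                seq[s - 1 : e] = _encode(chunk)
                off += e - s + 1
            # GFF3 phase per segment, in transcription order
            phases: dict[tuple[int, int], int] = {}
            cum = 0
            ordered = exons if strand == "+" else exons[::-1]
            for s, e in ordered:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    scaffold=name,
                    strand=strand,
                    exons=tuple(exons),
                    cds_segments=tuple((s, e, phases[(s, e)]) for s, e in exons),
                )
            )
            cursor = exons[-1][1] + gap

        # -- repeat track ----------------------------------------------------
        forbidden = [
            (s - 1, e)  # 0-based half-open
            for g in genes
            if g.scaffold == name and g.gene_id == config.causal_gene
            for s, e, _ in g.cds_segments
        ]
        target = config.repeat_fraction * length
        chosen: list[tuple[int, int]] = []
        covered = 0
        attempts = 0
        max_attempts = 200 + int(20 * target / 5_500 + 1) * 50
        while covered < target and attempts < max_attempts * 10:
            attempts += 1
            rep_len = int(rng.integers(1_000, 10_001))
            start = int(rng.integers(0, max(1, length - rep_len)))
            cand = (start, start + rep_len)
            if any(cand[0] < e and s < cand[1] for s, e in chosen + forbidden):
                continue
            chosen.append(cand)
            covered += rep_len
        repeats[name] = sorted(chosen)
        sequences[name] = seq

    bundle = ReferenceBundle(
        config=config, sequences=sequences, genes=tuple(genes), repeats=repeats
    )
    # sanity: causal CDS long enough for the configured position
    causal = bundle.gene(config.causal_gene)
    if causal.cds_length < config.causal_cds_pos:
        raise SimConfigError("causal gene shorter than causal_cds_pos")
    return bundle


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# planting the causal stop


def plant_causal_stop(
    bundle: ReferenceBundle,
    gene_id: str | None = None,
    cds_pos: int | None = None,
) -> SimTruth:
    """Record a C->T glutamine-to-stop substitution in the causal gene.

    The target codon must be glutamine (CAG or CAA) with ``cds_pos`` its first
    base, so the substitution yields TAG/TAA; the mutant protein is truncated
    at that codon.
    """
    config = bundle.config
    gene_id = gene_id or config.causal_gene
    cds_pos = cds_pos or config.causal_cds_pos
    gene = bundle.gene(gene_id)
    if cds_pos > gene.cds_length:
        raise SimConfigError(
            f"cds_pos {cds_pos} beyond CDS length {gene.cds_length} of {gene_id}"
        )
    if (cds_pos - 1) % 3 != 0:
        raise SimConfigError("cds_pos must be the first base of a codon")
    cds = spliced_cds(gene, bundle.sequence_map)
    codon = cds[cds_pos - 1 : cds_pos + 2]
    if codon not in ("CAG", "CAA"):
        raise SimConfigError(
            f"codon at CDS position {cds_pos} is {codon}, not glutamine (CAG/CAA)"
        )
    gpos = gene.cds_to_genomic(cds_pos)
    ref_base = "C" if gene.strand == "+" else "G"
    alt_base = "T" if gene.strand == "+" else "A"
    scaffold_len = config.scaffold_lengths[
        config.scaffold_names.index(gene.scaffold)
    ]
    half = config.linked_block_bp // 2
    lo = max(1, gpos - half)
    hi = min(scaffold_len, gpos + (config.linked_block_bp - half) - 1)
    return SimTruth(
        causal_scaffold=gene.scaffold,
        causal_pos=gpos,
        causal_ref=ref_base,
        causal_alt=alt_base,
        causal_gene=gene_id,
        causal_cds_pos=cds_pos,
        linked_interval=(lo, hi),
    )


def mutant_protein_length(bundle: ReferenceBundle, truth: SimTruth) -> int:
    """Residue count of the truncated protein implied by the planted stop."""
    gene = bundle.gene(truth.causal_gene)
    cds = spliced_cds(gene, bundle.sequence_map)
    mut = cds[: truth.causal_cds_pos - 1] + "T" + cds[truth.causal_cds_pos :]
    prot = translate(mut)
    stop = prot.find("*")
    return len(prot) if stop < 0 else stop


# ---------------------------------------------------------------------------
# sites and founder haplotypes


@dataclass
class ScaffoldSites:
    positions: np.ndarray  # 1-based, sorted
    refs: list[str]
    alts: list[str]
    founder_alleles: np.ndarray  # (n_founder_haplotypes, n_sites) of 0/1


# Founder haplotype columns. The first four belong to the family: the
# trait-linked haplotype L (father both copies in the linked block, one of the
# mother's), the father's second haplotype outside the block, the mother's
# carrier haplotype and her wild-type haplotype.
H_L = 0       # shared trait-linked haplotype
H_F2 = 1      # father's second haplotype (equals L inside the linked block)
H_LM = 2      # mother's carrier haplotype (equals L inside the linked block)
H_W = 3       # mother's wild-type haplotype
N_FAMILY_HAPS = 4


@dataclass
class Individual:
    ind_id: str
    role: str  # cosegscan role at the causal locus
    phenotype: str  # "affected" / "carrier" / "wildtype"
    origin: str
    # per scaffold: (maternal-or-other haplotype allele vector, paternal ...)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]]

    def dosage(self, scaffold: str) -> np.ndarray:
        a, b = self.alleles[scaffold]
        return a + b


@dataclass
class Cohort:
    config: SimConfig
    bundle: ReferenceBundle
    truth: SimTruth
    sites: dict[str, ScaffoldSites]
    individuals: list[Individual]

    def individual(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.ind_id == ind_id:
                return ind
        raise KeyError(ind_id)

    @property
    def pool_members(self) -> dict[str, list[Individual]]:
        return {
            POOL_AFFECTED: [i for i in self.individuals if i.ind_id.startswith("aff_")],
            POOL_CARRIER: [i for i in self.individuals if i.ind_id.startswith("car_")],
        }


def _cds_and_splice_mask(bundle: ReferenceBundle, scaffold: str) -> np.ndarray:
    """Boolean mask (1-based index shifted to 0) of CDS or splice-site bases."""
    length = len(bundle.sequences[scaffold])
    mask = np.zeros(length + 2, dtype=bool)  # pad so footprint checks are easy
    for g in bundle.genes:
        if g.scaffold != scaffold:
            continue
        for s, e, _ in g.cds_segments:
            mask[s : e + 1] = True
        for p in g.splice_site_positions():
            mask[p] = True
    return mask


def _gene_at(bundle: ReferenceBundle, scaffold: str, pos: int) -> Optional[GeneModel]:
    for g in bundle.genes:
        if g.scaffold == scaffold and g.genomic_to_cds(pos) is not None:
            return g
    return None


def _safe_snp_alt(bundle: ReferenceBundle, gene: GeneModel, pos: int,
                  rng: np.random.Generator) -> Optional[str]:
    """An ALT base that does not create a stop codon in the gene's CDS.

    Keeps background coding variation to missense/synonymous changes so that
    the planted stop-gain is the unique disruptive coding variant.
    """
    cds = spliced_cds(gene, bundle.sequence_map)
    ci = gene.genomic_to_cds(pos)
    codon_start = (ci - 1) // 3 * 3
    codon = list(cds[codon_start : codon_start + 3])
    within = (ci - 1) % 3
    ref_cds_base = codon[within]
    ref_genomic = bundle.sequence_str(gene.scaffold)[pos - 1]
    options = [b for b in "ACGT" if b != ref_genomic]
    rng.shuffle(options)
    for alt in options:
        cds_base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        trial = codon.copy()
        trial[within] = cds_base
        if "".join(trial) not in STOP_CODONS and cds_base != ref_cds_base:
            if codon_start == (len(cds) - 3) and "".join(trial) not in STOP_CODONS:
                # do not destroy the terminal stop either
                if "".join(codon) in STOP_CODONS:
                    continue
            return alt
    return None


def simulate_cross(
    config: SimConfig, bundle: ReferenceBundle, truth: SimTruth
) -> Cohort:
    """Simulate founders, the F1 cross and unrelated individuals.

    Heterozygous sites between founder haplotypes arise at ``variant_density``
    per bp; inside the linked block the three trait-linked founder haplotype
    copies are identical.  Crossovers per scaffold per meiosis are Poisson
    (``recomb_rate``) with uniform placement and no interference.  Offspring
    are sampled until each pool holds ``n_offspring_per_pool`` members whose
    phenotype matches the pool (affected = homozygous causal).
    """
    rng = config.rng(_STREAM_CROSS)
    n_unrel_haps = 2 * (config.n_unrelated_carriers + config.n_unrelated_wildtype)
    n_haps = N_FAMILY_HAPS + n_unrel_haps

    sites: dict[str, ScaffoldSites] = {}
    for name, length in zip(config.scaffold_names, config.scaffold_lengths):
        seq = bundle.sequence_str(name)
        blocked = _cds_and_splice_mask(bundle, name)
        draw = rng.random(length)
        positions = np.flatnonzero(draw < config.variant_density) + 1
        is_causal_scaffold = name == truth.causal_scaffold
        if is_causal_scaffold:
            positions = positions[positions != truth.causal_pos]

        pos_list: list[int] = []
        refs: list[str] = []
        alts: list[str] = []
        last_end = 0
        for pos in positions.tolist():
            if pos <= last_end:
                continue  # keep footprints disjoint
            u = rng.random()
            in_coding = bool(blocked[pos])
            ref_base = seq[pos - 1]
            if u < config.indel_fraction and not in_coding:
                k = int(rng.integers(1, 6))
                if rng.random() < 0.5 and pos + k <= length:
                    # deletion; skip if the removed bases touch coding sequence
                    if blocked[pos + 1 : pos + k + 1].any():
                        continue
                    ref = seq[pos - 1 : pos - 1 + k + 1]
                    alt = ref[0]
                else:
                    if blocked[pos + 1]:
                        continue
                    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
                    ref = ref_base
                    alt = ref_base + ins
                end = pos + len(ref) - 1
            elif u < config.indel_fraction + config.mnp_fraction and not in_coding:
                if pos + 1 > length or blocked[pos + 1]:
                    continue
                ref = seq[pos - 1 : pos + 1]
                alt = "".join(
                    "ACGT"[(_CODE[b] + 1 + int(rng.integers(0, 3))) % 4] for b in ref
                )
                if alt[0] == ref[0] or alt[1] == ref[1]:
                    alt = "".join("ACGT"[(_CODE[b] + 1) % 4] for b in ref)
                end = pos + 1
            else:
                gene = _gene_at(bundle, name, pos) if in_coding else None
                if in_coding and gene is None:
                    continue  # splice-site base: leave untouched
                if gene is not None:
                    alt_base = _safe_snp_alt(bundle, gene, pos, rng)
                    if alt_base is None:
                        continue
                else:
                    alt_base = "ACGT"[(_CODE[ref_base] + 1 + int(rng.integers(0, 3))) % 4]
                ref, alt = ref_base, alt_base
                end = pos
            pos_list.append(pos)
            refs.append(ref)
            alts.append(alt)
            last_end = end

        n_sites = len(pos_list)
        alleles = (rng.random((n_haps, n_sites)) < 0.5).astype(np.int8)
        pos_arr = np.asarray(pos_list, dtype=np.int64)
        if is_causal_scaffold:
            lo, hi = truth.linked_interval
            in_block = (pos_arr >= lo) & (pos_arr <= hi)
            shared = alleles[H_L]
            alleles[H_F2, in_block] = shared[in_block]
            alleles[H_LM, in_block] = shared[in_block]
            # insert the causal site itself
            idx = int(np.searchsorted(pos_arr, truth.causal_pos))
            causal_col = np.zeros(n_haps, dtype=np.int8)
            causal_col[[H_L, H_F2, H_LM]] = 1
            if config.n_unrelated_carriers:
                causal_col[N_FAMILY_HAPS] = 1  # first unrelated carrier haplotype
            pos_arr = np.insert(pos_arr, idx, truth.causal_pos)
            refs.insert(idx, truth.causal_ref)
            alts.insert(idx, truth.causal_alt)
            alleles = np.insert(alleles, idx, causal_col, axis=1)

        # drop sites where no sampled haplotype carries the ALT
        keep = alleles.any(axis=0)
        pos_arr = pos_arr[keep]
        refs = [r for r, k in zip(refs, keep) if k]
        alts = [a for a, k in zip(alts, keep) if k]
        alleles = alleles[:, keep]
        sites[name] = ScaffoldSites(pos_arr, refs, alts, alleles)

    # ----- individuals ------------------------------------------------------
    def founder_individual(ind_id, role, phenotype, origin, hap_a, hap_b):
        alleles = {
            name: (sites[name].founder_alleles[hap_a].copy(),
                   sites[name].founder_alleles[hap_b].copy())
            for name in config.scaffold_names
        }
        return Individual(ind_id, role, phenotype, origin, alleles)

    individuals = [
        founder_individual(FATHER, "affected_hom", "affected", "family", H_L, H_F2),
        founder_individual(MOTHER, "carrier_het", "carrier", "family", H_LM, H_W),
    ]

    def gamete(hap_a: int, hap_b: int) -> tuple[dict[str, np.ndarray], dict[str, list[int]]]:
        """One recombined gamete: per-scaffold allele vector + breakpoints."""
        out: dict[str, np.ndarray] = {}
        breakpoints: dict[str, list[int]] = {}
        for name, length in zip(config.scaffold_names, config.scaffold_lengths):
            sc = sites[name]
            n_cross = int(rng.poisson(config.recomb_rate))
            bps = sorted(int(b) for b in rng.integers(1, length + 1, n_cross))
            phase0 = int(rng.integers(0, 2))
            seg = np.searchsorted(np.asarray(bps), sc.positions, side="right")
            pick = (seg + phase0) % 2
            hap_pair = sc.founder_alleles[[hap_a, hap_b]]
            out[name] = hap_pair[pick, np.arange(len(sc.positions))]
            breakpoints[name] = bps
        return out, breakpoints

    causal_sc = truth.causal_scaffold
    causal_idx = int(
        np.searchsorted(sites[causal_sc].positions, truth.causal_pos)
    )
    truth.individual_haplotypes = {}
    n_aff = n_car = 0
    meioses = 0
    limit = 200 * config.n_offspring_per_pool
    while (n_aff < config.n_offspring_per_pool
           or n_car < config.n_offspring_per_pool):
        meioses += 1
        if meioses > limit:
            raise RuntimeError("cross did not fill both pools; check config")
        pat, pat_bp = gamete(H_L, H_F2)
        mat, mat_bp = gamete(H_LM, H_W)
        dose = pat[causal_sc][causal_idx] + mat[causal_sc][causal_idx]
        if dose == 2 and n_aff < config.n_offspring_per_pool:
            n_aff += 1
            ind_id = f"aff_{n_aff:02d}"
            role, phen = "affected_hom", "affected"
        elif dose == 1 and n_car < config.n_offspring_per_pool:
            n_car += 1
            ind_id = f"car_{n_car:02d}"
            role, phen = "carrier_het", "carrier"
        else:
            continue
        alleles = {name: (pat[name], mat[name]) for name in config.scaffold_names}
        individuals.append(Individual(ind_id, role, phen, "family", alleles))
        truth.individual_haplotypes[ind_id] = {
            name: (pat_bp[name], mat_bp[name]) for name in config.scaffold_names
        }

    hap = N_FAMILY_HAPS
    for i in range(config.n_unrelated_carriers):
        individuals.append(
            founder_individual(f"unrel_car_{i + 1}", "carrier_het", "carrier",
                               "unrelated", hap, hap + 1)
        )
        hap += 2
    for i in range(config.n_unrelated_wildtype):
        individuals.append(
            founder_individual(f"unrel_wt_{i + 1}", "wildtype_hom", "wildtype",
                               "unrelated", hap, hap + 1)
        )
        hap += 2

    return Cohort(config=config, bundle=bundle, truth=truth, sites=sites,
                  individuals=individuals)


# ---------------------------------------------------------------------------
# naive pooled genotype caller


HET_LOW, HET_HIGH = 0.1, 0.9  # allele-fraction cutoffs of the naive caller


def call_genotype(alt_reads: int, depth: int, error: float) -> tuple[Optional[int], int]:
    """Naive diploid call from an allele fraction, with a phred-scaled GQ.

    Returns (dosage 0/1/2 or None when depth is zero, genotype quality).  The
    GQ is the phred-scaled binomial likelihood ratio between the best and
    second-best of the three dosage hypotheses, capped at 99.
    """
    if depth <= 0:
        return None, 0
    frac = alt_reads / depth
    if frac <= HET_LOW:
        dosage = 0
    elif frac >= HET_HIGH:
        dosage = 2
    else:
        dosage = 1
    e = min(max(error, 1e-4), 0.25)
    from scipy.stats import binom

    lls = sorted(
        binom.logpmf(alt_reads, depth, p) for p in (e, 0.5, 1.0 - e)
    )
    gq = 10.0 * (lls[-1] - lls[-2]) / np.log(10.0)
    return dosage, int(min(99, max(0, round(gq))))


def _call_library(
    dosage_frac: np.ndarray, rng: np.random.Generator, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized read sampling + naive calling for one library.

    ``dosage_frac`` is the true pooled ALT-allele frequency per site.
    Returns (dosage with -1 for missing, gq, depth).
    """
    n = len(dosage_frac)
    depth = rng.poisson(config.depth_mean, n)
    e = config.genotype_error
    p_eff = dosage_frac * (1 - e) + (1 - dosage_frac) * e
    alt = rng.binomial(depth, p_eff)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    dosage = np.full(n, -1, dtype=np.int8)
    dosage[(depth > 0) & (frac <= HET_LOW)] = 0
    dosage[(depth > 0) & (frac > HET_LOW) & (frac < HET_HIGH)] = 1
    dosage[(depth > 0) & (frac >= HET_HIGH)] = 2

    from scipy.stats import binom

    e_gq = min(max(e, 1e-4), 0.25)
    lls = np.stack(
        [binom.logpmf(alt, np.maximum(depth, 1), p) for p in (e_gq, 0.5, 1 - e_gq)]
    )
    lls.sort(axis=0)
    gq = 10.0 * (lls[-1] - lls[-2]) / np.log(10.0)
    gq = np.clip(np.round(gq), 0, 99).astype(np.int64)
    gq[depth == 0] = 0
    return dosage, gq, depth


# ---------------------------------------------------------------------------
# VCF emission


def emit_vcf(
    cohort: Cohort,
    vcf_path: str | os.PathLike,
    roles_path: str | os.PathLike | None = None,
) -> list[str]:
    """Write the multi-sample VCF and the sample-role sheet.

    Pools are emitted as single diploid columns: reads are drawn binomially
    from the pooled allele frequency at Poisson(depth_mean) coverage and a
    naive caller assigns hom-REF / het / hom-ALT at allele-fraction cutoffs
    0.1 / 0.9.  True sites get QUAL > 100 and FILTER PASS; a configurable
    fraction of decoy low-quality sites (QUAL <= 100) is interleaved so the
    filter chain has real work.  Returns the ordered library names.
    """
    config = cohort.config
    rng = config.rng(_STREAM_VCF)
    pools = cohort.pool_members
    libraries: list[tuple[str, list[Individual]]] = [
        (FATHER, [cohort.individual(FATHER)]),
        (MOTHER, [cohort.individual(MOTHER)]),
        (POOL_AFFECTED, pools[POOL_AFFECTED]),
        (POOL_CARRIER, pools[POOL_CARRIER]),
    ]
    for ind in cohort.individuals:
        if ind.origin == "unrelated":
            libraries.append((ind.ind_id, [ind]))
    lib_names = [name for name, _ in libraries]

    records: dict[str, list[tuple]] = {name: [] for name in config.scaffold_names}
    for name in config.scaffold_names:
        sc = cohort.sites[name]
        n_sites = len(sc.positions)
        calls = {}
        for lib, members in libraries:
            total = np.zeros(n_sites, dtype=np.int64)
            for ind in members:
                total += ind.dosage(name)
            frac = total / (2 * len(members))
            calls[lib] = _call_library(frac, rng, config)
        quals = np.round(101.0 + rng.exponential(400.0, n_sites), 2)
        for i in range(n_sites):
            gts = []
            for lib in lib_names:
                dose, gq, depth = calls[lib]
                d = int(dose[i])
                if d < 0:
                    gts.append(f"./.:.:{int(depth[i])}")
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[d]
                    gts.append(f"{gt}:{int(gq[i])}:{int(depth[i])}")
            records[name].append(
                (int(sc.positions[i]), sc.refs[i], sc.alts[i],
                 f"{quals[i]:.2f}", "PASS", gts)
            )

        # decoy noise sites failing the quality filter
        n_decoy = int(round(config.decoy_fraction * n_sites))
        seq = cohort.bundle.sequence_str(name)
        taken = set(int(p) for p in sc.positions)
        length = len(seq)
        made = 0
        while made < n_decoy:
            pos = int(rng.integers(1, length + 1))
            if pos in taken:
                continue
            taken.add(pos)
            made += 1
            ref = seq[pos - 1]
            alt = "ACGT"[(_CODE[ref] + 1 + int(rng.integers(0, 3))) % 4]
            qual = float(rng.uniform(5.0, 100.0))
            filt = "PASS" if rng.random() < 0.5 else "badReads"
            gts = []
            for _ in lib_names:
                depth = int(rng.poisson(max(2.0, config.depth_mean / 4)))
                if depth == 0:
                    gts.append("./.:.:0")
                    continue
                gt = ("0/0", "0/1", "1/1")[int(rng.integers(0, 3))]
                gts.append(f"{gt}:{int(rng.integers(0, 40))}:{depth}")
            records[name].append((pos, ref, alt, f"{qual:.2f}", filt, gts))
        records[name].sort(key=lambda r: r[0])

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cosegmap-simulate\n")
        for name, length in zip(config.scaffold_names, config.scaffold_lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FILTER=<ID=badReads,Description="Decoy low-confidence site">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(lib_names) + "\n")
        for name in config.scaffold_names:
            for pos, ref, alt, qual, filt, gts in records[name]:
                fh.write(
                    f"{name}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t{filt}\t.\tGT:GQ:DP\t"
                    + "\t".join(gts) + "\n"
                )

    if roles_path is not None:
        write_roles(cohort, roles_path, lib_names)
    return lib_names


def write_roles(
    cohort: Cohort, path: str | os.PathLike, lib_names: Sequence[str] | None = None
) -> None:
    rows = {
        FATHER: ("affected_hom", "affected", "family"),
        MOTHER: ("carrier_het", "carrier", "family"),
        POOL_AFFECTED: ("affected_hom", "affected", "family"),
        POOL_CARRIER: ("carrier_het", "carrier", "family"),
    }
    for ind in cohort.individuals:
        if ind.origin == "unrelated":
            rows[ind.ind_id] = (ind.role, ind.phenotype, "unrelated")
    order = lib_names or list(rows)
    with open(path, "w") as fh:
        fh.write("library_id\trole\tphenotype\torigin\n")
        for lib in order:
            role, phen, origin = rows[lib]
            fh.write(f"{lib}\t{role}\t{phen}\t{origin}\n")


# ---------------------------------------------------------------------------
# file writers for the reference bundle


def write_fasta(bundle: ReferenceBundle, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in bundle.config.scaffold_names:
            fh.write(f">{name}\n")
            seq = bundle.sequence_str(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(bundle: ReferenceBundle, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in zip(bundle.config.scaffold_names,
                                bundle.config.scaffold_lengths):
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in bundle.genes:
            base = f"{g.scaffold}\tcosegmap\t"
            fh.write(base + f"gene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(base + f"mRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(base + f"exon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.exon{i};Parent={mrna}\n")
            for i, (s, e, phase) in enumerate(g.cds_segments, 1):
                fh.write(base + f"CDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                         f"ID={mrna}.cds;Parent={mrna}\n")


def write_repeats_bed(bundle: ReferenceBundle, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in bundle.config.scaffold_names:
            for s, e in bundle.repeats[name]:
                fh.write(f"{name}\t{s}\t{e}\trepeat\n")


# ---------------------------------------------------------------------------
# one-call study generation


@dataclass(frozen=True)
class StudyPaths:
    fasta: Path
    gff: Path
    bed: Path
    vcf: Path
    roles: Path
    truth: Path


def simulate_study(config: SimConfig, out_dir: str | os.PathLike) -> tuple[Cohort, StudyPaths]:
    """Run the full generator and write every study file into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = build_reference(config)
    truth = plant_causal_stop(bundle)
    cohort = simulate_cross(config, bundle, truth)
    paths = StudyPaths(
        fasta=out / "reference.fa",
        gff=out / "genes.gff3",
        bed=out / "repeats.bed",
        vcf=out / "variants.vcf",
        roles=out / "roles.tsv",
        truth=out / "truth.json",
    )
    write_fasta(bundle, paths.fasta)
    write_gff3(bundle, paths.gff)
    write_repeats_bed(bundle, paths.bed)
    emit_vcf(cohort, paths.vcf, paths.roles)
    paths.truth.write_text(truth.to_json())
    return cohort, paths


def causal_variant(cohort: Cohort) -> Variant:
    """The planted causal site as a Variant record (truth genotypes, no noise)."""
    t = cohort.truth
    genotypes = {}
    sc = cohort.sites[t.causal_scaffold]
    idx = int(np.searchsorted(sc.positions, t.causal_pos))
    for ind in cohort.individuals:
        a, b = ind.alleles[t.causal_scaffold]
        genotypes[ind.ind_id] = Genotype(int(a[idx]), int(b[idx]), gq=99, depth=30)
    return Variant(
        scaffold=t.causal_scaffold,
        pos=t.causal_pos,
        ref=t.causal_ref,
        alts=(t.causal_alt,),
        site_qual=1000.0,
        filter_pass=True,
        genotypes=genotypes,
    )
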