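"""Gene models and coding-consequence annotation.

Maps variants onto stranded exon/CDS structures, splices and translates coding
sequence, and classifies each variant's effect on the protein (synonymous,
missense, stop-gain, frameshift, splice-site, ...).  The stop-gain arithmetic
is the workhorse of candidate-gene triage in a recessive mapping experiment: a
premature termination codon at spliced-CDS position p (first base of a codon)
truncates the protein to ceil(p/3) - 1 residues.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .variantio import INDEL, MNP, SNP, Variant

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
SPLICE_PAD = 2  # canonical intronic bases on each side of a junction

# Consequence categories, roughly ordered by decreasing severity.
CATEGORIES = (
    "stop_gain",
    "frameshift",
    "splice_site",
    "start_lost",
    "stop_loss",
    "missense",
    "inframe_indel",
    "synonymous",
    "intron",
    "flank_upstream",
    "flank_downstream",
    "intergenic",
)
SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}
TOP_CATEGORIES = frozenset({"stop_gain", "frameshift", "splice_site"})


class DataError(ValueError):
    """Input data inconsistent with the reference sequence."""


class ModelIntegrityWarning(UserWarning):
    """A gene model violates CDS expectations (start/stop/frame)."""


@dataclass(frozen=True)
class GeneModel:
    """Stranded exon/CDS structure (1-based inclusive intervals).

    ``cds_segments`` are (start, end, phase) triples in genomic order; phase is
    the GFF3 frame column (bases to skip to reach the first complete codon).
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted, "
                                 "non-overlapping, 1-based")
            prev_end = e
        for s, e, _ in self.cds_segments:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS segment outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    def transcription_order_cds(self) -> tuple[tuple[int, int], ...]:
        segs = [(s, e) for s, e, _ in self.cds_segments]
        return tuple(segs if self.strand == "+" else segs[::-1])

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based spliced-CDS coordinate to its genomic base."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        offset = cds_pos - 1
        for s, e in self.transcription_order_cds():
            seg_len = e - s + 1
            if offset < seg_len:
                return s + offset if self.strand == "+" else e - offset
            offset -= seg_len
        raise AssertionError("unreachable")

    def genomic_to_cds(self, gpos: int) -> Optional[int]:
        """Inverse of :meth:`cds_to_genomic`; None outside the CDS."""
        offset = 0
        for s, e in self.transcription_order_cds():
            if s <= gpos <= e:
                delta = gpos - s if self.strand == "+" else e - gpos
                return offset + delta + 1
            offset += e - s + 1
        return None

    def splice_site_positions(self) -> frozenset[int]:
        """The canonical intronic bases flanking every exon junction."""
        sites: set[int] = set()
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            sites.update(range(e1 + 1, e1 + 1 + SPLICE_PAD))
            sites.update(range(s2 - SPLICE_PAD, s2))
        return frozenset(sites)


@dataclass(frozen=True)
class Consequence:
    variant: Variant
    gene_id: Optional[str]
    category: str
    cds_pos: Optional[int] = None
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    wt_protein_len: Optional[int] = None
    mut_protein_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in SEVERITY:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "stop_gain" and None not in (
            self.wt_protein_len, self.mut_protein_len
        ):
            assert self.mut_protein_len < self.wt_protein_len

    @property
    def truncation(self) -> Optional[int]:
        if self.wt_protein_len is None or self.mut_protein_len is None:
            return None
        return self.wt_protein_len - self.mut_protein_len


# ---------------------------------------------------------------------------
# reference-sequence access


def fetch(ref, scaffold: str, start: int, end: int) -> str:
    """Reference bases [start, end] (1-based inclusive) as uppercase string.

    ``ref`` may be a plain mapping of scaffold -> sequence string or a
    pyfaidx.Fasta-like object supporting ``ref[scaffold][a:b]``.
    """
    if isinstance(ref, Mapping) and isinstance(next(iter(ref.values()), ""), str):
        return ref[scaffold][start - 1 : end].upper()
    piece = ref[scaffold][start - 1 : end]
    return str(getattr(piece, "seq", piece)).upper()


# ---------------------------------------------------------------------------
# GFF3 input


def read_gene_models(gff_path: str | os.PathLike) -> list[GeneModel]:
    """Load gene models from GFF3 (one transcript per gene assumed)."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(g, featuretype="exon"))
        )
        cds = tuple(
            sorted(
                (f.start, f.end, 0 if f.frame == "." else int(f.frame))
                for f in db.children(g, featuretype="CDS")
            )
        )
        if not exons and cds:
            exons = tuple((s, e) for s, e, _ in cds)
        genes.append(
            GeneModel(
                gene_id=g.id,
                scaffold=g.seqid,
                strand=g.strand,
                exons=exons,
                cds_segments=cds,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# splicing / translation


def spliced_cds(gene: GeneModel, ref) -> str:
    """Concatenated CDS in transcription order (reverse-complemented for '-').

    Emits a :class:`ModelIntegrityWarning` when the model does not start with
    ATG, has a length not divisible by 3, or contains an internal stop.
    """
    parts = [fetch(ref, gene.scaffold, s, e) for s, e, _ in gene.cds_segments]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    issues = validate_cds(seq)
    for issue in issues:
        warnings.warn(f"{gene.gene_id}: {issue}", ModelIntegrityWarning,
                      stacklevel=2)
    return seq


def validate_cds(seq: str) -> list[str]:
    issues = []
    if len(seq) % 3 != 0:
        issues.append(f"CDS length {len(seq)} not divisible by 3")
    if not seq.startswith(START_CODON):
        issues.append("CDS does not start with ATG")
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    if codons and codons[-1] not in STOP_CODONS:
        issues.append("CDS does not end with a stop codon")
    if any(c in STOP_CODONS for c in codons[:-1]):
        issues.append("internal stop codon")
    return issues


def translate(seq: str) -> str:
    """Standard-code translation of full codons, '*' for stops."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def residues_before_stop(protein: str) -> int:
    idx = protein.find("*")
    return len(protein) if idx < 0 else idx


# ---------------------------------------------------------------------------
# locating variants relative to genes


def locate(
    v: Variant, genes: Sequence[GeneModel], flank: int = 3000
) -> list[tuple[GeneModel, str]]:
    """All genes whose body or flank overlaps the variant's REF footprint.

    Region labels are strand-aware: ``body``, ``flank_upstream`` or
    ``flank_downstream``.  Empty list means intergenic.
    """
    hits: list[tuple[GeneModel, str]] = []
    for g in genes:
        if g.scaffold != v.scaffold:
            continue
        if v.end >= g.start and v.pos <= g.end:
            hits.append((g, "body"))
        elif v.end >= g.start - flank and v.pos < g.start:
            hits.append((g, "flank_upstream" if g.strand == "+" else "flank_downstream"))
        elif v.pos <= g.end + flank and v.pos > g.end:
            hits.append((g, "flank_downstream" if g.strand == "+" else "flank_upstream"))
    return hits


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def consequence(v: Variant, gene: GeneModel, ref, flank: int = 3000) -> Consequence:
    """Classify one biallelic variant's effect on one gene.

    Substitutions inside the CDS are re-translated against the wild-type
    spliced CDS; indels are classified by net length change modulo 3 and
    re-translated to expose hidden premature stops.
    """
    if not v.is_biallelic:
        raise ValueError("consequence() requires a biallelic variant")
    observed = fetch(ref, v.scaffold, v.pos, v.end)
    if observed != v.ref:
        raise DataError(
            f"variant REF {v.ref!r} at {v.scaffold}:{v.pos} does not match "
            f"reference sequence {observed!r}"
        )
    region = None
    for g, r in locate(v, [gene], flank=flank):
        region = r
    if region is None:
        return Consequence(v, gene.gene_id, "intergenic")
    if region != "body":
        return Consequence(v, gene.gene_id, region)

    footprint = range(v.pos, v.end + 1)
    splice = gene.splice_site_positions()
    cds_hits = [(g, gene.genomic_to_cds(g)) for g in footprint]
    in_cds = [(g, c) for g, c in cds_hits if c is not None]
    touches_splice = any(g in splice for g in footprint)
    if v.vclass == INDEL:
        # For a VCF-style anchored indel the bases actually changed start
        # after the shared anchor base.
        changed = range(v.pos + 1, max(v.end, v.pos + 1) + 1)
        touches_splice = any(g in splice for g in changed)
        changed_in_cds = [g for g in changed if gene.genomic_to_cds(g) is not None]
        anchor_in_cds = gene.genomic_to_cds(v.pos) is not None
        if touches_splice:
            return Consequence(v, gene.gene_id, "splice_site")
        if len(v.ref) > len(v.alt):  # deletion: changed bases must hit CDS
            if not changed_in_cds:
                return Consequence(v, gene.gene_id, "intron")
        elif not (anchor_in_cds and gene.genomic_to_cds(v.pos + 1) is not None):
            # insertion lands between pos and pos+1; require both in CDS
            return Consequence(v, gene.gene_id, "intron")
        return _indel_consequence(v, gene, ref)

    # SNP / MNP
    if touches_splice:
        return Consequence(v, gene.gene_id, "splice_site")
    if not in_cds:
        return Consequence(v, gene.gene_id, "intron")
    return _substitution_consequence(v, gene, ref, in_cds)


def _substitution_consequence(
    v: Variant, gene: GeneModel, ref, in_cds: list[tuple[int, int]]
) -> Consequence:
    wt = spliced_cds(gene, ref)
    mut = list(wt)
    for gpos, cpos in in_cds:
        base = v.alt[gpos - v.pos]
        mut[cpos - 1] = base if gene.strand == "+" else base.translate(_COMPLEMENT)
    mut = "".join(mut)
    wt_prot = translate(wt)
    mut_prot = translate(mut)
    wt_len = residues_before_stop(wt_prot)
    mut_len = residues_before_stop(mut_prot)
    cds_pos = min(c for _, c in in_cds)
    common = dict(cds_pos=cds_pos, wt_protein_len=wt_len, mut_protein_len=mut_len)

    if mut_prot == wt_prot:
        return Consequence(v, gene.gene_id, "synonymous", **common)

    diff = next(i for i in range(len(wt_prot)) if wt_prot[i] != mut_prot[i])
    codon_index = diff + 1
    ref_aa, alt_aa = wt_prot[diff], mut_prot[diff]
    common.update(codon_index=codon_index, ref_aa=ref_aa, alt_aa=alt_aa)

    first_codon_hit = any((c - 1) // 3 == 0 for _, c in in_cds)
    if first_codon_hit and mut[0:3] != START_CODON:
        return Consequence(v, gene.gene_id, "start_lost", **common)
    if mut_len < wt_len:
        return Consequence(v, gene.gene_id, "stop_gain", **common)
    if mut_len > wt_len:
        return Consequence(v, gene.gene_id, "stop_loss", **common)
    return Consequence(v, gene.gene_id, "missense", **common)


def _indel_consequence(v: Variant, gene: GeneModel, ref) -> Consequence:
    wt = spliced_cds(gene, ref)
    net = len(v.alt) - len(v.ref)
    category = "frameshift" if net % 3 != 0 else "inframe_indel"

    # Rebuild the mutant CDS when the edited stretch sits inside one CDS
    # segment (input assumed left-normalized); otherwise report the category
    # from length arithmetic alone.
    if gene.strand == "+":
        c_first = gene.genomic_to_cds(v.pos)
    else:
        c_first = gene.genomic_to_cds(v.end)
    c_span_ok = c_first is not None and all(
        gene.genomic_to_cds(g) is not None for g in range(v.pos, v.end + 1)
    )
    common: dict = {"cds_pos": None, "wt_protein_len": None, "mut_protein_len": None}
    if c_span_ok:
        wt_prot = translate(wt)
        alt_str = v.alt if gene.strand == "+" else _revcomp(v.alt)
        mut = wt[: c_first - 1] + alt_str + wt[c_first - 1 + len(v.ref) :]
        mut_prot = translate(mut)
        wt_len = residues_before_stop(wt_prot)
        mut_len = residues_before_stop(mut_prot)
        common = dict(
            cds_pos=min(x for x in (gene.genomic_to_cds(v.pos),
                                    gene.genomic_to_cds(v.end)) if x is not None),
            wt_protein_len=wt_len,
            mut_protein_len=mut_len,
        )
        # A hidden premature stop: the mutant ends earlier than the pure
        # length change of an in-frame indel would predict.
        if category == "inframe_indel" and mut_len < wt_len + net // 3:
            category = "stop_gain"
    return Consequence(v, gene.gene_id, category, **common)


# ---------------------------------------------------------------------------
# candidate-gene triage


def annotate_all(
    variants: Iterable[Variant],
    genes: Sequence[GeneModel],
    ref,
    flank: int = 3000,
) -> list[Consequence]:
    """One consequence row per variant x overlapping gene (or intergenic)."""
    out: list[Consequence] = []
    for v in variants:
        hits = locate(v, genes, flank=flank)
        if not hits:
            out.append(Consequence(v, None, "intergenic"))
            continue
        for g, _region in hits:
            out.append(consequence(v, g, ref, flank=flank))
    return out


def candidate_report(
    variants: Iterable[Variant],
    genes: Sequence[GeneModel],
    ref,
    flank: int = 3000,
):
    """Per-gene consequence counts with disruptive genes flagged.

    Genes carrying a stop_gain, frameshift or splice_site variant are flagged
    as top candidates.  Ordering is deterministic: flagged genes first, then
    by most severe consequence, then genomic coordinate.
    """
    import pandas as pd

    conseqs = annotate_all(variants, genes, ref, flank=flank)
    by_gene: dict[str, list[Consequence]] = {}
    for c in conseqs:
        if c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)
    gene_index = {g.gene_id: g for g in genes}
    rows = []
    for gene_id, items in by_gene.items():
        g = gene_index[gene_id]
        counts = {cat: 0 for cat in CATEGORIES}
        for c in items:
            counts[c.category] += 1
        flagged = any(c.category in TOP_CATEGORIES for c in items)
        best = min(SEVERITY[c.category] for c in items)
        rows.append(
            {
                "gene_id": gene_id,
                "scaffold": g.scaffold,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "flagged": flagged,
                "most_severe": CATEGORIES[best],
                **counts,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["severity_rank"] = df["most_severe"].map(SEVERITY)
        df = df.sort_values(
            ["flagged", "severity_rank", "scaffold", "start"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).drop(columns="severity_rank").reset_index(drop=True)
    return df, conseqs
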