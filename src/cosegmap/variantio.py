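"""Variant input/output and site/genotype filtering.

Reads a multi-sample VCF together with a repeat-annotation BED track and
materializes light-weight :class:`Variant` records that flow through the rest
of the mapping pipeline.  The filter chain mirrors the criteria used to
pre-select candidate sites in a mapping-by-sequencing experiment:

1. caller-estimated site quality strictly greater than a threshold (100),
2. all caller FILTERs passed,
3. site not overlapping an annotated repetitive element,
4. per-library read depth strictly greater than a threshold (8),
5. per-library genotype quality of at least 20.

Variant-class selection (biallelic SNP/MNP for family mapping, plus biallelic
indels for extended mapping) is a separate, order-independent step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

SNP = "SNP"
MNP = "MNP"
INDEL = "INDEL"


class ConfigurationError(ValueError):
    """A parameter or library name is inconsistent with the input data."""


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class Genotype:
    """A single library's call at one site.

    Allele indices follow VCF conventions: 0 is REF, k is the k-th ALT.
    ``None`` for both alleles means a missing call (``./.``).
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    gq: int = 0
    depth: int = 0

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError("half-missing genotypes are not supported")
        if self.gq < 0 or self.depth < 0:
            raise ValueError("gq and depth must be non-negative")

    @property
    def missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_hom(self) -> bool:
        return not self.missing and self.allele_a == self.allele_b

    @property
    def is_het(self) -> bool:
        return not self.missing and self.allele_a != self.allele_b

    def carries(self, allele: int) -> bool:
        return not self.missing and allele in (self.allele_a, self.allele_b)

    def hom_for(self, allele: int) -> bool:
        return self.is_hom and self.allele_a == allele


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class of a single REF/ALT pair."""
    if len(ref) == len(alt) == 1:
        return SNP
    if len(ref) == len(alt):
        return MNP
    return INDEL


@dataclass(frozen=True)
class Variant:
    scaffold: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    site_qual: float
    filter_pass: bool
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)
    in_repeat: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.alts:
            raise ValueError("at least one ALT allele required")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def vclass(self) -> str:
        # Class is judged against the single ALT; for multiallelic records
        # (which the pipeline drops) the first ALT is used as representative.
        return classify_alleles(self.ref, self.alts[0])

    @property
    def end(self) -> int:
        """Last 1-based reference base covered by the REF footprint."""
        return self.pos + len(self.ref) - 1

    @property
    def key(self) -> tuple:
        return (self.scaffold, self.pos, self.ref, self.alts)


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds of the five-step site/genotype filter chain.

    ``min_site_qual`` and ``min_depth`` are strict lower bounds; ``min_gq``
    is inclusive, matching the wording "a minimum genotype quality of 20".
    """

    min_site_qual: float = 100.0
    require_pass: bool = True
    min_depth: int = 8
    min_gq: int = 20
    exclude_repeats: bool = True
    allowed_classes: frozenset[str] = frozenset({SNP, MNP})
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_site_qual < 0 or self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("thresholds must be non-negative")
        bad = set(self.allowed_classes) - {SNP, MNP, INDEL}
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")

    def with_indels(self) -> "FilterSpec":
        return replace(self, allowed_classes=frozenset(self.allowed_classes | {INDEL}))


def read_repeats(bed_path: str | os.PathLike) -> dict[str, IntervalTree]:
    """Load a repeat track (BED, 0-based half-open) into interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{bed_path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{bed_path}:{lineno}: non-integer interval") from exc
            if end <= start:
                raise FormatError(
                    f"{bed_path}:{lineno}: interval end ({end}) <= start ({start})"
                )
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _overlaps_repeat(trees: Mapping[str, IntervalTree], v: Variant) -> bool:
    tree = trees.get(v.scaffold)
    if tree is None:
        return False
    # REF footprint, converted to the BED 0-based half-open frame.
    return bool(tree.overlap(v.pos - 1, v.end))


def read_variants(
    vcf_path: str | os.PathLike,
    repeat_bed_path: str | os.PathLike | None = None,
) -> list[Variant]:
    """Materialize every VCF record with per-library GT/GQ/DP and a repeat flag.

    ``in_repeat`` is true iff any reference base of the record overlaps any
    repeat interval.  Missing FORMAT fields are mapped to missing genotypes
    with GQ/DP of zero.
    """
    from cyvcf2 import VCF

    trees = read_repeats(repeat_bed_path) if repeat_bed_path is not None else {}
    out: list[Variant] = []
    try:
        reader = VCF(os.fspath(vcf_path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot open VCF {vcf_path}: {exc}") from exc
    samples = list(reader.samples)
    for rec in reader:
        # FORMAT arrays; missing entries surface as negative sentinels.
        try:
            gqs = rec.format("GQ")
        except KeyError:
            gqs = None
        try:
            dps = rec.format("DP")
        except KeyError:
            dps = None
        genotypes: dict[str, Genotype] = {}
        for i, sample in enumerate(samples):
            a, b = rec.genotypes[i][0], rec.genotypes[i][1]
            missing = a < 0 or b < 0
            gq = int(gqs[i][0]) if gqs is not None and gqs[i][0] >= 0 else 0
            dp = int(dps[i][0]) if dps is not None and dps[i][0] >= 0 else 0
            genotypes[sample] = Genotype(
                allele_a=None if missing else int(a),
                allele_b=None if missing else int(b),
                gq=max(gq, 0),
                depth=max(dp, 0),
            )
        v = Variant(
            scaffold=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF.upper(),
            alts=tuple(a.upper() for a in rec.ALT),
            site_qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
            filter_pass=rec.FILTER is None,  # cyvcf2: None means PASS/'.'
            genotypes=genotypes,
        )
        if trees and _overlaps_repeat(trees, v):
            v = replace(v, in_repeat=True)
        out.append(v)
    reader.close()
    return out


def passes_filters(v: Variant, spec: FilterSpec, libraries: Iterable[str]) -> bool:
    """Apply the full filter chain for the named libraries to one variant."""
    libs = list(libraries)
    for lib in libs:
        if lib not in v.genotypes:
            raise ConfigurationError(f"library {lib!r} absent from record at "
                                     f"{v.scaffold}:{v.pos}")
    if not (v.site_qual > spec.min_site_qual):
        return False
    if spec.require_pass and not v.filter_pass:
        return False
    if spec.exclude_repeats and v.in_repeat:
        return False
    if spec.biallelic_only and not v.is_biallelic:
        return False
    if v.vclass not in spec.allowed_classes:
        return False
    for lib in libs:
        g = v.genotypes[lib]
        if g.missing:
            return False
        if not (g.depth > spec.min_depth):
            return False
        if not (g.gq >= spec.min_gq):
            return False
    return True


def apply_filters(
    variants: Iterable[Variant], spec: FilterSpec, libraries: Iterable[str]
) -> list[Variant]:
    libs = list(libraries)
    return [v for v in variants if passes_filters(v, spec, libs)]


def select_class(
    variants: Iterable[Variant],
    allowed_classes: Iterable[str],
    biallelic_only: bool = True,
) -> list[Variant]:
    """Order-preserving subset by variant class / allele count."""
    allowed = frozenset(allowed_classes)
    out = []
    for v in variants:
        if biallelic_only and not v.is_biallelic:
            continue
        if v.vclass in allowed:
            out.append(v)
    return out


def write_variants(
    variants: Sequence[Variant],
    path: str | os.PathLike,
    sample_order: Sequence[str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write variants back out as a minimal VCF v4.2 with GT:GQ:DP."""
    variants = list(variants)
    if sample_order is None:
        sample_order = list(variants[0].genotypes) if variants else []
    contigs: dict[str, int | None] = {}
    for v in variants:
        contigs.setdefault(v.scaffold, None)
    if contig_lengths:
        for k, length in contig_lengths.items():
            contigs[k] = length
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cosegmap\n")
        for name, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FILTER=<ID=lowQual,Description="Low caller confidence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                  "FORMAT", *sample_order]
        fh.write("\t".join(header) + "\n")
        for v in variants:
            cells = [
                v.scaffold,
                str(v.pos),
                ".",
                v.ref,
                ",".join(v.alts),
                f"{v.site_qual:g}",
                "PASS" if v.filter_pass else "lowQual",
                ".",
                "GT:GQ:DP",
            ]
            for sample in sample_order:
                g = v.genotypes.get(sample)
                if g is None or g.missing:
                    dp = 0 if g is None else g.depth
                    cells.append(f"./.:.:{dp}")
                else:
                    cells.append(f"{g.allele_a}/{g.allele_b}:{g.gq}:{g.depth}")
            fh.write("\t".join(cells) + "\n")


def variants_to_table(variants: Sequence[Variant], libraries: Sequence[str]):
    """Per-variant TSV-ready report (scaffold, pos, class, qual, per-library GT)."""
    import pandas as pd

    rows = []
    for v in variants:
        row = {
            "scaffold": v.scaffold,
            "pos": v.pos,
            "ref": v.ref,
            "alt": ",".join(v.alts),
            "class": v.vclass,
            "qual": v.site_qual,
            "in_repeat": v.in_repeat,
        }
        for lib in libraries:
            g = v.genotypes.get(lib)
            row[f"GT.{lib}"] = (
                "./." if g is None or g.missing else f"{g.allele_a}/{g.allele_b}"
            )
        rows.append(row)
    return pd.DataFrame(rows)
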