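"""End-to-end orchestration: simulate -> filter -> map -> windows -> refine -> annotate.

A single declarative :class:`RunConfig` drives every stage; intermediate
tables are persisted as TSV and a machine-readable JSON manifest records
parameters, per-stage counts and output checksums.  Reruns with an identical
config reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import cosegscan, effects, simdata, variantio
from .cosegscan import (
    DEFAULT_BIN,
    DEFAULT_MIN_SCAFFOLD_LEN,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
)
from .variantio import ConfigurationError, FilterSpec

log = logging.getLogger("cosegmap")


@dataclass
class RunConfig:
    outdir: str = "cosegmap_run"
    seed: int = 0
    mode: str = "family"  # or "extended"
    # input paths; filled automatically when simulate is set
    vcf: Optional[str] = None
    repeats: Optional[str] = None
    gff: Optional[str] = None
    fasta: Optional[str] = None
    roles: Optional[str] = None
    simulate: Optional[simdata.SimConfig] = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    min_run: int = 3
    max_mismatch: int = 2
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN
    bin_size: int = DEFAULT_BIN
    flank: int = 3000
    father_id: str = simdata.FATHER
    mother_id: str = simdata.MOTHER
    refine_markers: int = 40  # markers genotyped across the panel when simulating

    def __post_init__(self) -> None:
        if self.mode not in ("family", "extended"):
            raise ConfigurationError("mode must be 'family' or 'extended'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        fspec = raw.pop("filter", None)
        cfg = cls(**raw)
        if sim is not None:
            if "scaffold_lengths" in sim:
                sim["scaffold_lengths"] = tuple(sim["scaffold_lengths"])
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = simdata.SimConfig(**sim)
        if fspec is not None:
            if "allowed_classes" in fspec:
                fspec["allowed_classes"] = frozenset(fspec["allowed_classes"])
            cfg.filter_spec = FilterSpec(**fspec)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scaffold_lengths_from_fasta(fasta_path: str) -> dict[str, int]:
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    return {name: len(fa[name]) for name in fa.keys()}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": _echo_parameters(config),
        "counts": {},
        "outputs": {},
    }
    counts = manifest["counts"]

    cohort = None
    if config.simulate is not None:
        try:
            cohort, paths = simdata.simulate_study(config.simulate, out / "sim")
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        config.vcf = str(paths.vcf)
        config.repeats = str(paths.bed)
        config.gff = str(paths.gff)
        config.fasta = str(paths.fasta)
        config.roles = str(paths.roles)
        for key in ("fasta", "gff", "bed", "vcf", "roles", "truth"):
            manifest["outputs"][f"sim/{key}"] = _sha256(getattr(paths, key))
        log.info("simulate: %d individuals, truth at %s:%d",
                 len(cohort.individuals), cohort.truth.causal_scaffold,
                 cohort.truth.causal_pos)

    for name in ("vcf", "repeats", "gff", "fasta", "roles"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise ConfigurationError(f"required input {name!r} missing: {p}")

    # ---- read + filter -----------------------------------------------------
    try:
        variants = variantio.read_variants(config.vcf, config.repeats)
        roles = cosegscan.read_roles(config.roles)
    except Exception as exc:
        raise StageError("read", exc) from exc
    counts["variants_read"] = len(variants)

    roles_used = (
        roles if config.mode == "extended" else cosegscan.family_roles(roles)
    )
    spec = config.filter_spec
    if config.mode == "extended":
        spec = spec.with_indels()
    libs = [r.library_id for r in roles_used]
    try:
        surviving = variantio.apply_filters(variants, spec, libs)
    except Exception as exc:
        raise StageError("filter", exc) from exc
    counts["variants_surviving_filters"] = len(surviving)
    log.info("filter: %d -> %d variants", len(variants), len(surviving))
    variantio.variants_to_table(surviving, libs).to_csv(
        out / "filtered_variants.tsv", sep="\t", index=False
    )

    # ---- cosegregation -----------------------------------------------------
    try:
        calls = cosegscan.classify_all(
            surviving, roles_used, config.father_id, config.mother_id
        )
    except Exception as exc:
        raise StageError("classify", exc) from exc
    n_coseg = sum(c.cosegregating for c in calls)
    counts["variants_cosegregating"] = n_coseg
    log.info("classify: %d cosegregating of %d", n_coseg, len(calls))
    cosegscan.calls_to_table(calls).to_csv(
        out / "cosegregation.tsv", sep="\t", index=False
    )

    informative = [c for c in calls if c.informative_parental]
    try:
        runs = cosegscan.detect_runs(informative, config.min_run, config.max_mismatch)
    except Exception as exc:
        raise StageError("runs", exc) from exc
    counts["run_intervals"] = len(runs)
    with open(out / "run_intervals.bed", "w") as fh:
        for r in runs:
            fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t"
                     f"coseg_run\t{r.n_coseg}\n")

    try:
        lengths = _scaffold_lengths_from_fasta(config.fasta)
        windows = cosegscan.window_scan(
            calls, lengths, config.window, config.step, config.min_scaffold_len
        )
        bins = cosegscan.bin_counts(calls, config.bin_size)
    except Exception as exc:
        raise StageError("windows", exc) from exc
    cosegscan.windows_to_table(windows).to_csv(
        out / "windows.tsv", sep="\t", index=False
    )
    bins.to_csv(out / "bins.tsv", sep="\t", index=False)

    # ---- recombinant refinement (simulated genotyping panel) ---------------
    interval = max(runs, key=lambda r: r.length) if runs else None
    if interval is not None:
        counts["interval_bp"] = interval.length
    if interval is not None and cohort is not None:
        try:
            refined = _refine_from_cohort(cohort, interval, config.refine_markers)
        except Exception as exc:
            raise StageError("refine", exc) from exc
        counts["refined_interval_bp"] = refined.length
        with open(out / "refined_interval.bed", "w") as fh:
            fh.write(f"{refined.scaffold}\t{refined.start - 1}\t{refined.end}\t"
                     f"refined\t{refined.n_coseg}\n")
        interval = refined

    # ---- consequence annotation -------------------------------------------
    try:
        genes = effects.read_gene_models(config.gff)
        from pyfaidx import Fasta

        ref = Fasta(config.fasta)
        coseg_variants = [c.variant for c in calls if c.cosegregating]
        report, conseqs = effects.candidate_report(
            coseg_variants, genes, ref, flank=config.flank
        )
    except Exception as exc:
        raise StageError("annotate", exc) from exc
    flagged = report[report["flagged"]]["gene_id"].tolist() if not report.empty else []
    counts["genes_with_coseg_variants"] = int(len(report))
    counts["candidate_genes"] = flagged
    report.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    _write_conseq_table(conseqs, out / "consequences.tsv")
    log.info("annotate: %d candidate gene(s): %s", len(flagged), flagged)

    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")):
        manifest["outputs"][p.name] = _sha256(p)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _echo_parameters(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    fs = d.pop("filter_spec")
    fs["allowed_classes"] = sorted(fs["allowed_classes"])
    d["filter"] = fs
    if d.get("simulate") is not None:
        d["simulate"]["scaffold_lengths"] = list(d["simulate"]["scaffold_lengths"])
    return d


def _write_conseq_table(conseqs, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "scaffold": c.variant.scaffold,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": ",".join(c.variant.alts),
            "gene_id": c.gene_id or "",
            "category": c.category,
            "cds_pos": c.cds_pos,
            "codon_index": c.codon_index,
            "ref_aa": c.ref_aa,
            "alt_aa": c.alt_aa,
            "wt_protein_len": c.wt_protein_len,
            "mut_protein_len": c.mut_protein_len,
        }
        for c in conseqs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _refine_from_cohort(
    cohort: simdata.Cohort, interval: cosegscan.RunInterval, n_markers: int
) -> cosegscan.RunInterval:
    """Genotype the simulated F1 panel at evenly spaced markers in the interval.

    Mirrors the follow-up step of genotyping family members at cosegregating
    SNPs to find recombinants that trim the candidate interval.
    """
    sc = cohort.sites[interval.scaffold]
    lo = int(np.searchsorted(sc.positions, interval.start, "left"))
    hi = int(np.searchsorted(sc.positions, interval.end, "right"))
    alleles = sc.founder_alleles
    # Informative markers: the trait-linked haplotype differs from the
    # mother's wild-type haplotype and the father is homozygous for it.
    informative = (
        (alleles[simdata.H_L] != alleles[simdata.H_W])
        & (alleles[simdata.H_F2] == alleles[simdata.H_L])
        & (alleles[simdata.H_LM] == alleles[simdata.H_L])
    )
    idx = np.arange(lo, hi)[informative[lo:hi]]
    if len(idx) == 0:
        return interval
    if len(idx) > n_markers:
        idx = idx[np.linspace(0, len(idx) - 1, n_markers).round().astype(int)]
    marker_pos = [int(sc.positions[i]) for i in idx]
    trait_allele = alleles[simdata.H_L][idx]
    phenotypes = {}
    marker_genotypes = {}
    for ind in cohort.individuals:
        if ind.origin != "family" or ind.ind_id in (simdata.FATHER, simdata.MOTHER):
            continue
        phenotypes[ind.ind_id] = ind.phenotype
        a, b = ind.alleles[interval.scaffold]
        trait_dosage = (a[idx] == trait_allele).astype(int) + (
            b[idx] == trait_allele
        ).astype(int)
        marker_genotypes[ind.ind_id] = {
            p: int(d) for p, d in zip(marker_pos, trait_dosage)
        }
    return cosegscan.refine_with_recombinants(interval, marker_genotypes, phenotypes)
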