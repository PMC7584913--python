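"""Cosegregation scanning for a recessive single-locus trait.

Given per-library genotypes and the expected genotype class of each library at
the causal locus (affected individuals/pools homozygous, obligate carriers
heterozygous, unrelated wild types homozygous for the other allele), this
module:

* classifies each variant as cosegregating or not (:func:`classify`),
* detects candidate intervals as runs of consecutive cosegregating variants
  tolerating short mismatch gaps (:func:`detect_runs`),
* computes sliding-window cosegregation proportions and fixed-width bin
  counts (:func:`window_scan`, :func:`bin_counts`),
* trims a candidate interval using genotyped recombinants
  (:func:`refine_with_recombinants`).

The candidate causal allele at a site may be either REF or ALT: the reference
assembly comes from an unrelated individual, so at non-causal linked sites the
trait-linked allele can coincide with the assembly base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variantio import ConfigurationError, Variant

AFFECTED_HOM = "affected_hom"
CARRIER_HET = "carrier_het"
WILDTYPE_HOM = "wildtype_hom"
ROLES = (AFFECTED_HOM, CARRIER_HET, WILDTYPE_HOM)

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 100_000
DEFAULT_MIN_SCAFFOLD_LEN = 100_000
DEFAULT_BIN = 500_000


@dataclass(frozen=True)
class LibraryRole:
    library_id: str
    role: str
    origin: str = "family"  # "family" or "unrelated"
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.origin not in ("family", "unrelated"):
            raise ValueError(f"unknown origin {self.origin!r}")


def read_roles(path: str | os.PathLike) -> list[LibraryRole]:
    """Read the tab-separated sample-role sheet."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"library_id", "role"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"role sheet must have columns {sorted(required)}")
    return [
        LibraryRole(
            library_id=r.library_id,
            role=r.role,
            origin=getattr(r, "origin", "family") or "family",
            phenotype=getattr(r, "phenotype", "") or "",
        )
        for r in df.itertuples()
    ]


def family_roles(roles: Iterable[LibraryRole]) -> list[LibraryRole]:
    return [r for r in roles if r.origin == "family"]


@dataclass(frozen=True)
class CosegCall:
    variant: Variant
    cosegregating: bool
    causal_allele: Optional[int]
    informative_parental: bool

    def __post_init__(self) -> None:
        assert (self.causal_allele is not None) == self.cosegregating

    @property
    def scaffold(self) -> str:
        return self.variant.scaffold

    @property
    def pos(self) -> int:
        return self.variant.pos


def informative_parental(v: Variant, father_id: str, mother_id: str) -> bool:
    """Father homozygous (either allele) and mother heterozygous."""
    f = v.genotypes.get(father_id)
    m = v.genotypes.get(mother_id)
    if f is None or m is None:
        return False
    return f.is_hom and m.is_het


def classify(
    v: Variant,
    roles: Sequence[LibraryRole],
    father_id: str = "father",
    mother_id: str = "mother",
) -> CosegCall:
    """Per-variant cosegregation verdict against the expected genotype classes.

    Cosegregating iff some allele X in {REF, ALT} has every affected library
    homozygous X/X, every carrier heterozygous (carrying X), and every
    unrelated wild type homozygous for the other allele.
    """
    if not v.is_biallelic:
        raise ValueError("classify() requires a biallelic variant")
    if not any(r.role == AFFECTED_HOM for r in roles):
        raise ConfigurationError("role sheet lacks an affected_hom library")
    for r in roles:
        if r.library_id not in v.genotypes:
            raise ConfigurationError(
                f"library {r.library_id!r} absent from record {v.scaffold}:{v.pos}"
            )

    causal: Optional[int] = None
    for x in (1, 0):
        other = 1 - x
        ok = True
        for r in roles:
            g = v.genotypes[r.library_id]
            if g.missing:
                ok = False
            elif r.role == AFFECTED_HOM:
                ok = g.hom_for(x)
            elif r.role == CARRIER_HET:
                ok = g.is_het and g.carries(x)
            else:  # WILDTYPE_HOM
                ok = g.hom_for(other)
            if not ok:
                break
        if ok:
            causal = x
            break
    return CosegCall(
        variant=v,
        cosegregating=causal is not None,
        causal_allele=causal,
        informative_parental=informative_parental(v, father_id, mother_id),
    )


def classify_all(
    variants: Iterable[Variant],
    roles: Sequence[LibraryRole],
    father_id: str = "father",
    mother_id: str = "mother",
) -> list[CosegCall]:
    return [classify(v, roles, father_id, mother_id) for v in variants]


# ---------------------------------------------------------------------------
# run rule


@dataclass(frozen=True)
class RunInterval:
    scaffold: str
    start: int  # position of first cosegregating variant in the run
    end: int  # position of last cosegregating variant
    n_coseg: int
    n_mismatch: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, scaffold: str, pos: int) -> bool:
        return self.scaffold == scaffold and self.start <= pos <= self.end


def detect_runs(
    calls: Sequence[CosegCall],
    min_run: int = 3,
    max_mismatch: int = 2,
) -> list[RunInterval]:
    """Maximal runs of cosegregating variants tolerating short mismatch gaps.

    A reported interval (a) starts and ends on a cosegregating variant,
    (b) contains no gap of more than ``max_mismatch`` consecutive
    non-cosegregating variants, and (c) holds at least ``min_run``
    cosegregating variants.  Input must be position-sorted per scaffold;
    intervals are disjoint and reported in genomic order.
    """
    by_scaffold: dict[str, list[CosegCall]] = {}
    for c in calls:
        group = by_scaffold.setdefault(c.scaffold, [])
        if group and c.pos < group[-1].pos:
            raise ValueError("calls must be sorted by position within scaffold")
        group.append(c)

    intervals: list[RunInterval] = []
    for scaffold, group in by_scaffold.items():
        # Split at every gap of > max_mismatch consecutive mismatches, trim
        # each block to its terminal cosegregating variants, keep blocks with
        # enough cosegregating members.
        block: list[CosegCall] = []
        consec_mis = 0
        for call in group + [None]:  # sentinel flush
            if call is not None and call.cosegregating:
                block.append(call)
                consec_mis = 0
                continue
            if call is not None:
                consec_mis += 1
                block.append(call)
                if consec_mis <= max_mismatch:
                    continue
            # gap too long (or end of scaffold): close the current block
            coseg = [c for c in block if c.cosegregating]
            if len(coseg) >= min_run:
                first, last = coseg[0], coseg[-1]
                inside = [c for c in block if first.pos <= c.pos <= last.pos]
                intervals.append(
                    RunInterval(
                        scaffold=scaffold,
                        start=first.pos,
                        end=last.pos,
                        n_coseg=len(coseg),
                        n_mismatch=len(inside) - len(coseg),
                    )
                )
            block = []
            consec_mis = 0
    return intervals


# ---------------------------------------------------------------------------
# window scan / bins


@dataclass(frozen=True)
class WindowStat:
    scaffold: str
    win_start: int  # 1-based
    win_len: int
    n_coseg: int
    n_informative: int

    def __post_init__(self) -> None:
        if self.n_coseg > self.n_informative:
            raise ValueError("n_coseg cannot exceed n_informative")

    @property
    def win_end(self) -> int:
        return self.win_start + self.win_len - 1

    @property
    def proportion(self) -> Optional[float]:
        if self.n_informative == 0:
            return None
        return self.n_coseg / self.n_informative

    def contains(self, scaffold: str, pos: int) -> bool:
        return self.scaffold == scaffold and self.win_start <= pos <= self.win_end


def window_scan(
    calls: Sequence[CosegCall],
    scaffold_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN,
) -> list[WindowStat]:
    """Sliding-window cosegregation proportions.

    Windows are anchored at position 1 with the given step; only full-length
    windows are emitted, except that a scaffold shorter than one window
    contributes a single window spanning the whole scaffold.  ``n_informative``
    counts parental-informative variants, ``n_coseg`` cosegregating ones; the
    proportion is undefined (None) in windows without informative variants.
    """
    inf_pos: dict[str, list[int]] = {}
    coseg_pos: dict[str, list[int]] = {}
    for c in calls:
        if c.informative_parental:
            inf_pos.setdefault(c.scaffold, []).append(c.pos)
        if c.cosegregating:
            coseg_pos.setdefault(c.scaffold, []).append(c.pos)

    stats: list[WindowStat] = []
    for scaffold, length in scaffold_lengths.items():
        if length <= min_scaffold_len:
            continue
        inf = np.asarray(sorted(inf_pos.get(scaffold, [])))
        cos = np.asarray(sorted(coseg_pos.get(scaffold, [])))
        if length < window:
            starts = [1]
            win_lens = [length]
        else:
            starts = list(range(1, length - window + 2, step))
            win_lens = [window] * len(starts)
        for start, wlen in zip(starts, win_lens):
            end = start + wlen - 1
            n_inf = int(np.searchsorted(inf, end, "right") - np.searchsorted(inf, start, "left"))
            n_cos = int(np.searchsorted(cos, end, "right") - np.searchsorted(cos, start, "left"))
            stats.append(WindowStat(scaffold, start, wlen, n_cos, n_inf))
    return stats


def top_windows(stats: Sequence[WindowStat]) -> list[WindowStat]:
    """All windows tied at the highest defined proportion, in input order."""
    defined = [w for w in stats if w.proportion is not None]
    if not defined:
        return []
    best = max(w.proportion for w in defined)
    return [w for w in defined if w.proportion == best]


def bin_counts(calls: Sequence[CosegCall], bin_size: int = DEFAULT_BIN) -> pd.DataFrame:
    """Counts of cosegregating variants in non-overlapping fixed-width bins.

    Bins partition each scaffold as [1, bin], [bin+1, 2*bin], ...; a variant at
    position k*bin falls in bin k (inclusive right edge).
    """
    rows: dict[tuple[str, int], int] = {}
    for c in calls:
        if not c.cosegregating:
            continue
        b = (c.pos - 1) // bin_size
        rows[(c.scaffold, b)] = rows.get((c.scaffold, b), 0) + 1
    out = [
        {
            "scaffold": scaffold,
            "bin_start": b * bin_size + 1,
            "bin_end": (b + 1) * bin_size,
            "n_coseg": n,
        }
        for (scaffold, b), n in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["scaffold", "bin_start", "bin_end", "n_coseg"])


# ---------------------------------------------------------------------------
# recombinant refinement


PHENOTYPE_DOSAGE = {"affected": 2, "carrier": 1, "wildtype": 0}


def refine_with_recombinants(
    interval: RunInterval,
    marker_genotypes: Mapping[str, Mapping[int, int]],
    phenotypes: Mapping[str, str],
) -> RunInterval:
    """Trim a candidate interval using genotyped family recombinants.

    ``marker_genotypes`` maps individual -> {marker position -> dosage of the
    trait-linked allele (0/1/2)}; ``phenotypes`` maps individual -> one of
    "affected" / "carrier" / "wildtype".  An individual is recombinant at a
    marker when its dosage differs from the one its phenotype implies.  The
    interval is trimmed to the region of universal concordance bounded by the
    innermost flanking discordant markers; without recombinants it is returned
    unchanged.
    """
    positions: set[int] = set()
    for ind, markers in marker_genotypes.items():
        if ind not in phenotypes:
            raise ConfigurationError(f"individual {ind!r} lacks a phenotype")
        positions.update(markers)
    for p in positions:
        if not interval.start <= p <= interval.end:
            raise ValueError(f"marker {p} outside interval "
                             f"[{interval.start}, {interval.end}]")
    ordered = sorted(positions)
    concordant: list[bool] = []
    for p in ordered:
        ok = True
        for ind, markers in marker_genotypes.items():
            if p not in markers:
                continue
            expected = PHENOTYPE_DOSAGE[phenotypes[ind]]
            if markers[p] != expected:
                ok = False
                break
        concordant.append(ok)
    if all(concordant):
        return interval
    if not any(concordant):
        raise ValueError("no marker is concordant in all individuals; "
                         "interval cannot be refined")

    # Longest contiguous block of universally concordant markers (first on tie).
    best_start = best_len = 0
    i = 0
    while i < len(ordered):
        if not concordant[i]:
            i += 1
            continue
        j = i
        while j < len(ordered) and concordant[j]:
            j += 1
        if j - i > best_len:
            best_start, best_len = i, j - i
        i = j
    left_disc = any(not c for c in concordant[:best_start])
    right_disc = any(not c for c in concordant[best_start + best_len :])
    new_start = ordered[best_start] if left_disc else interval.start
    new_end = ordered[best_start + best_len - 1] if right_disc else interval.end
    return replace(interval, start=new_start, end=new_end,
                   n_coseg=best_len, n_mismatch=0)


def density(n_variants: int, interval_len_bp: int) -> float:
    """Variant density in variants per kilobase (full precision)."""
    if interval_len_bp <= 0:
        raise ValueError("interval length must be positive")
    return n_variants / (interval_len_bp / 1000.0)


# ---------------------------------------------------------------------------
# tabular reports


def calls_to_table(calls: Sequence[CosegCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": c.scaffold,
                "pos": c.pos,
                "ref": c.variant.ref,
                "alt": ",".join(c.variant.alts),
                "class": c.variant.vclass,
                "cosegregating": c.cosegregating,
                "causal_allele": "" if c.causal_allele is None else c.causal_allele,
                "informative_parental": c.informative_parental,
            }
            for c in calls
        ]
    )


def windows_to_table(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": w.scaffold,
                "start": w.win_start,
                "end": w.win_end,
                "n_coseg": w.n_coseg,
                "n_informative": w.n_informative,
                "proportion": np.nan if w.proportion is None else w.proportion,
            }
            for w in stats
        ]
    )
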