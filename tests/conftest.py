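"""Shared fixtures: a small synthetic study and hand-built toy objects."""

from __future__ import annotations

import pytest

from cosegmap import simdata, variantio


SMALL = dict(
    scaffold_lengths=(400_000, 300_000, 120_000),
    linked_block_bp=150_000,
)


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    """Down-scaled study (1.2 Mb total) used by most integration fixtures."""
    return simdata.SimConfig(seed=7, genotype_error=0.0, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """Fully written-out small study: (cohort, paths)."""
    out = tmp_path_factory.mktemp("study")
    return simdata.simulate_study(small_config, out)


@pytest.fixture(scope="session")
def small_bundle(small_study):
    return small_study[0].bundle


def make_variant(
    scaffold="s1",
    pos=100,
    ref="A",
    alts=("G",),
    qual=150.0,
    filter_pass=True,
    in_repeat=False,
    genotypes=None,
):
    """Convenience builder for hand-written variant records in tests."""
    return variantio.Variant(
        scaffold=scaffold,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        site_qual=qual,
        filter_pass=filter_pass,
        in_repeat=in_repeat,
        genotypes=genotypes or {},
    )


def gt(a, b, gq=99, depth=30):
    return variantio.Genotype(a, b, gq=gq, depth=depth)


def missing_gt(gq=0, depth=0):
    return variantio.Genotype(None, None, gq=gq, depth=depth)
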