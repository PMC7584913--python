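"""Tests of cosegregation classification, runs, windows, bins and refinement."""

import itertools

import numpy as np
import pytest

from cosegmap import cosegscan
from cosegmap.cosegscan import (
    CosegCall,
    LibraryRole,
    RunInterval,
    classify,
    detect_runs,
    informative_parental,
    refine_with_recombinants,
    window_scan,
)
from cosegmap.variantio import ConfigurationError

from conftest import gt, make_variant

FAMILY = [
    LibraryRole("father", "affected_hom"),
    LibraryRole("pool_affected", "affected_hom"),
    LibraryRole("mother", "carrier_het"),
    LibraryRole("pool_carrier", "carrier_het"),
]
UNRELATED = [
    LibraryRole("unrel_car_1", "carrier_het", origin="unrelated"),
    LibraryRole("unrel_wt_1", "wildtype_hom", origin="unrelated"),
]


def family_variant(f, m, pa, pc, extra=None):
    genotypes = {
        "father": gt(*f),
        "mother": gt(*m),
        "pool_affected": gt(*pa),
        "pool_carrier": gt(*pc),
    }
    if extra:
        genotypes.update({k: gt(*v) for k, v in extra.items()})
    return make_variant(genotypes=genotypes)


def oracle_cosegregates(pattern: dict[str, tuple[int, int]],
                        roles) -> tuple[bool, int | None]:
    """Exhaustive-rule oracle: try each candidate allele explicitly."""
    for x in (1, 0):
        ok = True
        for r in roles:
            a, b = pattern[r.library_id]
            if r.role == "affected_hom":
                ok = (a, b) == (x, x)
            elif r.role == "carrier_het":
                ok = {a, b} == {0, 1} and x in (a, b)
            else:
                ok = (a, b) == (1 - x, 1 - x)
            if not ok:
                break
        if ok:
            return True, x
    return False, None


class TestClassify:
    def test_alt_cosegregation(self):
        v = family_variant((1, 1), (0, 1), (1, 1), (0, 1))
        call = classify(v, FAMILY)
        assert call.cosegregating and call.causal_allele == 1
        assert call.informative_parental

    def test_ref_cosegregation(self):
        # The assembly comes from an unrelated animal, so the trait-linked
        # allele can be the reference allele.
        v = family_variant((0, 0), (0, 1), (0, 0), (0, 1))
        call = classify(v, FAMILY)
        assert call.cosegregating and call.causal_allele == 0

    def test_unrelated_wildtype_carrying_candidate_breaks_cosegregation(self):
        v = family_variant(
            (1, 1), (0, 1), (1, 1), (0, 1),
            extra={"unrel_car_1": (0, 1), "unrel_wt_1": (0, 1)},
        )
        call = classify(v, FAMILY + UNRELATED)
        assert not call.cosegregating

    def test_missing_affected_role_is_configuration_error(self):
        v = family_variant((1, 1), (0, 1), (1, 1), (0, 1))
        with pytest.raises(ConfigurationError):
            classify(v, [LibraryRole("mother", "carrier_het")])

    def test_exhaustive_pattern_enumeration_matches_oracle(self):
        """All 3^4 biallelic diploid genotype patterns agree with the oracle."""
        gts = [(0, 0), (0, 1), (1, 1)]
        for combo in itertools.product(gts, repeat=4):
            pattern = dict(zip(
                ("father", "mother", "pool_affected", "pool_carrier"), combo))
            v = family_variant(*combo)
            call = classify(v, FAMILY)
            expected, allele = oracle_cosegregates(pattern, FAMILY)
            assert call.cosegregating == expected
            assert call.causal_allele == allele

    def test_ref_alt_relabeling_symmetry(self):
        """Swapping REF<->ALT (and remapping indices) preserves the verdict."""
        gts = [(0, 0), (0, 1), (1, 1)]
        for combo in itertools.product(gts, repeat=4):
            v = family_variant(*combo)
            flipped = family_variant(*[(1 - a, 1 - b) for a, b in combo])
            assert (classify(v, FAMILY).cosegregating
                    == classify(flipped, FAMILY).cosegregating)


class TestInformativeParental:
    @pytest.mark.parametrize(
        "father, mother, expected",
        [((1, 1), (0, 1), True), ((0, 0), (0, 1), True),
         ((0, 1), (0, 1), False), ((1, 1), (1, 1), False)],
    )
    def test_father_hom_mother_het(self, father, mother, expected):
        v = family_variant(father, mother, (1, 1), (0, 1))
        assert informative_parental(v, "father", "mother") is expected


# ---------------------------------------------------------------------------
# run rule


def calls_from_pattern(pattern: str, start=10, step=10, scaffold="s1"):
    """'C' = cosegregating, 'M' = informative mismatch."""
    calls = []
    for i, ch in enumerate(pattern):
        coseg = ch == "C"
        v = make_variant(scaffold=scaffold, pos=start + i * step)
        calls.append(CosegCall(v, coseg, 1 if coseg else None, True))
    return calls


def oracle_runs(pattern: str, min_run=3, max_mismatch=2):
    """Brute force: all maximal [i, j] segments satisfying the run rule."""
    n = len(pattern)
    valid = []
    for i in range(n):
        if pattern[i] != "C":
            continue
        consec = 0
        n_coseg = 0
        for j in range(i, n):
            if pattern[j] == "C":
                n_coseg += 1
                consec = 0
                if n_coseg >= min_run:
                    valid.append((i, j))
            else:
                consec += 1
                if consec > max_mismatch:
                    break
    return [seg for seg in valid
            if not any(o != seg and o[0] <= seg[0] and seg[1] <= o[1]
                       for o in valid)]


class TestDetectRuns:
    def test_minimal_run_of_three(self):
        runs = detect_runs(calls_from_pattern("CCC", start=10, step=10))
        assert [(r.start, r.end, r.n_coseg, r.n_mismatch) for r in runs] == \
            [(10, 30, 3, 0)]

    def test_mismatch_gaps_of_two_are_bridged(self):
        runs = detect_runs(calls_from_pattern("CMMCMMC", start=100, step=100))
        assert [(r.start, r.end, r.n_coseg, r.n_mismatch) for r in runs] == \
            [(100, 700, 3, 4)]

    def test_three_consecutive_mismatches_split(self):
        assert detect_runs(calls_from_pattern("CMMMCC")) == []

    def test_trailing_mismatches_do_not_extend_interval(self):
        runs = detect_runs(calls_from_pattern("MMCCCMM", start=10, step=10))
        assert [(r.start, r.end) for r in runs] == [(30, 50)]

    def test_unsorted_input_rejected(self):
        calls = calls_from_pattern("CCC")
        with pytest.raises(ValueError):
            detect_runs(list(reversed(calls)))

    def test_matches_bruteforce_oracle_up_to_length_12(self):
        for n in range(13):
            for bits in itertools.product("CM", repeat=n):
                pattern = "".join(bits)
                got = detect_runs(calls_from_pattern(pattern, start=1, step=1))
                got_idx = [(r.start - 1, r.end - 1) for r in got]
                assert got_idx == oracle_runs(pattern), pattern

    def test_matches_oracle_on_long_random_patterns(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=300, deadline=None, derandomize=True)
        @given(st.lists(st.booleans(), min_size=0, max_size=40),
               st.integers(2, 4), st.integers(0, 3))
        def check(bits, min_run, max_mismatch):
            pattern = "".join("C" if b else "M" for b in bits)
            got = [(r.start - 1, r.end - 1)
                   for r in detect_runs(calls_from_pattern(pattern, 1, 1),
                                        min_run=min_run,
                                        max_mismatch=max_mismatch)]
            assert got == oracle_runs(pattern, min_run, max_mismatch)

        check()

    def test_runs_are_disjoint_and_ordered(self):
        pattern = "CCCMMMCCCCMMCMMMCCC"
        runs = detect_runs(calls_from_pattern(pattern, start=1, step=1))
        for a, b in zip(runs, runs[1:]):
            assert a.end < b.start


# ---------------------------------------------------------------------------
# windows and bins


def call_at(pos, coseg, informative=True, scaffold="s1"):
    v = make_variant(scaffold=scaffold, pos=pos)
    return CosegCall(v, coseg, 1 if coseg else None, informative)


def oracle_window_counts(calls, start, end):
    """Naive double-loop count of informative/cosegregating calls."""
    n_inf = sum(1 for c in calls if c.informative_parental
                and start <= c.pos <= end)
    n_cos = sum(1 for c in calls if c.cosegregating and start <= c.pos <= end)
    return n_cos, n_inf


class TestWindowScan:
    CALLS = [
        call_at(50_000, True),
        call_at(150_000, True),
        call_at(250_000, False),
        call_at(1_050_000, True),
    ]

    def test_hand_counted_example(self):
        stats = window_scan(self.CALLS, {"s1": 1_200_000})
        first = stats[0]
        assert (first.win_start, first.win_len) == (1, 1_000_000)
        assert (first.n_coseg, first.n_informative) == (2, 3)
        assert first.proportion == pytest.approx(2 / 3)
        # Only full windows: starts 1, 100001, 200001 for a 1.2-Mb scaffold.
        assert [w.win_start for w in stats] == [1, 100_001, 200_001]
        for w in stats:
            assert (w.n_coseg, w.n_informative) == oracle_window_counts(
                self.CALLS, w.win_start, w.win_end
            )

    def test_short_scaffold_yields_single_whole_window(self):
        stats = window_scan([call_at(10_000, True, scaffold="tiny")],
                            {"tiny": 400_000})
        assert len(stats) == 1
        assert (stats[0].win_start, stats[0].win_len) == (1, 400_000)

    def test_scaffold_at_or_below_min_length_skipped(self):
        stats = window_scan([], {"small": 100_000, "big": 2_000_000})
        assert {w.scaffold for w in stats} == {"big"}

    def test_zero_informative_window_is_undefined(self):
        stats = window_scan([], {"s1": 1_000_000})
        assert all(w.proportion is None for w in stats)
        assert cosegscan.top_windows(stats) == []

    def test_all_cosegregating_gives_proportion_one(self):
        calls = [call_at(p, True) for p in range(10_000, 900_000, 100_000)]
        stats = window_scan(calls, {"s1": 1_000_000})
        assert all(w.proportion == 1.0 for w in stats if w.n_informative)

    def test_window_equals_bins_when_step_is_window(self):
        rng = np.random.default_rng(5)
        calls = sorted(
            (call_at(int(p), bool(rng.integers(0, 2)))
             for p in rng.choice(np.arange(1, 2_000_001), 300, replace=False)),
            key=lambda c: c.pos,
        )
        width = 500_000
        stats = window_scan(calls, {"s1": 2_000_000}, window=width, step=width,
                            min_scaffold_len=0)
        bins = cosegscan.bin_counts(calls, bin_size=width)
        by_start = {(r.scaffold, r.bin_start): r.n_coseg
                    for r in bins.itertuples()}
        for w in stats:
            assert w.n_coseg == by_start.get((w.scaffold, w.win_start), 0)


class TestBinCounts:
    def test_inclusive_right_edge(self):
        calls = [call_at(1, True), call_at(500_000, True), call_at(500_001, True)]
        bins = cosegscan.bin_counts(calls)
        assert bins.loc[0, ["bin_start", "n_coseg"]].tolist() == [1, 2]
        assert bins.loc[1, ["bin_start", "n_coseg"]].tolist() == [500_001, 1]

    def test_bins_partition_total(self):
        rng = np.random.default_rng(11)
        calls = sorted((call_at(int(p), True)
                        for p in rng.integers(1, 3_000_000, 500)),
                       key=lambda c: c.pos)
        bins = cosegscan.bin_counts(calls)
        assert bins["n_coseg"].sum() == sum(c.cosegregating for c in calls)


# ---------------------------------------------------------------------------
# recombinant refinement and density


class TestRefine:
    INTERVAL = RunInterval("s1", 1000, 9000, n_coseg=9, n_mismatch=0)
    MARKERS = list(range(1000, 10_000, 1000))

    def genotypes(self, discordant: dict[str, dict[int, int]] | None = None):
        base = {
            "ind_aff": {p: 2 for p in self.MARKERS},
            "ind_car": {p: 1 for p in self.MARKERS},
        }
        for ind, changes in (discordant or {}).items():
            base[ind].update(changes)
        return base

    PHENO = {"ind_aff": "affected", "ind_car": "carrier"}

    def test_no_recombinant_leaves_interval_unchanged(self):
        out = refine_with_recombinants(self.INTERVAL, self.genotypes(), self.PHENO)
        assert (out.start, out.end) == (1000, 9000)

    def test_left_discordance_moves_left_bound_to_next_marker(self):
        # affected individual heterozygous at the leftmost marker
        geno = self.genotypes({"ind_aff": {1000: 1}})
        out = refine_with_recombinants(self.INTERVAL, geno, self.PHENO)
        assert (out.start, out.end) == (2000, 9000)

    def test_double_sided_discordance_shrinks_both_bounds(self):
        geno = self.genotypes({"ind_aff": {1000: 1, 2000: 1},
                               "ind_car": {9000: 2}})
        out = refine_with_recombinants(self.INTERVAL, geno, self.PHENO)
        assert (out.start, out.end) == (3000, 8000)
        assert out.start > self.INTERVAL.start and out.end < self.INTERVAL.end

    def test_bruteforce_concordance_patterns(self):
        """Refined bounds equal a brute-force scan over concordance patterns."""
        for bits in itertools.product([True, False], repeat=6):
            if not any(bits):
                continue
            markers = [1000 * (i + 1) for i in range(6)]
            interval = RunInterval("s1", 1000, 6000, 6, 0)
            geno = {"ind": {m: (2 if ok else 1)
                            for m, ok in zip(markers, bits)}}
            out = refine_with_recombinants(interval, geno, {"ind": "affected"})
            # oracle: longest contiguous True block, first on ties
            best, cur, best_i, cur_i = 0, 0, 0, 0
            for i, ok in enumerate(bits):
                if ok:
                    cur += 1
                    if cur > best:
                        best, best_i = cur, i - cur + 1
                else:
                    cur = 0
                cur_i = i
            block = markers[best_i : best_i + best]
            left = block[0] if any(not b for b in bits[:best_i]) else 1000
            right = (block[-1]
                     if any(not b for b in bits[best_i + best :]) else 6000)
            assert (out.start, out.end) == (left, right), bits

    def test_marker_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            refine_with_recombinants(
                self.INTERVAL, {"ind_aff": {99_999: 2}}, self.PHENO)


class TestDensity:
    def test_basic_and_zero(self):
        assert cosegscan.density(1000, 1_000_000) == pytest.approx(1.0)
        assert cosegscan.density(0, 500) == 0.0

    def test_study_scale_figures(self):
        # 32,088 variants over 25.3 Mb is ~1.27 per kb (1.26 at the source's
        # rounding of the interval length).
        assert cosegscan.density(32_088, 25_300_000) == pytest.approx(1.268, abs=1e-3)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            cosegscan.density(10, 0)
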