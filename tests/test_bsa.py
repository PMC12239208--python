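"""Pooled-mapping stages against hand-executed examples and brute-force oracles."""

import statistics

import numpy as np
import pytest

from sectormap.bsa import (
    BinCounts,
    NoConsensusError,
    apply_blacklist,
    bin_variant_counts,
    call_homozygous,
    detect_mapping_interval,
    filter_ems_spectrum,
    intersect_pools,
    MappingInterval,
    shared_variants,
    subtract_shared,
)
from sectormap.model import PoolVariantSet, ReferenceGenome, SiteBlacklist, VariantCall


def vc(chrom, pos, ref="C", alt="T", depth=20, alt_depth=20):
    return VariantCall(chrom, pos, ref, alt, depth, alt_depth)


class TestCallHomozygous:
    def test_frequency_and_coverage_thresholds(self):
        pool = PoolVariantSet(
            "m",
            "mutant_pool",
            [
                vc("c", 1, depth=10, alt_depth=10),   # freq 1.0 -> kept
                vc("c", 2, depth=100, alt_depth=98),  # freq 0.98 -> dropped
                vc("c", 3, depth=1, alt_depth=1),     # below 2-read coverage
                vc("c", 4, depth=2, alt_depth=2),     # exactly at both limits
            ],
        )
        kept = {c.pos for c in call_homozygous(pool)}
        assert kept == {1, 4}


class TestSubtractShared:
    def _sibling(self, calls):
        return PoolVariantSet("s", "wildtype_pool", calls)

    def test_homozygous_in_both_removed_heterozygous_kept(self):
        mutant = {vc("c", 1), vc("c", 2)}
        sibling = self._sibling(
            [vc("c", 1, depth=30, alt_depth=30), vc("c", 2, depth=30, alt_depth=15)]
        )
        out = subtract_shared(mutant, sibling)
        assert {c.pos for c in out} == {2}

    def test_matches_brute_force_set_difference(self, rng):
        for _ in range(50):
            positions = rng.choice(500, size=40, replace=False) + 1
            mutant = {vc("c", int(p)) for p in positions[:25]}
            sib_hom = {int(p) for p in positions[10:30]}
            sibling = self._sibling(
                [vc("c", p, depth=40, alt_depth=40 if p in sib_hom else 20)
                 for p in map(int, positions)]
            )
            out = subtract_shared(mutant, sibling)
            # Oracle: exhaustive pairwise comparison on full allele identity.
            expected = {
                m for m in mutant
                if not any(
                    s.pos == m.pos and s.ref == m.ref and s.alt == m.alt
                    and s.allele_frequency >= 0.99 and s.depth >= 2
                    for s in sibling.calls.values()
                )
            }
            assert out == expected


class TestBlacklistAndSpectrum:
    def test_empty_blacklist_is_identity(self):
        s = {vc("c", 1), vc("c", 2)}
        assert apply_blacklist(s, SiteBlacklist(frozenset())) == s

    def test_full_blacklist_empties_set(self):
        s = {vc("c", 1), vc("c", 2)}
        bl = SiteBlacklist(frozenset({("c", 1), ("c", 2)}))
        assert apply_blacklist(s, bl) == set()
        assert len(apply_blacklist(s, SiteBlacklist(frozenset({("c", 1)})))) == 1

    def test_spectrum_keeps_only_ems_transitions(self):
        s = {
            vc("Chr4", 61494009, "C", "T"),
            vc("c", 2, "G", "A"),
            vc("c", 3, "A", "G"),
            vc("c", 4, "G", "T"),
        }
        out = filter_ems_spectrum(s)
        assert {c.pos for c in out} == {61494009, 2}

    def test_filters_never_grow_and_commute(self, rng):
        genome_sites = [(f"c{rng.integers(1, 3)}", int(p)) for p in rng.choice(2000, 80, replace=False) + 1]
        s = {
            vc(c, p, *rng.choice([("G", "A"), ("C", "T"), ("A", "C")]))
            for c, p in genome_sites
        }
        bl = SiteBlacklist(frozenset(genome_sites[:30]))
        a = filter_ems_spectrum(apply_blacklist(s, bl))
        b = apply_blacklist(filter_ems_spectrum(s), bl)
        assert a == b
        assert len(a) <= len(s)


class TestBinning:
    def test_boundary_arithmetic(self):
        genome = ReferenceGenome([("c", "A" * 2_500_000)])
        s = {vc("c", 1), vc("c", 1_000_000), vc("c", 1_000_001)}
        (bins,) = bin_variant_counts(s, genome)
        assert bins.counts[0] == (1, 2)
        assert bins.counts[1] == (1_000_001, 1)
        assert len(bins.counts) == 3  # partial final bin still tiled

    def test_empty_set_gives_zero_bins(self):
        genome = ReferenceGenome([("c", "A" * 3_000_000)])
        (bins,) = bin_variant_counts(set(), genome)
        assert [n for _, n in bins.counts] == [0, 0, 0]

    def test_counts_conserved_and_match_recount_oracle(self, rng):
        genome = ReferenceGenome([("c1", "A" * 900_000), ("c2", "A" * 500_000)])
        s = set()
        for _ in range(1000):
            chrom = "c1" if rng.random() < 0.6 else "c2"
            pos = int(rng.integers(1, 900_001 if chrom == "c1" else 500_001))
            s.add(vc(chrom, pos))
        bins = bin_variant_counts(s, genome, bin_size=100_000)
        assert sum(bc.total for bc in bins) == len(s)
        for bc in bins:
            for start, n in bc.counts:
                # Oracle: exhaustive recount over the bin's coordinate range.
                expected = sum(
                    1 for c in s
                    if c.chrom == bc.chrom and start <= c.pos < start + bc.bin_size
                )
                assert n == expected


def make_bins(counts_by_chrom: dict[str, list[int]], bin_size=1_000_000):
    return [
        BinCounts(
            chrom=c,
            bin_size=bin_size,
            counts=tuple((i * bin_size + 1, n) for i, n in enumerate(vals)),
        )
        for c, vals in counts_by_chrom.items()
    ]


class TestIntervalDetection:
    def test_hand_executed_example(self):
        # Genome-wide median is 1; the peak of 15 extends left/right until
        # two consecutive bins sit at or below background.
        bins = make_bins(
            {
                "cA": [0, 1, 0, 12, 15, 9, 1, 0, 0, 0],
                "cB": [1] * 10,
                "cC": [0, 1] * 5,
            }
        )
        iv = detect_mapping_interval(bins)
        assert iv is not None
        assert iv.chrom == "cA"
        assert iv.background_level == 1.0
        assert iv.peak_count == 15 and iv.peak_bin == 4_000_001
        assert iv.start == 3_000_001 and iv.end == 6_000_000

    def test_all_zero_genome_returns_none(self):
        bins = make_bins({"cA": [0] * 10, "cB": [0] * 10})
        assert detect_mapping_interval(bins) is None

    def test_flat_noise_below_prominence_returns_none(self):
        bins = make_bins({"cA": [0, 1, 2, 3, 1, 0], "cB": [1, 0, 1, 0, 1, 0]})
        assert detect_mapping_interval(bins) is None  # peak 3 <= median 1 + 3

    def test_equal_peaks_tie_breaks_to_lower_coordinates(self):
        bins = make_bins({"cA": [0, 0, 9, 0], "cB": [9, 0, 0, 0]})
        iv = detect_mapping_interval(bins)
        assert iv.chrom == "cA" and iv.peak_bin == 2_000_001

    def test_matches_independent_reimplementation(self, rng):
        for _ in range(300):
            n_chrom = int(rng.integers(1, 4))
            counts = {
                f"c{i}": [int(x) for x in rng.poisson(0.7, size=int(rng.integers(3, 12)))]
                for i in range(n_chrom)
            }
            if rng.random() < 0.5:  # sometimes plant a real peak
                ch = f"c{int(rng.integers(0, n_chrom))}"
                counts[ch][int(rng.integers(0, len(counts[ch])))] += int(rng.integers(4, 20))
            bins = make_bins(counts)
            assert detect_mapping_interval(bins) == _oracle_detect(counts)


def _oracle_detect(counts_by_chrom, bin_size=1_000_000, consec=2, excess=3):
    """Naive re-derivation of the peak-and-extend rule, written independently."""
    flat = [n for vals in counts_by_chrom.values() for n in vals]
    bg = statistics.median(flat)
    best = None
    for chrom, vals in counts_by_chrom.items():  # insertion order = genome order
        for i, n in enumerate(vals):
            if best is None or n > best[2]:
                best = (chrom, i, n)
    chrom, pi, pc = best
    if pc <= bg + excess:
        return None
    vals = counts_by_chrom[chrom]
    lo = pi
    run = 0
    for i in range(pi - 1, -1, -1):
        if vals[i] <= bg:
            run += 1
            if run >= consec:
                break
        else:
            run = 0
            lo = i
    hi = pi
    run = 0
    for i in range(pi + 1, len(vals)):
        if vals[i] <= bg:
            run += 1
            if run >= consec:
                break
        else:
            run = 0
            hi = i
    return MappingInterval(
        chrom=chrom,
        start=lo * bin_size + 1,
        end=(hi + 1) * bin_size,
        peak_bin=pi * bin_size + 1,
        peak_count=pc,
        background_level=float(bg),
    )


class TestIntersection:
    def _iv(self, chrom, start, end):
        return MappingInterval(chrom, start, end, peak_bin=start, peak_count=10,
                               background_level=0.0)

    def test_disjoint_sets_error_on_refinement(self):
        a, b = {vc("c", 1)}, {vc("c", 2)}
        assert shared_variants(a, b) == set()
        with pytest.raises(NoConsensusError):
            intersect_pools(a, b, self._iv("c", 1, 100), self._iv("c", 1, 100))

    def test_identical_sets_refine_to_shared_span(self):
        s = {vc("c", 150), vc("c", 400), vc("c", 900)}
        shared, refined = intersect_pools(
            s, set(s), self._iv("c", 100, 1000), self._iv("c", 120, 950)
        )
        assert shared == s
        assert (refined.start, refined.end) == (150, 900)

    def test_allele_identity_not_just_position(self):
        a = {vc("c", 150, "C", "T")}
        b = {vc("c", 150, "G", "A")}
        assert shared_variants(a, b) == set()

    def test_different_chromosomes_error(self):
        with pytest.raises(NoConsensusError, match="different chromosomes"):
            intersect_pools(
                {vc("c1", 5)}, {vc("c1", 5)},
                self._iv("c1", 1, 10), self._iv("c2", 1, 10),
            )
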