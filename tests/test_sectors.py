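"""Sector-pair analysis: het calling, differencing, prior confirmation,
and the cis/trans phasing rule (including an exhaustive enumeration oracle)."""

import itertools

import pytest

from sectormap.bsa import MappingInterval
from sectormap.effects import EffectAnnotation
from sectormap.model import PoolVariantSet, ReadObservation, VariantCall
from sectormap.sectors import (
    call_heterozygous,
    confirm_prior_allele,
    differential_sterile_unique,
    nominate_allele,
    phase_relative_to_prior,
    phase_variant_pair,
    verdict_from_counts,
)


def vc(pos, ref="C", alt="T", depth=60, alt_depth=30, chrom="c"):
    return VariantCall(chrom, pos, ref, alt, depth, alt_depth)


SITE_A = ("c", 100, "C", "T")
SITE_B = ("c", 140, "C", "T")


def reads_from_counts(both_alt, both_ref, alt_a, alt_b, site_a=SITE_A, site_b=SITE_B):
    """Materialise a read list with the requested informative-read pattern."""
    reads = []
    patterns = (
        [(site_a[3], site_b[3])] * both_alt
        + [(site_a[2], site_b[2])] * both_ref
        + [(site_a[3], site_b[2])] * alt_a
        + [(site_a[2], site_b[3])] * alt_b
    )
    for i, (a, b) in enumerate(patterns):
        reads.append(
            ReadObservation(
                f"r{i}",
                ((site_a[0], site_a[1], a), (site_b[0], site_b[1], b)),
            )
        )
    return reads


class TestCallHeterozygous:
    def test_window_depth_and_spectrum(self):
        pool = PoolVariantSet(
            "st",
            "sterile_sector",
            [
                vc(1, depth=60, alt_depth=31),            # 0.517 -> kept
                vc(2, depth=60, alt_depth=58),            # homozygous-like
                vc(3, "A", "C", depth=60, alt_depth=30),  # non-EMS
                vc(4, depth=9, alt_depth=4),              # below depth
                vc(5, "G", "A", depth=60, alt_depth=15),  # 0.25: boundary kept
            ],
        )
        assert {c.pos for c in call_heterozygous(pool)} == {1, 5}


class TestDifferential:
    def _interval(self):
        return MappingInterval("c", 1, 10_000, peak_bin=1, peak_count=9,
                               background_level=0.0)

    def test_partition_shared_vs_unique(self):
        sterile = {vc(10), vc(20), vc(30)}
        fertile = PoolVariantSet(
            "fe",
            "fertile_sector",
            [
                vc(10, depth=60, alt_depth=30),  # het in fertile -> shared
                vc(20, depth=60, alt_depth=1),   # 1/60 <= 0.02 -> unique
            ],
        )
        res = differential_sterile_unique(sterile, fertile, self._interval())
        assert {c.pos for c in res.unique} == {20, 30}
        assert {c.pos for c in res.shared} == {10}
        # Partition property: union is the input, intersection empty.
        assert res.unique | res.shared == sterile
        assert res.unique & res.shared == set()

    def test_interval_restriction(self):
        sterile = {vc(10), vc(99_999)}
        fertile = PoolVariantSet("fe", "fertile_sector", [])
        res = differential_sterile_unique(sterile, fertile, self._interval())
        assert {c.pos for c in res.unique} == {10}

    def test_different_alt_allele_counts_as_no_evidence(self):
        sterile = {vc(10, "C", "T")}
        fertile = PoolVariantSet(
            "fe", "fertile_sector", [vc(10, "C", "A", depth=60, alt_depth=30)]
        )
        res = differential_sterile_unique(sterile, fertile, self._interval())
        assert {c.pos for c in res.unique} == {10}


class TestConfirmPrior:
    def _sector(self, name, role, freq, depth=60):
        return PoolVariantSet(
            name, role, [vc(500, depth=depth, alt_depth=round(freq * depth))]
        )

    def test_both_near_half_confirmed(self):
        r = confirm_prior_allele(
            ("c", 500),
            self._sector("st", "sterile_sector", 0.48),
            self._sector("fe", "fertile_sector", 0.52),
        )
        assert r.confirmed
        assert r.freq_sterile == pytest.approx(0.48, abs=0.01)

    def test_low_frequency_not_confirmed(self):
        r = confirm_prior_allele(
            ("c", 500),
            self._sector("st", "sterile_sector", 0.05),
            self._sector("fe", "fertile_sector", 0.50),
        )
        assert not r.confirmed

    def test_missing_call_is_error(self):
        with pytest.raises(ValueError, match="fertile"):
            confirm_prior_allele(
                ("c", 500),
                self._sector("st", "sterile_sector", 0.5),
                PoolVariantSet("fe", "fertile_sector", []),
            )


class TestPhasing:
    def test_all_or_none_pattern_is_cis(self):
        v = phase_variant_pair(reads_from_counts(12, 10, 0, 0), SITE_A, SITE_B)
        assert v.verdict == "cis"
        assert (v.n_both_alt, v.n_both_ref, v.n_discordant) == (12, 10, 0)

    def test_complementary_single_alt_pattern_is_trans(self):
        v = phase_variant_pair(reads_from_counts(0, 0, 11, 9), SITE_A, SITE_B)
        assert v.verdict == "trans"

    def test_excess_discordance_is_ambiguous(self):
        # 9 cis-consistent + 1 discordant: 1/10 > 0.05.
        v = phase_variant_pair(reads_from_counts(5, 4, 1, 0), SITE_A, SITE_B)
        assert v.verdict == "ambiguous"

    def test_too_few_informative_reads_is_ambiguous(self):
        v = phase_variant_pair(reads_from_counts(1, 1, 0, 0), SITE_A, SITE_B)
        assert v.verdict == "ambiguous"
        # Reads covering only one site are uninformative.
        reads = [ReadObservation("r", (("c", 100, "T"),))] * 10
        v = phase_variant_pair(reads, SITE_A, SITE_B)
        assert v.n_informative == 0 and v.verdict == "ambiguous"

    def test_third_base_observations_excluded(self):
        reads = reads_from_counts(5, 5, 0, 0)
        reads.append(ReadObservation("err", (("c", 100, "G"), ("c", 140, "T"))))
        v = phase_variant_pair(reads, SITE_A, SITE_B)
        assert v.n_informative == 10 and v.verdict == "cis"

    def test_same_site_raises(self):
        with pytest.raises(ValueError):
            phase_variant_pair([], SITE_A, SITE_A)

    def test_symmetry_in_site_order(self):
        for counts in [(12, 10, 0, 0), (0, 0, 11, 9), (5, 4, 1, 0), (2, 0, 0, 0)]:
            fwd = phase_variant_pair(reads_from_counts(*counts), SITE_A, SITE_B)
            # Swapping the sites swaps the single-alt orientations only.
            rev = phase_variant_pair(reads_from_counts(*counts), SITE_B, SITE_A)
            assert fwd.verdict == rev.verdict

    def test_matches_enumeration_oracle(self):
        """Exhaustive agreement over all read-classification multisets up to
        12 informative reads (1,820 instances)."""
        checked = 0
        for total in range(0, 13):
            for a, b, ca in itertools.product(range(total + 1), repeat=3):
                cb = total - a - b - ca
                if cb < 0:
                    continue
                v = phase_variant_pair(reads_from_counts(a, b, ca, cb), SITE_A, SITE_B)
                assert v.verdict == _oracle_verdict(a, b, ca, cb)
                checked += 1
        assert checked >= 1000


def _oracle_verdict(a, b, ca, cb, min_inf=3, frac=0.05):
    """Independent restatement of the decision rule on raw counts."""
    n = a + b + ca + cb
    if n < min_inf:
        return "ambiguous"
    if (a + b) / n >= 1 - frac:
        return "cis"
    if ca >= 1 and cb >= 1 and (ca + cb) / n >= 1 - frac:
        return "trans"
    return "ambiguous"


def test_phase_relative_to_prior_trans_construction():
    """Novel lesion on the opposite homolog: reads carry the novel alt with
    the prior ref and vice versa -> trans; same-homolog control -> cis."""
    prior = ("c", 300, "C", "T")
    novel = ("c", 260, "C", "T")
    trans_reads = reads_from_counts(0, 0, 7, 8, site_a=novel, site_b=prior)
    assert phase_relative_to_prior(trans_reads, novel, prior).verdict == "trans"
    cis_reads = reads_from_counts(7, 8, 0, 0, site_a=novel, site_b=prior)
    assert phase_relative_to_prior(cis_reads, novel, prior).verdict == "cis"


class TestNomination:
    def _ann(self, gene, vtype="stop_gained", impact="HIGH"):
        hgvs = "p.Q1*" if vtype == "stop_gained" else "p.A1V"
        return EffectAnnotation(gene, vtype, impact, hgvs, 1)

    def test_empty_unique_set_gives_empty_report(self):
        nom = nominate_allele(set(), {}, {}, {})
        assert nom.genes == [] and nom.nominated_gene is None

    def test_cis_pair_trans_to_prior_nominates(self):
        va, vb = vc(100), vc(140)
        anns = {va.key: self._ann("geneX"), vb.key: self._ann("geneX", "missense_variant", "MODERATE")}
        pair = {frozenset({va.key, vb.key}): phase_variant_pair(
            reads_from_counts(8, 9, 0, 0, site_a=va.key, site_b=vb.key), va, vb)}
        prior_site = ("c", 300, "C", "T")
        prior = {
            va.key: phase_variant_pair(
                reads_from_counts(0, 0, 5, 6, site_a=va.key, site_b=prior_site),
                va, prior_site),
        }
        nom = nominate_allele({va, vb}, anns, pair, prior)
        assert nom.nominated_gene == "geneX"

    def test_two_genes_without_phasing_not_nominated(self, caplog):
        va, vb = vc(100), vc(5000)
        anns = {va.key: self._ann("geneX"), vb.key: self._ann("geneY")}
        nom = nominate_allele({va, vb}, anns, {}, {})
        assert nom.nominated_gene is None
        assert {g.gene_id for g in nom.genes} == {"geneX", "geneY"}

    def test_noncoding_variants_ignored(self):
        v = vc(100)
        anns = {v.key: EffectAnnotation("", "intergenic", "MODIFIER")}
        nom = nominate_allele({v}, anns, {}, {})
        assert nom.genes == []
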