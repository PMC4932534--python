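from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snptriage.classify import (
    classify_uniqueness,
    classify_zygosity,
    high_impact_fraction,
    inbreeding_expectation,
    intersect_labels,
    pairwise_sharing,
    zygosity_of_call,
)
from snptriage.effects import EffectAnnotation
from snptriage.records import GenotypeCall, VariantRecord

ACCS = ("H4", "Ru", "YW")


def _rec(pos, genotypes, ref="A", alt="G"):
    calls = {}
    for acc in ACCS:
        alleles = genotypes.get(acc)
        if alleles is None:
            calls[acc] = GenotypeCall(False)
        else:
            calls[acc] = GenotypeCall(True, frozenset(alleles))
    return VariantRecord("LG1", pos, ref, (alt,), 100.0, calls)


class TestZygosity:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            ({"A"}, "hom_ref"),
            ({"G"}, "hom_alt"),
            ({"A", "G"}, "het"),
            ({"G", "T"}, "het"),  # two alts, no ref: still >1 allele
            (None, "missing"),
        ],
    )
    def test_pool_allele_count_rule(self, alleles, expected):
        call = GenotypeCall(alleles is not None, frozenset(alleles or ()))
        assert zygosity_of_call(call, "A") == expected

    def test_classify_zygosity_table(self):
        recs = [_rec(1, {"H4": {"A", "G"}, "Ru": {"A"}, "YW": {"G"}})]
        (labels,) = classify_zygosity(recs, ACCS)
        assert labels == {"H4": "het", "Ru": "hom_ref", "YW": "hom_alt"}

    @settings(derandomize=True, max_examples=50)
    @given(st.sets(st.sampled_from("ACGT"), min_size=1, max_size=4))
    def test_invariant_under_allele_relabeling(self, alleles):
        """Zygosity depends only on how many distinct alleles the pool
        shows, not on which bases they are."""
        relabel = {"A": "T", "C": "G", "G": "C", "T": "A"}
        call = GenotypeCall(True, frozenset(alleles))
        swapped = GenotypeCall(True, frozenset(relabel[a] for a in alleles))
        a = zygosity_of_call(call, "A")
        b = zygosity_of_call(swapped, relabel["A"])
        assert (a == "het") == (b == "het")


class TestUniqueness:
    def test_het_carrier_is_still_unique(self):
        (p,) = classify_uniqueness(
            [_rec(1, {"H4": {"A", "G"}, "Ru": {"A"}, "YW": {"A"}})], ACCS
        )
        assert p.uniqueness == "H4"
        assert p.zygosity["H4"] == "het"

    def test_all_three_carriers_shared(self):
        (p,) = classify_uniqueness(
            [_rec(1, {"H4": {"G"}, "Ru": {"G"}, "YW": {"G"}})], ACCS
        )
        assert p.uniqueness == "shared"

    def test_two_carriers_shared_not_unique(self):
        (p,) = classify_uniqueness(
            [_rec(1, {"H4": {"A"}, "Ru": {"G"}, "YW": {"G"}})], ACCS
        )
        assert p.uniqueness == "shared"

    def test_missing_call_disqualifies(self):
        (p,) = classify_uniqueness(
            [_rec(1, {"H4": {"G"}, "Ru": {"A"}})], ACCS
        )
        assert p.uniqueness == "none"

    def test_unknown_accession_is_error(self):
        with pytest.raises(KeyError):
            classify_uniqueness([_rec(1, {"H4": {"G"}})], ("H4", "Nope"))

    def test_partition_property(self, small_panel):
        """Every fully-called locus is exactly one of unique-to-X, shared,
        or none."""
        profiles = classify_uniqueness(
            small_panel.records, small_panel.config.accessions
        )
        valid = set(ACCS) | {"shared", "none"}
        for p in profiles:
            assert p.uniqueness in valid
            if any(z == "missing" for z in p.zygosity.values()):
                assert p.uniqueness == "none"


class TestPairwiseSharing:
    def test_hand_counted_matrix(self):
        recs = [
            _rec(1, {"H4": {"G"}, "Ru": {"A"}, "YW": {"A"}}),  # H4 only
            _rec(2, {"H4": {"A"}, "Ru": {"G"}, "YW": {"G"}}),  # Ru & YW
            _rec(3, {"H4": {"G"}, "Ru": {"G"}, "YW": {"G"}}),  # all three
        ]
        mat = pairwise_sharing(classify_uniqueness(recs, ACCS))
        assert mat.loc["Ru", "YW"] == 2
        assert mat.loc["H4", "Ru"] == 1
        assert mat.loc["YW", "Ru"] == mat.loc["Ru", "YW"]

    def test_no_variants(self):
        assert pairwise_sharing([]).empty

    def test_planted_pair_excess(self, small_panel):
        """The generator plants more Ru/YW co-carried loci than either
        shares with H4, and classification recovers that asymmetry."""
        profiles = classify_uniqueness(
            small_panel.records, small_panel.config.accessions
        )
        mat = pairwise_sharing(profiles)
        assert mat.loc["Ru", "YW"] > mat.loc["H4", "Ru"]
        assert mat.loc["Ru", "YW"] > mat.loc["H4", "YW"]


class TestIntersect:
    def _fixture(self):
        recs = [
            _rec(i, {"H4": {"G"}, "Ru": {"A"}, "YW": {"A"}}) for i in range(1, 5)
        ] + [_rec(i, {"H4": {"A", "G"}, "Ru": {"G"}, "YW": {"A"}}) for i in range(5, 11)]
        profiles = classify_uniqueness(recs, ACCS)
        anns = [
            EffectAnnotation("LG1", i, "g1", "frameshift" if i <= 2 else "intron", "G")
            for i in range(1, 11)
        ]
        return profiles, anns

    def test_unique_and_high(self):
        profiles, anns = self._fixture()
        hits = intersect_labels(
            profiles, anns, accession="H4", want_unique=True, want_impacts={"HIGH"}
        )
        assert [p.position for p in hits] == [1, 2]

    def test_no_predicates_is_identity(self):
        profiles, anns = self._fixture()
        assert intersect_labels(profiles, anns) == profiles

    def test_het_predicate(self):
        profiles, anns = self._fixture()
        hits = intersect_labels(profiles, anns, accession="H4", want_het=True)
        assert [p.position for p in hits] == list(range(5, 11))


class TestHighImpactFraction:
    def test_overall_fraction(self):
        recs = [
            _rec(i, {"H4": {"G"}, "Ru": {"A"}, "YW": {"A"}}) for i in range(1, 201)
        ]
        profiles = classify_uniqueness(recs, ACCS)
        anns = [
            EffectAnnotation("LG1", i, "g", "frameshift" if i <= 2 else "intron", "G")
            for i in range(1, 201)
        ]
        out = high_impact_fraction(profiles, anns)
        assert out["all"] == pytest.approx(0.01)

    def test_empty_stratum_is_undefined_not_crash(self):
        recs = [_rec(1, {"H4": {"G"}, "Ru": {"A"}, "YW": {"A"}})]
        profiles = classify_uniqueness(recs, ACCS)
        anns = [EffectAnnotation("LG1", 1, "g", "intron", "G")]
        out = high_impact_fraction(profiles, anns)
        assert out["het_H4"] is None


class TestInbreeding:
    def test_seven_generations(self):
        exp = inbreeding_expectation(7, 100_000, 200_000_000)
        assert exp.reduction_factor == 128
        assert exp.mean_spacing == pytest.approx(2000.0)
        assert exp.inferred_ancestral_spacing == 16  # 15.625 rounds up

    def test_zero_generations(self):
        exp = inbreeding_expectation(0, 100_000, 200_000_000)
        assert exp.reduction_factor == 1
        assert exp.inferred_ancestral_spacing == 2000

    def test_one_generation(self):
        exp = inbreeding_expectation(1, 100_000, 200_000_000)
        assert exp.reduction_factor == 2
        assert exp.inferred_ancestral_spacing == 1000

    @pytest.mark.parametrize("g", range(0, 10))
    def test_factor_doubles_each_generation(self, g):
        a = inbreeding_expectation(g, 1000, 10_000_000)
        b = inbreeding_expectation(g + 1, 1000, 10_000_000)
        assert b.reduction_factor == 2 * a.reduction_factor

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inbreeding_expectation(-1, 10, 10)
        with pytest.raises(ValueError):
            inbreeding_expectation(1, 0, 10)
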