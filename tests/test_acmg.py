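"""ACMG evidence-code evaluation and combining."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from brcakit.acmg import (
    Classification,
    ConfigError,
    EngineConfig,
    classify_acmg,
    combine_counts,
    evaluate_criteria,
    find_pf_boundary,
)
from brcakit.knowledge_base import (
    AnnotationBundle,
    DatabaseAssertion,
    FunctionalRecord,
    PopulationFrequency,
)
from brcakit.tiers import Tier
from brcakit.variant_model import build_variant

from oracle_combining import all_count_vectors, oracle_combine


def _freq(pf, cohort_id="ToMMo", kind="japanese", an=10**7):
    return PopulationFrequency(cohort_id, kind, round(pf * an), an)


@pytest.fixture(scope="module")
def missense_brca1(models):
    return build_variant("BRCA1", "c.4957G>T", "p.V1653L", None, models)


@pytest.fixture(scope="module")
def missense_brca2(models):
    return build_variant("BRCA2", "c.520C>T", "p.R174C", None, models)


def _triggered(variant, bundle, config=None):
    profile = evaluate_criteria(variant, bundle, config or EngineConfig())
    return set(profile.triggered_codes)


class TestPerCodeTriggers:
    def test_empty_bundle_missense_triggers_only_absence(self, missense_brca2):
        # no domain annotation on file: neither PM1 nor BP1 may fire
        b = AnnotationBundle.empty(missense_brca2.key)
        assert _triggered(missense_brca2, b) == {"PM2"}

    def test_pvs1_full_strength_for_early_nonsense(self, models):
        v = build_variant("BRCA1", "c.1066C>T", "p.Q356*", None, models)
        profile = evaluate_criteria(v, AnnotationBundle.empty(v.key))
        code = next(c for c in profile.codes if c.code == "PVS1")
        assert code.triggered and code.strength_override is None
        assert profile.counts["PVS"] == 1

    def test_pvs1_downgraded_in_last_exon(self, models, fixture):
        v = next(x for x in fixture.variants if x.key == "BRCA2:c.10219del")
        profile = evaluate_criteria(v, fixture.kb.bundle(v.key))
        code = next(c for c in profile.codes if c.code == "PVS1")
        assert code.triggered and code.strength_override == "PM"
        assert profile.counts["PVS"] == 0 and profile.counts["PM"] == 2

    @pytest.mark.parametrize("state,expected_code", [
        ("same_aa_change", "PS1"),
        ("different_aa_change", "PM5"),
    ])
    def test_same_residue_codes(self, missense_brca1, state, expected_code):
        b = AnnotationBundle(missense_brca1.key, same_residue_known_pathogenic=state)
        codes = _triggered(missense_brca1, b)
        other = ({"PS1", "PM5"} - {expected_code}).pop()
        assert expected_code in codes
        assert other not in codes

    def test_ps3_needs_well_established_assay(self, missense_brca2):
        ok = AnnotationBundle(
            missense_brca2.key,
            functional=(FunctionalRecord("HR_capacity", "deleterious",
                                         "complete_deficiency", "t"),),
        )
        not_ok = AnnotationBundle(
            missense_brca2.key,
            functional=(FunctionalRecord("splicing", "deleterious",
                                         "partial_deficiency", "t"),),
        )
        assert "PS3" in _triggered(missense_brca2, ok)
        assert "PS3" not in _triggered(missense_brca2, not_ok)

    def test_bs3_requires_all_neutral(self, missense_brca2):
        all_neutral = AnnotationBundle(
            missense_brca2.key,
            functional=(
                FunctionalRecord("complementation", "neutral", "proficient", "a"),
                FunctionalRecord("splicing", "neutral", "proficient", "b"),
            ),
        )
        mixed = AnnotationBundle(
            missense_brca2.key,
            functional=(
                FunctionalRecord("complementation", "neutral", "proficient", "a"),
                FunctionalRecord("HR_capacity", "intermediate", "partial_deficiency", "b"),
            ),
        )
        only_non_established = AnnotationBundle(
            missense_brca2.key,
            functional=(FunctionalRecord("splicing", "neutral", "proficient", "a"),),
        )
        assert "BS3" in _triggered(missense_brca2, all_neutral)
        assert "BS3" not in _triggered(missense_brca2, mixed)
        assert "BS3" not in _triggered(missense_brca2, only_non_established)

    def test_domain_codes_need_explicit_annotation(self, missense_brca1, missense_brca2):
        in_domain = AnnotationBundle(
            missense_brca1.key, in_functional_domain=True, domain_name="BRCT"
        )
        outside = AnnotationBundle(missense_brca2.key, in_functional_domain=False)
        assert "PM1" in _triggered(missense_brca1, in_domain)
        assert "BP1" in _triggered(missense_brca2, outside)
        # PP2 is a gene policy: BRCA1 missense yes, BRCA2 missense no
        assert "PP2" in _triggered(missense_brca1, in_domain)
        assert "PP2" not in _triggered(missense_brca2, outside)
        assert "BP1" not in _triggered(missense_brca1, in_domain)

    def test_pm2_rare_and_absent(self, missense_brca2):
        absent = AnnotationBundle.empty(missense_brca2.key)
        ultra_rare = AnnotationBundle(
            missense_brca2.key, frequencies=(_freq(5e-6, an=10**7),)
        )
        modest = AnnotationBundle(
            missense_brca2.key, frequencies=(_freq(5e-5, an=10**7),)
        )
        assert "PM2" in _triggered(missense_brca2, absent)
        assert "PM2" in _triggered(missense_brca2, ultra_rare)
        assert "PM2" not in _triggered(missense_brca2, modest)

    def test_indel_codes_split_on_repeat_context(self, models):
        v = build_variant("BRCA2", "c.3067_3072del", "p.N1023_I1024del", None, models)
        plain = AnnotationBundle(v.key)
        repeat = AnnotationBundle(v.key, in_repeat_region=True)
        assert "PM4" in _triggered(v, plain) and "BP3" not in _triggered(v, plain)
        assert "BP3" in _triggered(v, repeat) and "PM4" not in _triggered(v, repeat)

    def test_insilico_thresholds(self, missense_brca2):
        high = AnnotationBundle(missense_brca2.key, insilico_deleterious_fraction=0.95)
        low = AnnotationBundle(missense_brca2.key, insilico_deleterious_fraction=0.05)
        mid = AnnotationBundle(missense_brca2.key, insilico_deleterious_fraction=0.5)
        assert "PP3" in _triggered(missense_brca2, high)
        assert "BP4" in _triggered(missense_brca2, low)
        assert {"PP3", "BP4"} & _triggered(missense_brca2, mid) == set()

    def test_frequency_codes_are_strict_and_exclusive(self, missense_brca2):
        common = AnnotationBundle(missense_brca2.key, frequencies=(_freq(0.015),))
        uncommon = AnnotationBundle(missense_brca2.key, frequencies=(_freq(0.001),))
        at_ba1 = AnnotationBundle(missense_brca2.key, frequencies=(_freq(0.01),))
        at_bs1 = AnnotationBundle(missense_brca2.key, frequencies=(_freq(0.0001),))
        assert "BA1" in _triggered(missense_brca2, common)
        assert "BS1" not in _triggered(missense_brca2, common)  # BA1 supersedes
        assert "BS1" in _triggered(missense_brca2, uncommon)
        assert "BA1" not in _triggered(missense_brca2, at_ba1)  # strict >
        assert "BS1" in _triggered(missense_brca2, at_ba1)
        assert "BS1" not in _triggered(missense_brca2, at_bs1)  # strict >

    def test_bs2_healthy_adults(self, missense_brca2):
        b = AnnotationBundle(missense_brca2.key, healthy_adult_observations=5)
        few = AnnotationBundle(missense_brca2.key, healthy_adult_observations=4)
        assert "BS2" in _triggered(missense_brca2, b)
        assert "BS2" not in _triggered(missense_brca2, few)

    def test_pp5_gated_by_consensus_arm(self, missense_brca2):
        b = AnnotationBundle(
            missense_brca2.key,
            assertions=(DatabaseAssertion("ENIGMA", Tier.PATHOGENIC, "expert_panel"),),
        )
        assert "PP5" not in _triggered(missense_brca2, b)
        cfg = EngineConfig(use_db_assertions=True)
        assert "PP5" in _triggered(missense_brca2, b, cfg)

    def test_rationales_cite_evidence(self, missense_brca1):
        b = AnnotationBundle(
            missense_brca1.key,
            functional=(FunctionalRecord("saturation_editing", "deleterious",
                                         "complete_deficiency", "sge_tag"),),
        )
        profile = evaluate_criteria(missense_brca1, b)
        ps3 = next(c for c in profile.codes if c.code == "PS3")
        assert ps3.triggered and "sge_tag" in ps3.rationale
        assert all(c.rationale for c in profile.codes if c.triggered)


class TestCombining:
    @pytest.mark.parametrize("counts,tier,conflict", [
        ({"PS": 1, "PM": 1}, Tier.LIKELY_PATHOGENIC, False),   # PS3 + PM2
        ({}, Tier.VUS, False),
        ({"BA": 1}, Tier.BENIGN, False),
        ({"PVS": 1, "PS": 1, "BA": 1}, Tier.VUS, True),
        ({"PVS": 1, "PS": 1}, Tier.PATHOGENIC, False),
        ({"PM": 1}, Tier.VUS, False),                          # lone PVS1@PM
        ({"BS": 1, "BP": 1}, Tier.LIKELY_BENIGN, False),
        ({"BS": 2}, Tier.BENIGN, False),
    ])
    def test_combine_examples(self, counts, tier, conflict):
        result = combine_counts(counts)
        assert (result.value, result.conflict_flag) == (tier, conflict)

    def test_truth_table_matches_independent_oracle(self):
        """Exhaustive agreement with a literally-enumerated clause oracle."""
        for counts in all_count_vectors():
            got = combine_counts(counts)
            assert (got.value, got.conflict_flag) == oracle_combine(counts), counts

    @given(
        pvs=st.integers(0, 1), ps=st.integers(0, 4), pm=st.integers(0, 6),
        pp=st.integers(0, 5), ba=st.integers(0, 1), bs=st.integers(0, 4),
        bp=st.integers(0, 7),
        bump=st.sampled_from(["PVS", "PS", "PM", "PP", "BA", "BS", "BP"]),
    )
    def test_adding_evidence_moves_monotonically(self, pvs, ps, pm, pp, ba, bs, bp, bump):
        counts = {"PVS": pvs, "PS": ps, "PM": pm, "PP": pp,
                  "BA": ba, "BS": bs, "BP": bp}
        before = combine_counts(counts).value
        bumped = dict(counts)
        bumped[bump] += 1
        after = combine_counts(bumped).value
        if bump in ("PVS", "PS", "PM", "PP"):
            assert after >= before
        else:
            assert after <= before


class TestClassifyAcmg:
    def test_fixture_tiers(self, fixture):
        by_key = {v.key: v for v in fixture.variants}
        expectations = {
            "BRCA1:c.4957G>T": Tier.LIKELY_PATHOGENIC,
            "BRCA1:c.3707A>G": Tier.VUS,
            "BRCA2:c.2350A>G": Tier.BENIGN,
            "BRCA2:c.6131G>T": Tier.BENIGN,
        }
        for key, tier in expectations.items():
            v = by_key[key]
            cls = classify_acmg(v, fixture.kb.bundle(key))
            assert cls.tier == tier, key
            assert cls.provenance == "ACMG"

    def test_determinism_byte_identical_profile(self, fixture):
        v = fixture.variants[0]
        b = fixture.kb.bundle(v.key)
        p1 = evaluate_criteria(v, b)
        p2 = evaluate_criteria(v, b)
        assert p1 == p2
        assert p1.describe() == p2.describe()

    def test_default_code_inventory_is_the_automated_set(self, fixture):
        v = fixture.variants[0]
        profile = evaluate_criteria(v, fixture.kb.bundle(v.key))
        codes = [c.code for c in profile.codes]
        assert len(codes) == 17
        assert "BP7" not in codes and "BP6" not in codes
        for case_level in ("PS2", "PS4", "PM3", "PM6", "PP1", "PP4", "BS4", "BP2", "BP5"):
            assert case_level not in codes

    def test_unknown_enabled_code_is_a_config_error(self):
        with pytest.raises(ConfigError):
            EngineConfig(enabled_codes=("PVS1", "BP7"))

    def test_cohort_restriction_drops_japanese_evidence(self, missense_brca2):
        b = AnnotationBundle(missense_brca2.key, frequencies=(_freq(0.02),))
        full = classify_acmg(missense_brca2, b)
        no_jp = classify_acmg(missense_brca2, b, EngineConfig().restrict_cohorts(
            {"east_asian", "global"}
        ))
        assert full.tier == Tier.BENIGN
        assert no_jp.tier == Tier.VUS


class TestBoundaries:
    def _single_freq_predicate(self, variant, check):
        an = 10**9

        def predicate(pf):
            b = AnnotationBundle(
                variant.key,
                frequencies=(PopulationFrequency("ToMMo", "japanese",
                                                 round(pf * an), an),),
            )
            return check(variant, b)

        return predicate

    def test_bs1_activates_strictly_above_its_threshold(self, missense_brca2, config):
        pred = self._single_freq_predicate(
            missense_brca2,
            lambda v, b: "BS1" in _triggered(v, b, config),
        )
        boundary = find_pf_boundary(pred)
        assert boundary == pytest.approx(config.bs1_pf, rel=1e-4)
        assert not pred(config.bs1_pf)  # exactly at the threshold: no trigger

    def test_stand_alone_benign_activates_strictly_above_one_percent(
        self, missense_brca2, config
    ):
        pred = self._single_freq_predicate(
            missense_brca2,
            lambda v, b: classify_acmg(v, b, config).tier == Tier.BENIGN,
        )
        boundary = find_pf_boundary(pred)
        assert boundary == pytest.approx(config.ba1_pf, rel=1e-4)
        assert not pred(config.ba1_pf)
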