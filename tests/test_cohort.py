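"""Phenotype definition, eligibility, pair extraction, descriptives."""

import numpy as np
import pandas as pd
import pytest

from pmdd.cohort import (CodeSet, apply_eligibility, classify_mdd, conversion_table,
                         descriptives, extract_pairs, normalize_code, summarize_counts)
from pmdd.exceptions import ConfigError, DataError
from pmdd.registry import GeneratorConfig, simulate_population


class TestCodes:
    @pytest.mark.parametrize("raw,norm", [
        ("f323", "F32.3"), ("F32.3", "F32.3"), ("F20", "F20"), ("f33", "F33")])
    def test_normalize(self, raw, norm):
        assert normalize_code(raw) == norm

    def test_empty_codeset_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            CodeSet("x", ())

    def test_default_sets_cover_both_psychotic_definitions(self, codesets):
        assert codesets["psychotic_mdd"].icd10 == ("F32.3", "F33.3")
        assert codesets["psychotic_mdd_f322"].icd10 == ("F32.2", "F32.3")
        assert "F20" not in codesets["other_psychotic"].icd10
        assert "F25" not in codesets["other_psychotic"].icd10


class TestClassify:
    def test_hand_traced_labels_main(self, toy_diagnoses, codesets):
        lab = classify_mdd(toy_diagnoses, codesets, definition="main")
        assert lab[1] == "psychotic_mdd"
        assert lab[2] == "psychotic_mdd"          # SCZ does not matter for main
        assert lab[3] == "non_psychotic_mdd"
        assert lab[4] == "non_psychotic_mdd"
        assert lab[5] == "none"
        assert lab[6] == "psychotic_mdd"

    def test_hand_traced_labels_restrictive(self, toy_diagnoses, codesets):
        lab = classify_mdd(toy_diagnoses, codesets, definition="restrictive")
        assert lab[2] == "none"   # psychotic with SCZ excluded
        assert lab[4] == "none"   # BD excluded from all MDD
        assert lab[6] == "none"   # BD excluded from all MDD
        assert lab[1] == "psychotic_mdd"
        assert lab[3] == "non_psychotic_mdd"

    def test_restrictive_subset_of_main(self, codesets):
        pop = simulate_population(GeneratorConfig(n_families=800, seed=31))
        main = classify_mdd(pop.diagnoses, codesets, "main")
        restr = classify_mdd(pop.diagnoses, codesets, "restrictive")
        m_psy = set(main.index[main == "psychotic_mdd"])
        r_psy = set(restr.index[restr == "psychotic_mdd"])
        assert r_psy <= m_psy
        m_mdd = set(main.index[main != "none"])
        r_mdd = set(restr.index[restr != "none"])
        assert r_mdd <= m_mdd
        # labels partition the diagnosed persons
        assert set(main.unique()) <= {"none", "non_psychotic_mdd", "psychotic_mdd"}

    def test_unknown_codes_rejected(self, codesets):
        bad = pd.DataFrame({"person_id": [1], "icd10": ["296.2"], "age": [30.0]})
        with pytest.raises(DataError, match="296"):
            classify_mdd(bad, codesets)


class TestEligibility:
    def test_death_before_20_excluded_null_retained(self):
        persons = pd.DataFrame({
            "person_id": [1, 2, 3],
            "birth_year": [1970, 1971, 1972],
            "age_at_death_or_emigration": [19.0, np.nan, 20.0],
        })
        out = apply_eligibility(persons)
        assert list(out["person_id"]) == [2, 3]

    def test_hand_traced_survivor_set(self):
        persons = pd.DataFrame({
            "person_id": range(10),
            "birth_year": [1950, 1960, 1970, 1980, 1990, 1995, 1960, 1970, 1980, 1990],
            "age_at_death_or_emigration":
                [np.nan, np.nan, 5.0, np.nan, 25.0, np.nan, 19.9, 20.0, np.nan, 1.0],
        })
        out = apply_eligibility(persons, birth_window=(1958, 1993))
        assert list(out["person_id"]) == [1, 3, 4, 7, 8]


class TestPairs:
    def test_hand_enumerated_pedigree(self, pedigree_12):
        pairs = extract_pairs(pedigree_12)
        by_kin = {k: {frozenset(t) for t in sub[["person_a", "person_b"]].to_numpy()}
                  for k, sub in pairs.groupby("kinship")}
        assert by_kin["full_sib"] == {frozenset((7, 8)), frozenset((3, 4))}
        # 9-10 full sibs born 11 years apart: dropped
        assert frozenset((9, 10)) not in by_kin["full_sib"]
        assert by_kin["half_sib"] == {frozenset((7, 12)), frozenset((8, 12))}
        # cousins: children of 3 x children of 4; gap filter does not apply
        assert by_kin["cousin"] == {frozenset((7, 9)), frozenset((7, 10)),
                                    frozenset((8, 9)), frozenset((8, 10)),
                                    frozenset((12, 9)), frozenset((12, 10))}

    def test_shares_match_kinship(self, pedigree_12):
        pairs = extract_pairs(pedigree_12, half_sib_kappa=0.25)
        share = pairs.set_index("kinship")[["a_share", "c_share"]].drop_duplicates()
        assert share.loc["full_sib"].tolist() == [0.5, 1.0]
        assert share.loc["half_sib"].tolist() == [0.25, 0.25]
        assert share.loc["cousin"].tolist() == [0.125, 0.0]

    def test_two_persons_sharing_mother_only_are_half_sibs(self):
        persons = pd.DataFrame({
            "person_id": [1, 2, 3, 10, 11],
            "family_id": 0, "sex": "F",
            "birth_year": [1960, 1961, 1935, 1933, 1934],
            "father_id": pd.array([10, 11, None, None, None], dtype="Int64"),
            "mother_id": pd.array([3, 3, None, None, None], dtype="Int64"),
            "age_at_death_or_emigration": np.nan,
        })
        pairs = extract_pairs(persons)
        assert pairs["kinship"].tolist() == ["half_sib"]

    def test_idempotent_and_unordered_once(self, pedigree_12):
        p1 = extract_pairs(pedigree_12)
        p2 = extract_pairs(pedigree_12)
        pd.testing.assert_frame_equal(p1, p2)
        key = p1.apply(lambda r: frozenset((r.person_a, r.person_b)), axis=1)
        assert key.is_unique

    def test_cycle_detection(self, pedigree_12):
        bad = pedigree_12.copy()
        bad.loc[bad["person_id"] == 1, "father_id"] = 7  # grandchild is ancestor
        with pytest.raises(DataError, match="cycle"):
            extract_pairs(bad)


class TestConversion:
    def _toy(self):
        # 8 persons: 4 psychotic, 4 non-psychotic, comorbidity timed by hand
        rows = [
            (1, "F32.3", 30), (1, "F31", 25),            # BD before
            (2, "F32.3", 30), (2, "F20", 35),            # SCZ after
            (3, "F33.3", 30), (3, "F23", 30),            # tie -> before
            (4, "F32.3", 30),                            # clean
            (5, "F32.1", 30), (5, "F31", 32),            # BD after
            (6, "F33.1", 30), (6, "F25", 28),            # SCZ before
            (7, "F32.1", 30), (7, "F23", 25), (7, "F23", 33),  # both sides
            (8, "F33.1", 30),
        ]
        return pd.DataFrame(rows, columns=["person_id", "icd10", "age"]).astype(
            {"age": float})

    def test_hand_computed_proportions(self, codesets):
        d = self._toy()
        lab = classify_mdd(d, codesets)
        conv = conversion_table(lab, d, codesets).set_index(["subtype", "group"])
        psy = conv.loc["psychotic_mdd"]
        assert psy.loc["bd", "prop_before"] == 0.25 and psy.loc["bd", "prop_after"] == 0.0
        assert psy.loc["scz_sad", "prop_after"] == 0.25
        assert psy.loc["other_psychotic", "prop_before"] == 0.25  # tie counts before
        non = conv.loc["non_psychotic_mdd"]
        assert non.loc["bd", "prop_after"] == 0.25
        assert non.loc["scz_sad", "prop_before"] == 0.25
        assert non.loc["other_psychotic", "prop_before"] == 0.25
        assert non.loc["other_psychotic", "prop_after"] == 0.25

    def test_tie_configurable(self, codesets):
        d = self._toy()
        lab = classify_mdd(d, codesets)
        conv = conversion_table(lab, d, codesets, ties="after") \
            .set_index(["subtype", "group"])
        assert conv.loc[("psychotic_mdd", "other_psychotic"), "prop_before"] == 0.0
        assert conv.loc[("psychotic_mdd", "other_psychotic"), "prop_after"] == 0.25

    def test_no_comorbidity_gives_zeros(self, codesets):
        d = pd.DataFrame({"person_id": [1, 2], "icd10": ["F32.3", "F32.1"],
                          "age": [30.0, 31.0]})
        lab = classify_mdd(d, codesets)
        conv = conversion_table(lab, d, codesets)
        assert (conv[["prop_before", "prop_after"]] == 0).all().all()

    def test_generator_conversion_probabilities_recovered(self, codesets):
        cfg = GeneratorConfig(n_families=4000, seed=37)
        # boost prevalence so the psychotic group is large enough
        cfg.traits[0] = cfg.traits[0].__class__(
            "psychotic_mdd", 0.3017, 0.0, 0.6983, 0.05, ("F32.3", "F33.3"),
            exclusive_with="nonpsychotic_mdd", exclusivity_rule="psychotic_mdd")
        pop = simulate_population(cfg)
        lab = classify_mdd(pop.diagnoses, codesets)
        conv = conversion_table(lab, pop.diagnoses, codesets) \
            .set_index(["subtype", "group"])
        n = conv.loc[("psychotic_mdd", "bd"), "n"]
        for group, p_after in (("scz_sad", 0.159), ("bd", 0.174),
                               ("other_psychotic", 0.219)):
            got = conv.loc[("psychotic_mdd", group), "prop_after"]
            assert got == pytest.approx(p_after, abs=4 * np.sqrt(p_after * (1 - p_after) / n))


class TestDescriptives:
    def test_empty_cohort(self):
        persons = pd.DataFrame({"person_id": [], "sex": []})
        lab = pd.Series(dtype=object)
        d = descriptives(persons, lab)
        assert d["n_total"] == 0 and d["pct_female"] is None

    def test_hand_counted_summary(self):
        persons = pd.DataFrame({
            "person_id": range(20),
            "sex": ["F"] * 11 + ["M"] * 9,
        })
        lab = pd.Series({0: "psychotic_mdd", 1: "non_psychotic_mdd",
                         2: "non_psychotic_mdd", 3: "none"})
        d = descriptives(persons, lab)
        assert d["n_total"] == 20
        assert d["pct_female"] == 55.0
        assert d["n_mdd_icd10"] == 3
        assert d["pct_psychotic_in_mdd"] == round(100 / 3, 2)
        assert d["pct_psychotic_in_population"] == 5.0

    def test_summarize_counts_rounding(self):
        s = summarize_counts(1000, 487, 100, 7)
        assert s["pct_psychotic_in_mdd"] == 7.0
        assert s["pct_female"] == 48.7
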