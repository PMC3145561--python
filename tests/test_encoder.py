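"""Category assignment, step/yield calculus and design-matrix construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastyield.encoder import (CategoryProfile, ModelVariant,
                                assign_categories, blended_yield,
                                build_design, carbon_yield, effective_steps,
                                encode_record, reclassify_ethanol)
from yeastyield.exceptions import DomainError

from conftest import make_record


class TestAssignCategories:
    @pytest.mark.parametrize("descriptor,expected", [
        # many modified genes, everything else baseline
        (dict(modified_genes=3, knockouts=0, medium="defined",
              intermediate="no", vessel="flask", aeration="aerobic"),
         ("C3", "C1", "C1", "C1", "C1", "C1")),
        # all-baseline reference condition
        (dict(modified_genes=0, knockouts=0, medium="defined",
              intermediate="no", vessel="flask", aeration="aerobic"),
         ("C1", "C1", "C1", "C1", "C1", "C1")),
        # each rule triggered independently
        (dict(modified_genes=2, knockouts=1, medium="rich",
              intermediate="yes", vessel="bioreactor", aeration="anaerobic"),
         ("C2", "C2", "C2", "C2", "C2", "C2")),
        # one modified gene is still C2; micro-aerobic counts as limited
        (dict(modified_genes=1, knockouts=0, medium="defined",
              intermediate="no", vessel="fed-batch", aeration="micro-aerobic"),
         ("C2", "C1", "C1", "C1", "C2", "C2")),
    ])
    def test_rules(self, descriptor, expected):
        assert assign_categories(descriptor).as_tuple() == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            assign_categories(modified_genes=-1, knockouts=0)

    def test_unknown_tokens_rejected(self):
        with pytest.raises(DomainError):
            assign_categories(modified_genes=0, knockouts=0, medium="weird")


class TestStepAndYieldCalculus:
    @pytest.mark.parametrize("sub,inter,int_add,expected", [
        (10, 0, "C2", 5.0),
        (4, None, "C1", 4.0),
        (2, 1, "C2", 1.5),
    ])
    def test_effective_steps(self, sub, inter, int_add, expected):
        assert effective_steps(sub, inter, int_add) == expected

    def test_effective_steps_requires_intermediate_when_fed(self):
        with pytest.raises(DomainError):
            effective_steps(4, None, "C2")

    @given(sub=st.floats(0, 30), inter=st.floats(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_effective_steps_between_min_and_max(self, sub, inter):
        eff = effective_steps(sub, inter, "C2")
        assert min(sub, inter) <= eff <= max(sub, inter)

    def test_carbon_yield_examples(self):
        # 1.5 mol ethanol (2 C) from 1 mol glucose (6 C)
        assert carbon_yield(1.5, 2, 1, 6) == pytest.approx(0.5)
        assert carbon_yield(1, 7, 1, 7) == 1.0
        assert carbon_yield(0.1, 3, 1, 6) == pytest.approx(0.05)

    def test_carbon_yield_above_one_warns_but_returns(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            assert carbon_yield(4, 2, 1, 6) == pytest.approx(4 / 3)

    def test_carbon_yield_rejects_nonpositive_substrate(self):
        with pytest.raises(DomainError):
            carbon_yield(1, 2, 0, 6)

    def test_blended_yield(self):
        assert blended_yield(0.2, 0.1) == pytest.approx(0.15)
        assert blended_yield(0.3, 0.3) == 0.3
        assert blended_yield(0.5, 0.0011) == pytest.approx(0.25055)

    def test_blended_yield_domain(self):
        with pytest.raises(DomainError):
            blended_yield(0.0, 0.5)
        with pytest.raises(DomainError):
            blended_yield(0.5, 1.2)


class TestReclassifyEthanol:
    def test_moves_core_steps_to_primary(self):
        r = make_record(product="Ethanol", pri_substrate=9, sec_substrate=2)
        out = reclassify_ethanol(r)
        assert (out.pri_substrate, out.sec_substrate) == (11, 0)

    def test_other_start_counts(self):
        r = make_record(product="ethanol", pri_substrate=8, sec_substrate=2)
        out = reclassify_ethanol(r)
        assert (out.pri_substrate, out.sec_substrate) == (10, 0)

    def test_non_ethanol_unchanged(self):
        r = make_record(product="Glycerol", pri_substrate=4, sec_substrate=2)
        assert reclassify_ethanol(r) is r

    def test_move_is_capped_at_available_secondary_steps(self):
        r = make_record(product="ethanol", pri_substrate=9, sec_substrate=1)
        out = reclassify_ethanol(r)
        assert (out.pri_substrate, out.sec_substrate) == (10, 0)

    @given(pri=st.floats(0, 20), sec=st.floats(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_conserves_total_steps(self, pri, sec):
        r = make_record(product="ethanol", pri_substrate=pri,
                        sec_substrate=sec)
        out = reclassify_ethanol(r)
        assert out.pri_substrate + out.sec_substrate == pytest.approx(pri + sec)
        assert out.sec_substrate >= 0


class TestBuildDesign:
    def test_model1_shape(self, corpus):
        design, response = build_design(corpus, ModelVariant.MODEL1_WITH_PRI)
        assert design.shape == (len(corpus), 10)
        assert list(design.columns) == [
            "Intercept", "PRI", "SEC", "OVE_C2", "OVE_C3", "KNO_C2",
            "NUT_C2", "INT_C2", "CUL_C2", "OXY_C2"]
        assert len(response) == len(corpus)

    def test_model2_drops_pri(self, corpus):
        design, _ = build_design(corpus, ModelVariant.MODEL2_NO_PRI)
        assert design.shape[1] == 9
        assert "PRI" not in design.columns

    def test_single_baseline_record(self):
        r = make_record(yield_c=0.01, pri_substrate=0, sec_substrate=0)
        design, response = build_design([r], ModelVariant.MODEL1_WITH_PRI)
        assert list(design.iloc[0]) == [1.0] + [0.0] * 9
        assert response.iloc[0] == pytest.approx(-2.0)

    def test_indicators_match_printed_dummies(self, corpus):
        """Encoded indicators reproduce the fixture's dummy columns exactly."""
        import pandas as pd

        from yeastyield.corpus import packaged_corpus_path
        raw = pd.read_csv(packaged_corpus_path(), sep="\t")
        design, _ = build_design(corpus, ModelVariant.MODEL1_WITH_PRI)
        for col in ("OVE_C2", "OVE_C3", "KNO_C2", "NUT_C2", "INT_C2",
                    "CUL_C2", "OXY_C2"):
            assert (design[col].to_numpy() == raw[col].to_numpy()).all()

    def test_effective_steps_used_for_dual_rows(self, corpus):
        design, _ = build_design(corpus, ModelVariant.MODEL1_WITH_PRI)
        idx = [i for i, r in enumerate(corpus) if r.product == "Cyanophycin"]
        assert all(design["PRI"].iloc[i] == 5.0 for i in idx)
        assert all(design["SEC"].iloc[i] == 1.5 for i in idx)

    def test_order_invariance_up_to_permutation(self, corpus):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(corpus))
        shuffled = [corpus[i] for i in perm]
        d1, y1 = build_design(corpus, ModelVariant.MODEL1_WITH_PRI)
        d2, y2 = build_design(shuffled, ModelVariant.MODEL1_WITH_PRI)
        assert np.allclose(d1.to_numpy()[perm], d2.to_numpy())
        assert np.allclose(y1.to_numpy()[perm], y2.to_numpy())

    def test_nonpositive_yield_rejected(self):
        r = make_record(yield_c=0.0)
        with pytest.raises(DomainError):
            build_design([r], ModelVariant.MODEL1_WITH_PRI)

    def test_empty_corpus_rejected(self):
        with pytest.raises(DomainError):
            build_design([], ModelVariant.MODEL1_WITH_PRI)

    def test_encode_record_log10(self):
        enc = encode_record(make_record(yield_c=0.001))
        assert enc.y_log10 == pytest.approx(-3.0)
        assert sum(enc.indicators) == 0


def test_category_profile_rejects_bad_levels():
    with pytest.raises(DomainError):
        CategoryProfile(ove="C4")
    with pytest.raises(DomainError):
        CategoryProfile(kno="C3")
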