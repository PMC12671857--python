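"""SLEDAI-2K scoring, LLDAS, flare classification, complement flag, exclusions."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ighvstrat.clinical import (
    ComplementReferenceRange,
    FlareCategory,
    FlareSnapshot,
    SLEDAI_2K_WEIGHTS,
    apply_exclusions,
    assess_lldas,
    classify_flare,
    flag_low_complement,
    score_sledai2k,
)
from ighvstrat.errors import MissingDataError

from conftest import make_patient


class TestSledai2k:
    def test_no_items_scores_zero(self):
        assert score_sledai2k({}) == 0

    def test_worked_example(self):
        items = {"arthritis": True, "rash": True, "low_complement": True,
                 "increased_dna_binding": True}
        assert score_sledai2k(items) == 10  # 4 + 2 + 2 + 2

    def test_all_items_maximum(self):
        assert score_sledai2k({k: True for k in SLEDAI_2K_WEIGHTS}) == 105

    def test_unknown_descriptor_named_in_error(self):
        with pytest.raises(ValueError, match="nephritis"):
            score_sledai2k({"nephritis": True})

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.dictionaries(st.sampled_from(sorted(SLEDAI_2K_WEIGHTS)), st.booleans()),
           st.sampled_from(sorted(SLEDAI_2K_WEIGHTS)))
    def test_monotone_in_items(self, items, extra):
        base = score_sledai2k(items)
        items2 = dict(items)
        items2[extra] = True
        assert score_sledai2k(items2) >= base


class TestLldas:
    def test_quiescent_patient_achieves(self):
        assert assess_lldas(make_patient(pga=0.0, prednisolone=5.0)) is True

    def test_sledai_above_four_fails_regardless(self):
        p = make_patient(items={"arthritis": True, "rash": True}, pga=0.0)  # score 6
        assert assess_lldas(p) is False

    def test_prednisolone_bound_is_7_5(self):
        p = make_patient(items={"low_complement": True}, pga=0.5, prednisolone=10.0)
        assert assess_lldas(p) is False
        assert assess_lldas(make_patient(pga=0.5, prednisolone=7.5)) is True

    def test_major_organ_activity_fails_even_at_low_score(self):
        p = make_patient(items={"haematuria": True}, pga=0.0)  # score 4
        assert assess_lldas(p) is False

    def test_serology_only_activity_is_allowed(self):
        p = make_patient(
            items={"low_complement": True, "increased_dna_binding": True}, pga=0.5
        )  # score 4, no major organ
        assert assess_lldas(p) is True

    def test_missing_fields_error_not_false(self):
        with pytest.raises(MissingDataError):
            assess_lldas(make_patient(pga=None))
        p = make_patient()
        p.medications.pop("prednisolone")
        with pytest.raises(MissingDataError):
            assess_lldas(p)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.dictionaries(st.sampled_from(sorted(SLEDAI_2K_WEIGHTS)), st.booleans()),
           st.floats(0, 3), st.floats(0, 20))
    def test_lldas_implies_sledai_at_most_four(self, items, pga, pred):
        p = make_patient(items=items, pga=pga, prednisolone=pred)
        if assess_lldas(p):
            assert score_sledai2k(items) <= 4


def snap(sledai=0, pga=0.0, pred=5.0, **kw):
    return FlareSnapshot(sledai=sledai, pga=pga, prednisolone_mg=pred, **kw)


class TestFlareIndex:
    def test_identical_snapshots_are_no_flare(self):
        s = snap(sledai=4, pga=1.0)
        assert classify_flare(s, s) is FlareCategory.NONE

    def test_moderate_sledai_rise_is_mild_moderate(self):
        assert (
            classify_flare(snap(sledai=2, pga=0.5), snap(sledai=6, pga=1.0))
            is FlareCategory.MILD_MODERATE
        )

    def test_large_sledai_rise_is_severe(self):
        assert classify_flare(snap(sledai=4), snap(sledai=18)) is FlareCategory.SEVERE

    def test_new_major_organ_item_is_severe(self):
        prev = snap(sledai=0, items={})
        curr = snap(sledai=8, items={"vasculitis": True})
        assert classify_flare(prev, curr) is FlareCategory.SEVERE

    def test_high_dose_steroid_increase_is_severe(self):
        # weight known: 0.5 mg/kg x 60 kg = 30 mg threshold
        prev = snap(pred=5.0)
        curr = snap(pred=35.0, weight_kg=60.0)
        assert classify_flare(prev, curr) is FlareCategory.SEVERE
        # small increase stays mild/moderate
        assert classify_flare(prev, snap(pred=12.0, weight_kg=60.0)) \
            is FlareCategory.MILD_MODERATE

    def test_pga_triggers(self):
        assert classify_flare(snap(pga=0.5), snap(pga=2.8)) is FlareCategory.SEVERE
        assert classify_flare(snap(pga=0.5), snap(pga=1.6)) is FlareCategory.MILD_MODERATE

    def test_incomplete_snapshot_errors(self):
        with pytest.raises(MissingDataError):
            classify_flare(snap(), FlareSnapshot(sledai=None, pga=1.0, prednisolone_mg=5.0))


class TestLowComplement:
    REFS = ComplementReferenceRange(c3_low=73.0, c4_low=11.0)

    def test_boundary_is_strictly_below(self):
        assert flag_low_complement(73.0, 20.0, self.REFS) is False
        assert flag_low_complement(72.9, 20.0, self.REFS) is True

    def test_or_rule(self):
        assert flag_low_complement(60.0, 20.0, self.REFS) is True
        assert flag_low_complement(90.0, 5.0, self.REFS) is True
        assert flag_low_complement(90.0, 20.0, self.REFS) is False

    def test_single_analyte(self):
        assert flag_low_complement(None, 5.0, self.REFS) is True
        assert flag_low_complement(None, 20.0, self.REFS) is False

    def test_both_absent_is_error(self):
        with pytest.raises(MissingDataError):
            flag_low_complement(None, float("nan"), self.REFS)

    def test_truth_table_enumeration(self):
        """Exhaustive presence x below-range enumeration matches the OR rule."""
        c3_vals = {True: 50.0, False: 100.0}
        c4_vals = {True: 5.0, False: 20.0}
        for c3_present, c4_present in itertools.product([True, False], repeat=2):
            if not (c3_present or c4_present):
                continue
            for c3_low, c4_low in itertools.product([True, False], repeat=2):
                c3 = c3_vals[c3_low] if c3_present else None
                c4 = c4_vals[c4_low] if c4_present else None
                expected = (c3_present and c3_low) or (c4_present and c4_low)
                assert flag_low_complement(c3, c4, self.REFS) == expected


class TestExclusions:
    def test_prednisolone_21_inclusive(self):
        kept, log = apply_exclusions([make_patient(prednisolone=21.0)])
        assert kept == [] and len(log) == 1

    def test_prednisolone_20_retained(self):
        kept, log = apply_exclusions([make_patient(prednisolone=20.0)])
        assert len(kept) == 1 and log == []

    def test_cohort_handcount(self):
        cohort = [
            make_patient("A"),
            make_patient("B", meds={"cyc_within_1y": True}),
            make_patient("C"),
            make_patient("D", prednisolone=25.0),
            make_patient("E"),
        ]
        kept, log = apply_exclusions(cohort)
        assert [p.patient_id for p in kept] == ["A", "C", "E"]
        assert {e["patient_id"] for e in log} == {"B", "D"}
        rules = {e["patient_id"]: e["rule"] for e in log}
        assert "cyclophosphamide" in rules["B"]
        assert "prednisolone" in rules["D"]
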