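"""Rule-engine tests: criterion semantics, exclusions, and an exhaustive
truth-table comparison against an independently written brute-force oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from opioid_subtypes.phenotype import (
    CodeSetRegistry,
    build_cohort,
    criterion_icd,
    criterion_polysubstance,
    criterion_unexplained_opiate,
    evaluate_all,
    evaluate_encounter,
    uds_eligible,
)

from conftest import EMPTY_DX, EMPTY_MEDS, med_event, one_encounter, uds_panel

REG = CodeSetRegistry()
MISUSE_CODE = sorted(REG.codes("opioid_misuse_icd"))[0]
PAIN_CODE = sorted(REG.codes("chronic_pain"))[0]


class TestUdsEligibility:
    def test_no_medication_events_is_vacuously_eligible(self):
        panel = uds_panel().iloc[0]
        assert uds_eligible(panel, EMPTY_MEDS) is True

    @pytest.mark.parametrize(
        "drug,source,event_time,expected",
        [
            # dispensed 1h before the order blocks eligibility
            ("opioid", "inpatient_dispense", "2010-01-01 09:00", False),
            ("benzodiazepine", "inpatient_dispense", "2010-01-01 09:00", False),
            # dispensed after the order does not
            ("opioid", "inpatient_dispense", "2010-01-01 11:00", True),
            # admission-list entries never affect timing eligibility
            ("benzodiazepine", "admission_mar", None, True),
            ("opioid", "admission_mar", None, True),
            # non-screen drug classes are irrelevant
            ("amphetamine", "inpatient_dispense", "2010-01-01 09:00", True),
            # a tie counts as dispensed-before
            ("opioid", "inpatient_dispense", "2010-01-01 10:00", False),
        ],
    )
    def test_dispense_timing_rule(self, drug, source, event_time, expected):
        panel = uds_panel().iloc[0]
        meds = pd.DataFrame([med_event(drug_class=drug, source=source, event_time=event_time)])
        assert uds_eligible(panel, meds) is expected

    def test_dispense_missing_time_raises(self):
        meds = pd.DataFrame([med_event(source="inpatient_dispense", event_time=None)])
        with pytest.raises(ValueError, match="missing event_time"):
            uds_eligible(uds_panel().iloc[0], meds)


class TestCriteria:
    def test_opiate_plus_cocaine_is_polysubstance(self):
        panel = uds_panel(opiate_pos=True, cocaine_pos=True).iloc[0]
        assert criterion_polysubstance(panel, EMPTY_MEDS)

    def test_benzo_on_admission_list_does_not_count(self):
        panel = uds_panel(opiate_pos=True, benzo_pos=True).iloc[0]
        meds = pd.DataFrame([med_event(drug_class="benzodiazepine", source="admission_mar")])
        assert not criterion_polysubstance(panel, meds)
        assert criterion_polysubstance(panel, EMPTY_MEDS)

    def test_opiate_gate(self):
        panel = uds_panel(opiate_pos=False, cocaine_pos=True, pcp_pos=True,
                          benzo_pos=True, amphetamine_pos=True).iloc[0]
        assert not criterion_polysubstance(panel, EMPTY_MEDS)

    def test_unexplained_opiate(self):
        panel = uds_panel(opiate_pos=True).iloc[0]
        assert criterion_unexplained_opiate(panel, EMPTY_MEDS)
        meds = pd.DataFrame([med_event(drug_class="opioid", source="admission_mar")])
        assert not criterion_unexplained_opiate(panel, meds)
        # inpatient dispensing after the order is not an admission prescription
        meds2 = pd.DataFrame([med_event(source="inpatient_dispense", event_time="2010-01-01 11:00")])
        assert criterion_unexplained_opiate(panel, meds2)

    def test_icd_criterion(self):
        assert criterion_icd(pd.DataFrame([{"encounter_id": 1, "code": MISUSE_CODE}]), REG)
        assert not criterion_icd(pd.DataFrame([{"encounter_id": 1, "code": PAIN_CODE}]), REG)
        dup = pd.DataFrame([{"encounter_id": 1, "code": MISUSE_CODE}] * 3)
        assert criterion_icd(dup, REG)  # idempotent under duplicates

    def test_unknown_tag_raises(self):
        with pytest.raises(KeyError, match="unknown code-set tag"):
            REG.codes("nonexistent_tag")


class TestEvaluateEncounter:
    def test_transfer_excluded_even_when_criteria_hold(self):
        enc = one_encounter(is_transfer=True)
        dx = pd.DataFrame([{"encounter_id": 1, "code": MISUSE_CODE}])
        ev = evaluate_encounter(enc, uds_panel(opiate_pos=True, cocaine_pos=True), EMPTY_MEDS, dx, REG)
        assert ev.exclusion_reason == "transfer"
        assert not ev.is_misuse
        assert ev.criterion1 and ev.criterion3

    def test_pediatric_excluded(self):
        enc = one_encounter(age_years=17)
        dx = pd.DataFrame([{"encounter_id": 1, "code": MISUSE_CODE}])
        ev = evaluate_encounter(enc, uds_panel(), EMPTY_MEDS, dx, REG)
        assert ev.exclusion_reason == "pediatric"
        assert not ev.is_misuse

    def test_eligible_cocaine_panel_flags(self):
        ev = evaluate_encounter(one_encounter(), uds_panel(opiate_pos=True, cocaine_pos=True),
                                EMPTY_MEDS, EMPTY_DX, REG)
        assert ev.criterion1 and ev.is_misuse

    def test_adding_ineligible_panel_changes_nothing(self):
        # an opiate+cocaine panel poisoned by a pre-order opioid dispense
        base = evaluate_encounter(one_encounter(), uds_panel(), EMPTY_MEDS, EMPTY_DX, REG)
        poisoned = uds_panel(order_time="2010-01-02 10:00", opiate_pos=True, cocaine_pos=True)
        meds = pd.DataFrame([med_event(source="inpatient_dispense", event_time="2010-01-02 09:00")])
        both = pd.concat([uds_panel(), poisoned], ignore_index=True)
        after = evaluate_encounter(one_encounter(), both, meds, EMPTY_DX, REG)
        assert (base.criterion1, base.criterion2, base.is_misuse) == \
               (after.criterion1, after.criterion2, after.is_misuse)

    def test_idempotent(self):
        enc = one_encounter()
        uds = uds_panel(opiate_pos=True)
        a = evaluate_encounter(enc, uds, EMPTY_MEDS, EMPTY_DX, REG)
        b = evaluate_encounter(enc, uds, EMPTY_MEDS, EMPTY_DX, REG)
        assert a == b


# ---------------------------------------------------------------------------
# Exhaustive truth-table oracle
# ---------------------------------------------------------------------------

_MED_STATES = ("absent", "admission_mar", "dispense_before", "dispense_after")


def _oracle(flags, med_state, icd):
    """Independent brute-force transcription of the misuse definition."""
    opiate, cocaine, pcp, benzo, amph = flags
    op_med, bz_med, am_med = med_state
    eligible = op_med != "dispense_before" and bz_med != "dispense_before"
    c1 = c2 = False
    if eligible:
        unexplained_benzo = benzo and bz_med != "admission_mar"
        unexplained_amph = amph and am_med != "admission_mar"
        c1 = opiate and (pcp or cocaine or unexplained_benzo or unexplained_amph)
        c2 = opiate and op_med != "admission_mar"
    return c1, c2, icd, (c1 or c2 or icd)


def _build_universe():
    encounters, uds_rows, med_rows, dx_rows, expected = [], [], [], [], {}
    eid = 0
    order = pd.Timestamp("2010-01-01 10:00")
    for flags in itertools.product([False, True], repeat=5):
        for med_state in itertools.product(_MED_STATES, repeat=3):
            for icd in (False, True):
                eid += 1
                encounters.append(one_encounter(encounter_id=eid).to_dict())
                uds_rows.append(dict(encounter_id=eid, order_time=order,
                                     opiate_pos=flags[0], cocaine_pos=flags[1],
                                     pcp_pos=flags[2], benzo_pos=flags[3],
                                     amphetamine_pos=flags[4]))
                for drug, state in zip(("opioid", "benzodiazepine", "amphetamine"), med_state):
                    if state == "absent":
                        continue
                    if state == "admission_mar":
                        med_rows.append(med_event(eid, drug, "admission_mar"))
                    elif state == "dispense_before":
                        med_rows.append(med_event(eid, drug, "inpatient_dispense", "2010-01-01 09:00"))
                    else:
                        med_rows.append(med_event(eid, drug, "inpatient_dispense", "2010-01-01 11:00"))
                if icd:
                    dx_rows.append(dict(encounter_id=eid, code=MISUSE_CODE))
                expected[eid] = _oracle(flags, med_state, icd)
    return (pd.DataFrame(encounters), pd.DataFrame(uds_rows), pd.DataFrame(med_rows),
            pd.DataFrame(dx_rows), expected)


def test_truth_table_matches_bruteforce_oracle():
    """Vectorized engine agrees with the brute-force rules on all 4096
    combinations of UDS flags x medication states x ICD tag."""
    encounters, uds, meds, dx, expected = _build_universe()
    # note: amphetamine dispense-before does NOT poison eligibility; only
    # opioid/benzodiazepine do — encoded in the oracle via eligibility rule
    result = evaluate_all(encounters, uds, meds, dx, REG).set_index("encounter_id")
    for eid, (c1, c2, c3, mis) in expected.items():
        row = result.loc[eid]
        assert (bool(row["criterion1"]), bool(row["criterion2"]),
                bool(row["criterion3"]), bool(row["is_misuse"])) == (c1, c2, c3, mis), eid


def test_per_encounter_agrees_with_vectorized_on_sample():
    encounters, uds, meds, dx, _ = _build_universe()
    result = evaluate_all(encounters, uds, meds, dx, REG).set_index("encounter_id")
    rng = np.random.default_rng(5)
    for eid in rng.choice(encounters["encounter_id"].to_numpy(), size=120, replace=False):
        enc = encounters[encounters["encounter_id"] == eid].iloc[0]
        ev = evaluate_encounter(enc, uds[uds["encounter_id"] == eid],
                                meds[meds["encounter_id"] == eid],
                                dx[dx["encounter_id"] == eid], REG)
        row = result.loc[eid]
        assert ev.criterion1 == bool(row["criterion1"])
        assert ev.criterion2 == bool(row["criterion2"])
        assert ev.is_misuse == bool(row["is_misuse"])


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _toy_evaluations(eids, flags):
    return pd.DataFrame({
        "encounter_id": eids, "criterion1": flags, "criterion2": False,
        "criterion3": False, "is_misuse": flags, "exclusion_reason": None,
    })


def test_build_cohort_modes():
    encounters = pd.DataFrame([
        one_encounter(1, patient_id=1, admit_time=pd.Timestamp("2010-01-01")).to_dict(),
        one_encounter(2, patient_id=1, admit_time=pd.Timestamp("2011-01-01")).to_dict(),
        one_encounter(3, patient_id=1, admit_time=pd.Timestamp("2012-01-01")).to_dict(),
        one_encounter(4, patient_id=2, admit_time=pd.Timestamp("2010-06-01")).to_dict(),
    ])
    evals = _toy_evaluations([1, 2, 3, 4], [True, True, True, False])
    enc_level = build_cohort(encounters, evals, "encounter_level")
    assert len(enc_level) == int(evals["is_misuse"].sum()) == 3
    pat_level = build_cohort(encounters, evals, "patient_level")
    assert len(pat_level) == 1
    assert pat_level["encounter_id"].tolist() == [3]  # latest admit wins


def test_empty_cohort_is_graceful():
    encounters = pd.DataFrame([one_encounter(1).to_dict()])
    evals = _toy_evaluations([1], [False])
    assert len(build_cohort(encounters, evals)) == 0


def test_orphan_rows_rejected():
    encounters = pd.DataFrame([one_encounter(1).to_dict()])
    uds = uds_panel(encounter_id=99)
    with pytest.raises(ValueError, match="unknown encounters"):
        evaluate_all(encounters, uds, EMPTY_MEDS, EMPTY_DX, REG)


def test_recovery_reported_on_synthetic_cohort(small_cohort):
    """Sensitivity/specificity against planted ground truth are computed and
    sit where the generator's construction puts them (sensitivity ~1,
    specificity ~1 - background false-positive rate)."""
    from opioid_subtypes.phenotype import misuse_confusion

    cfg, tables = small_cohort
    ev = evaluate_all(tables.encounters, tables.uds, tables.medications, tables.diagnoses, REG)
    stats = misuse_confusion(ev, tables.ground_truth)
    assert stats["sensitivity"] > 0.995
    assert stats["specificity"] > 0.99
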