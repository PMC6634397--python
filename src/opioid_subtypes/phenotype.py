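"""Rule-based opioid-misuse phenotyping over encounter-level EHR tables.

An encounter is flagged as opioid misuse when any of three criteria holds:

1. *Polysubstance*: an eligible urine drug screen positive for an opiate
   together with phencyclidine or cocaine, or with a benzodiazepine or
   amphetamine that is absent from the admission medication list.
2. *Unexplained opiate*: an eligible screen positive for an opiate with no
   opioid prescription on the admission medication list.
3. *Diagnosis code*: any diagnosis whose code carries the
   ``opioid_misuse_icd`` tag in the code-set registry.

A screen is *eligible* only if no opioid or benzodiazepine was dispensed by
the inpatient pharmacy at or before the time the screen was ordered (a
dispense at exactly the order time counts as dispensed-before).  Hospital
transfers, patients under 18, and non-ED/non-inpatient encounters are
excluded.  "Admission medication list" means ``source == "admission_mar"``;
inpatient dispensing matters only for screen-eligibility timing.

Both a per-encounter API (:func:`evaluate_encounter` and the individual
criterion functions) and a vectorized whole-table path
(:func:`evaluate_all`) are provided; they implement identical semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .config import default_registry

__all__ = [
    "CodeSetRegistry",
    "MisuseEvaluation",
    "uds_eligible",
    "criterion_polysubstance",
    "criterion_unexplained_opiate",
    "criterion_icd",
    "evaluate_encounter",
    "evaluate_all",
    "build_cohort",
    "misuse_confusion",
]

_SCREEN_CLASSES = frozenset({"opioid", "benzodiazepine"})


@dataclass(frozen=True)
class CodeSetRegistry:
    """Mapping from code-set label to a set of diagnosis-code strings."""

    code_sets: dict[str, frozenset[str]] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        for label, codes in self.code_sets.items():
            if not isinstance(label, str):
                raise ValueError("code-set labels must be strings")
            object.__setattr__(
                self, "code_sets", {k: frozenset(v) for k, v in self.code_sets.items()}
            )

    def codes(self, label: str) -> frozenset[str]:
        try:
            cs = self.code_sets[label]
        except KeyError:
            raise KeyError(f"unknown code-set tag: {label!r}") from None
        if not cs:
            raise ValueError(f"code set {label!r} is empty")
        return cs

    @classmethod
    def from_yaml(cls, path: str) -> "CodeSetRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: frozenset(v) for k, v in raw.items()})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: sorted(v) for k, v in self.code_sets.items()}, fh)


@dataclass
class MisuseEvaluation:
    encounter_id: int
    eligible_uds_ids: frozenset
    criterion1: bool
    criterion2: bool
    criterion3: bool
    is_misuse: bool
    exclusion_reason: str | None = None


def _check_dispense_times(meds: pd.DataFrame) -> None:
    disp = meds[meds["source"] == "inpatient_dispense"]
    bad = disp[disp["event_time"].isna()]
    if len(bad):
        ids = bad["encounter_id"].tolist()
        raise ValueError(f"inpatient_dispense events missing event_time for encounters {ids}")


def uds_eligible(uds_row: pd.Series, meds: pd.DataFrame) -> bool:
    """True iff no opioid/benzodiazepine pharmacy dispense at or before the order.

    Ties (dispense at exactly the order time) count as dispensed-before.
    """
    if len(meds) == 0:
        return True
    _check_dispense_times(meds)
    disp = meds[(meds["source"] == "inpatient_dispense") & meds["drug_class"].isin(_SCREEN_CLASSES)]
    if len(disp) == 0:
        return True
    return not bool((disp["event_time"] <= uds_row["order_time"]).any())


def _on_admission_list(meds: pd.DataFrame, drug_class: str) -> bool:
    if len(meds) == 0:
        return False
    sub = meds[(meds["source"] == "admission_mar") & (meds["drug_class"] == drug_class)]
    return len(sub) > 0


def criterion_polysubstance(uds_row: pd.Series, meds: pd.DataFrame) -> bool:
    """Opiate positive plus an unexplained co-positive (PCP/cocaine always count;
    benzodiazepine/amphetamine only when absent from the admission list)."""
    if not bool(uds_row["opiate_pos"]):
        return False
    if bool(uds_row["pcp_pos"]) or bool(uds_row["cocaine_pos"]):
        return True
    if bool(uds_row["benzo_pos"]) and not _on_admission_list(meds, "benzodiazepine"):
        return True
    if bool(uds_row["amphetamine_pos"]) and not _on_admission_list(meds, "amphetamine"):
        return True
    return False


def criterion_unexplained_opiate(uds_row: pd.Series, meds: pd.DataFrame) -> bool:
    """Opiate positive with no opioid on the admission medication list."""
    return bool(uds_row["opiate_pos"]) and not _on_admission_list(meds, "opioid")


def criterion_icd(diagnoses: pd.DataFrame, registry: CodeSetRegistry) -> bool:
    """Any diagnosis code tagged ``opioid_misuse_icd`` (idempotent in duplicates)."""
    codes = registry.codes("opioid_misuse_icd")
    if len(diagnoses) == 0:
        return False
    return bool(diagnoses["code"].isin(codes).any())


def _exclusion_reason(encounter: pd.Series) -> str | None:
    if bool(encounter.get("is_transfer", False)):
        return "transfer"
    if int(encounter["age_years"]) < 18:
        return "pediatric"
    if str(encounter.get("encounter_type", "inpatient")) not in ("ED", "inpatient"):
        return "not_ed_or_inpatient"
    return None


def evaluate_encounter(
    encounter: pd.Series,
    uds: pd.DataFrame,
    meds: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: CodeSetRegistry | None = None,
) -> MisuseEvaluation:
    """Evaluate one encounter; criteria are satisfied if *any* eligible panel
    satisfies them."""
    registry = registry or CodeSetRegistry()
    _check_dispense_times(meds)
    reason = _exclusion_reason(encounter)
    eligible_ids = []
    c1 = c2 = False
    for idx, row in uds.iterrows():
        if uds_eligible(row, meds):
            eligible_ids.append(idx)
            c1 = c1 or criterion_polysubstance(row, meds)
            c2 = c2 or criterion_unexplained_opiate(row, meds)
    c3 = criterion_icd(diagnoses, registry)
    is_misuse = (c1 or c2 or c3) and reason is None
    return MisuseEvaluation(
        encounter_id=encounter["encounter_id"],
        eligible_uds_ids=frozenset(eligible_ids),
        criterion1=c1,
        criterion2=c2,
        criterion3=c3,
        is_misuse=is_misuse,
        exclusion_reason=reason,
    )


def _check_orphans(encounters: pd.DataFrame, table: pd.DataFrame, name: str) -> None:
    known = set(encounters["encounter_id"])
    orphan = sorted(set(table["encounter_id"]) - known)
    if orphan:
        raise ValueError(f"{name} rows reference unknown encounters: {orphan[:20]}")


def evaluate_all(
    encounters: pd.DataFrame,
    uds: pd.DataFrame,
    meds: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: CodeSetRegistry | None = None,
) -> pd.DataFrame:
    """Vectorized evaluation of every encounter.

    Returns a frame keyed by ``encounter_id`` with columns ``criterion1..3``,
    ``is_misuse`` and ``exclusion_reason`` (None when not excluded).
    """
    registry = registry or CodeSetRegistry()
    _check_dispense_times(meds)
    for tbl, name in ((uds, "uds"), (meds, "medication"), (diagnoses, "diagnosis")):
        _check_orphans(encounters, tbl, name)

    eid = encounters["encounter_id"].to_numpy()
    n = len(encounters)

    reason = np.full(n, None, dtype=object)
    not_ed_ip = ~encounters["encounter_type"].isin(["ED", "inpatient"]).to_numpy()
    reason[not_ed_ip] = "not_ed_or_inpatient"
    reason[(encounters["age_years"] < 18).to_numpy()] = "pediatric"
    reason[encounters["is_transfer"].to_numpy(dtype=bool)] = "transfer"

    # admission-list flags per encounter
    adm = meds[meds["source"] == "admission_mar"]
    adm_flags = {}
    for drug in ("opioid", "benzodiazepine", "amphetamine"):
        ids = set(adm.loc[adm["drug_class"] == drug, "encounter_id"])
        adm_flags[drug] = pd.Series(eid).isin(ids).to_numpy()
    adm_df = pd.DataFrame(
        {"encounter_id": eid,
         "opioid_adm": adm_flags["opioid"],
         "benzo_adm": adm_flags["benzodiazepine"],
         "amph_adm": adm_flags["amphetamine"]}
    )

    # panel eligibility: earliest opioid/benzo dispense per encounter
    disp = meds[(meds["source"] == "inpatient_dispense") & meds["drug_class"].isin(_SCREEN_CLASSES)]
    dmin = disp.groupby("encounter_id")["event_time"].min()
    panels = uds.merge(adm_df, on="encounter_id", how="left")
    panels["first_dispense"] = panels["encounter_id"].map(dmin)
    panels["eligible"] = ~(panels["first_dispense"] <= panels["order_time"])

    elig = panels[panels["eligible"]]
    p_c1 = elig["opiate_pos"].to_numpy(dtype=bool) & (
        elig["pcp_pos"].to_numpy(dtype=bool)
        | elig["cocaine_pos"].to_numpy(dtype=bool)
        | (elig["benzo_pos"].to_numpy(dtype=bool) & ~elig["benzo_adm"].to_numpy(dtype=bool))
        | (elig["amphetamine_pos"].to_numpy(dtype=bool) & ~elig["amph_adm"].to_numpy(dtype=bool))
    )
    p_c2 = elig["opiate_pos"].to_numpy(dtype=bool) & ~elig["opioid_adm"].to_numpy(dtype=bool)
    c1_ids = set(elig.loc[p_c1, "encounter_id"])
    c2_ids = set(elig.loc[p_c2, "encounter_id"])
    c3_ids = set(diagnoses.loc[diagnoses["code"].isin(registry.codes("opioid_misuse_icd")), "encounter_id"])

    eid_s = pd.Series(eid)
    c1 = eid_s.isin(c1_ids).to_numpy()
    c2 = eid_s.isin(c2_ids).to_numpy()
    c3 = eid_s.isin(c3_ids).to_numpy()
    excluded = np.array([r is not None for r in reason])
    return pd.DataFrame({
        "encounter_id": eid,
        "criterion1": c1,
        "criterion2": c2,
        "criterion3": c3,
        "is_misuse": (c1 | c2 | c3) & ~excluded,
        "exclusion_reason": reason,
    })


def build_cohort(
    encounters: pd.DataFrame,
    evaluations: pd.DataFrame,
    mode: str = "encounter_level",
) -> pd.DataFrame:
    """Analysis cohort of misuse encounters.

    ``patient_level`` keeps, per patient, the misuse encounter with the
    latest admit time (sensitivity analysis); ``encounter_level`` keeps all.
    """
    if mode not in ("encounter_level", "patient_level"):
        raise ValueError(f"unknown mode: {mode!r}")
    merged = encounters.merge(
        evaluations[["encounter_id", "criterion1", "criterion2", "criterion3", "is_misuse"]],
        on="encounter_id",
    )
    cohort = merged[merged["is_misuse"].astype(bool)].reset_index(drop=True)
    if mode == "patient_level" and len(cohort):
        cohort = (
            cohort.sort_values(["patient_id", "admit_time", "encounter_id"], kind="stable")
            .groupby("patient_id", as_index=False)
            .last()
        )
        cohort = cohort.sort_values("encounter_id", kind="stable").reset_index(drop=True)
    return cohort


def misuse_confusion(evaluations: pd.DataFrame, ground_truth: pd.DataFrame) -> dict[str, float]:
    """Sensitivity/specificity of the flag against planted ground truth."""
    m = evaluations.merge(ground_truth, on="encounter_id")
    pred = m["is_misuse"].to_numpy(dtype=bool)
    truth = m["true_misuse"].to_numpy(dtype=bool)
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }
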