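"""Build the class-defining indicator matrix from the raw EHR tables.

Ten items in eight named variable groups: the five-level age band; six
binary diagnosis-tag items (liver disease, alcohol use disorder, psychoses,
depression, chronic pain, opioid-related hospitalization code); and three
binary urine-drug-screen items computed over *eligible* panels only —
unexplained opiate positive (no opioid on the admission med list),
cocaine positive, and unexplained benzodiazepine positive (no
benzodiazepine on the admission list).  A screen that was never ordered, or
whose panels are all ineligible, contributes level 0 to each UDS item.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AGE_BANDS
from .phenotype import CodeSetRegistry, _SCREEN_CLASSES, _check_dispense_times

__all__ = ["age_band_index", "build_indicator_matrix"]

_BAND_EDGES = np.array([b[0] for b in AGE_BANDS][1:])  # 26, 36, 46, 56


def age_band_index(age_years) -> np.ndarray:
    """Map ages to the five study bands (<=25, 26-35, 36-45, 46-55, >=56)."""
    return np.searchsorted(_BAND_EDGES, np.asarray(age_years), side="right").astype(np.int64)


_TAG_ITEMS = (
    ("liver", "liver"),
    ("alcohol_use_disorder", "alcohol_use_disorder"),
    ("psychoses", "psychoses"),
    ("depression", "depression"),
    ("chronic_pain", "chronic_pain"),
    ("opioid_misuse_icd", "opioid_misuse_icd"),
)


def build_indicator_matrix(
    cohort: pd.DataFrame,
    uds: pd.DataFrame,
    meds: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: CodeSetRegistry | None = None,
) -> pd.DataFrame:
    """Indicator matrix (one row per cohort encounter, integer levels).

    Returns a DataFrame indexed by ``encounter_id`` with the ten item
    columns in canonical order; values are 0-based level indices.
    """
    registry = registry or CodeSetRegistry()
    _check_dispense_times(meds)
    eid = cohort["encounter_id"].to_numpy()
    eid_s = pd.Series(eid)
    out = pd.DataFrame(index=pd.Index(eid, name="encounter_id"))
    out["age_band"] = age_band_index(cohort["age_years"].to_numpy())

    for item, tag in _TAG_ITEMS:
        tagged = set(diagnoses.loc[diagnoses["code"].isin(registry.codes(tag)), "encounter_id"])
        out[item] = eid_s.isin(tagged).to_numpy().astype(np.int64)

    adm = meds[meds["source"] == "admission_mar"]
    opioid_adm = set(adm.loc[adm["drug_class"] == "opioid", "encounter_id"])
    benzo_adm = set(adm.loc[adm["drug_class"] == "benzodiazepine", "encounter_id"])
    disp = meds[(meds["source"] == "inpatient_dispense") & meds["drug_class"].isin(_SCREEN_CLASSES)]
    dmin = disp.groupby("encounter_id")["event_time"].min()

    panels = uds[uds["encounter_id"].isin(set(eid))].copy()
    panels["first_dispense"] = panels["encounter_id"].map(dmin)
    panels = panels[~(panels["first_dispense"] <= panels["order_time"])]
    op_unexp = set(
        panels.loc[
            panels["opiate_pos"].astype(bool) & ~panels["encounter_id"].isin(opioid_adm),
            "encounter_id",
        ]
    )
    cocaine = set(panels.loc[panels["cocaine_pos"].astype(bool), "encounter_id"])
    benzo_unexp = set(
        panels.loc[
            panels["benzo_pos"].astype(bool) & ~panels["encounter_id"].isin(benzo_adm),
            "encounter_id",
        ]
    )
    out["uds_opiate_unexplained"] = eid_s.isin(op_unexp).to_numpy().astype(np.int64)
    out["uds_cocaine"] = eid_s.isin(cocaine).to_numpy().astype(np.int64)
    out["uds_benzo_unexplained"] = eid_s.isin(benzo_unexp).to_numpy().astype(np.int64)
    return out
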