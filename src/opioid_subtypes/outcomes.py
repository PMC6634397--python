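"""Clinical outcomes: 30-day unplanned readmission and discharge dispositions.

Readmission follows CMS-style rules.  An *index* admission is any encounter
except in-hospital deaths, encounters discharged within 30 days of the end
of the study period (incomplete follow-up), and encounters that are
themselves planned admissions (tagged via the code-set registry's
``planned_readmission`` set).  For an eligible index, subsequent admissions
of the same patient are scanned in admit order using calendar-day
arithmetic (delta = admit date minus index discharge date):

* same-calendar-day admissions (delta = 0) never count and are skipped;
* the first admission with 0 < delta <= 30 decides the outcome — unplanned
  triggers the (single) readmission outcome, planned cancels it
  (readmissions that follow a planned readmission are not counted);
* at most one outcome per index admission.

Dispositions (home / psychiatric / AMA / in-hospital death / other) are
tabulated per latent class with Pearson chi-square comparisons, either
across all classes or one class against the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .config import DISPOSITIONS
from .phenotype import CodeSetRegistry

__all__ = [
    "ComparisonResult",
    "planned_encounter_ids",
    "eligible_index",
    "flag_unplanned_readmission_30d",
    "disposition_table",
    "compare_classes",
    "naloxone_early_flag",
]

_EARLY_NALOXONE = pd.Timedelta(hours=3)


def planned_encounter_ids(diagnoses: pd.DataFrame, registry: CodeSetRegistry | None = None) -> set:
    """Encounters carrying a planned-readmission code (obstetrical delivery,
    scheduled procedures, maintenance chemotherapy, rehabilitation — as tags)."""
    registry = registry or CodeSetRegistry()
    codes = registry.codes("planned_readmission")
    return set(diagnoses.loc[diagnoses["code"].isin(codes), "encounter_id"])


def eligible_index(
    encounter: pd.Series,
    planned_ids: set,
    study_end: pd.Timestamp,
) -> bool:
    """Index-admission eligibility for the 30-day readmission outcome."""
    if str(encounter["disposition"]) == "death":
        return False
    if pd.Timestamp(encounter["discharge_time"]) > study_end - pd.Timedelta(days=30):
        return False
    if encounter["encounter_id"] in planned_ids:
        return False
    return True


def _check_overlaps(df: pd.DataFrame) -> None:
    prev_discharge = df.groupby("patient_id")["discharge_time"].shift(1)
    bad = df["admit_time"] < prev_discharge
    if bad.any():
        patients = sorted(df.loc[bad, "patient_id"].unique().tolist())
        raise ValueError(f"overlapping encounters for patients {patients[:10]}")


def flag_unplanned_readmission_30d(
    encounters: pd.DataFrame,
    planned_ids: set,
    study_end: pd.Timestamp,
) -> pd.DataFrame:
    """Per-encounter readmission flags over a full encounter table.

    Returns columns ``encounter_id, eligible_index, readmitted_30d,
    triggering_encounter_id`` (NA when not readmitted).
    """
    df = encounters.sort_values(["patient_id", "admit_time", "encounter_id"], kind="stable")
    df = df.reset_index(drop=True)
    _check_overlaps(df)

    eligible = (
        (df["disposition"] != "death").to_numpy()
        & (df["discharge_time"] <= study_end - pd.Timedelta(days=30)).to_numpy()
        & ~df["encounter_id"].isin(planned_ids).to_numpy()
    )
    readmitted = np.zeros(len(df), dtype=bool)
    trigger = np.full(len(df), -1, dtype=np.int64)

    eid = df["encounter_id"].to_numpy()
    planned = df["encounter_id"].isin(planned_ids).to_numpy()
    admit_day = df["admit_time"].dt.normalize().to_numpy()
    dis_day = df["discharge_time"].dt.normalize().to_numpy()
    pat = df["patient_id"].to_numpy()

    start = np.flatnonzero(np.r_[True, pat[1:] != pat[:-1]])
    end = np.r_[start[1:], len(df)]
    day = np.timedelta64(1, "D")
    for s, e in zip(start, end):
        if e - s < 2:
            continue
        for i in range(s, e - 1):
            if not eligible[i]:
                continue
            for j in range(i + 1, e):
                delta = int((admit_day[j] - dis_day[i]) / day)
                if delta <= 0:
                    continue  # same-calendar-day (or overlapping-day) admissions never count
                if delta > 30:
                    break
                if planned[j]:
                    break  # readmissions following a planned readmission are not counted
                readmitted[i] = True
                trigger[i] = eid[j]
                break
    out = pd.DataFrame({
        "encounter_id": eid,
        "eligible_index": eligible,
        "readmitted_30d": readmitted,
        "triggering_encounter_id": pd.array(
            np.where(readmitted, trigger, np.int64(0)), dtype="Int64"
        ),
    })
    out.loc[~readmitted, "triggering_encounter_id"] = pd.NA
    assert int(out["readmitted_30d"].sum()) == int((out["readmitted_30d"] & out["eligible_index"]).sum())
    return out.sort_values("encounter_id", kind="stable").reset_index(drop=True)


def disposition_table(
    cohort: pd.DataFrame,
    class_labels: pd.Series,
    readmission_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-class outcome table: n, readmission, discharge dispositions.

    ``class_labels`` is indexed by encounter_id with 1-based class labels.
    Readmission percentages are reported both over eligible index encounters
    (``readmit_pct``) and over all class encounters (``readmit_pct_all``).
    """
    labels = class_labels.reindex(cohort["encounter_id"])
    if labels.isna().any():
        raise ValueError("class labels do not cover every cohort encounter")
    work = cohort[["encounter_id", "disposition"]].copy()
    work["cls"] = labels.to_numpy()
    if readmission_flags is not None:
        work = work.merge(
            readmission_flags[["encounter_id", "eligible_index", "readmitted_30d"]],
            on="encounter_id", how="left",
        )
    classes = sorted(pd.unique(work["cls"]))
    rows = []
    for key, grp in [("overall", work)] + [(c, work[work["cls"] == c]) for c in classes]:
        row: dict[str, object] = {"class": key, "n": len(grp)}
        for d in DISPOSITIONS:
            cnt = int((grp["disposition"] == d).sum())
            row[f"{d}_n"] = cnt
            row[f"{d}_pct"] = 100.0 * cnt / len(grp) if len(grp) else np.nan
        if readmission_flags is not None:
            elig = int(grp["eligible_index"].sum())
            readm = int(grp["readmitted_30d"].sum())
            row["eligible_index_n"] = elig
            row["readmit_n"] = readm
            row["readmit_pct"] = 100.0 * readm / elig if elig else np.nan
            row["readmit_pct_all"] = 100.0 * readm / len(grp) if len(grp) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    dof: int
    warning: str | None = None


def _chi2(table: np.ndarray, yates: bool) -> ComparisonResult:
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ComparisonResult(float("nan"), float("nan"), 0, "degenerate table")
    stat, p, dof, expected = chi2_contingency(table, correction=yates)
    warning = None
    if (expected < 1).any():
        warning = "expected cell count below 1; chi-square approximation unreliable"
        warnings.warn(warning)
    return ComparisonResult(float(stat), float(p), int(dof), warning)


def compare_classes(
    outcome_table: pd.DataFrame,
    outcome: str,
    comparison: str = "all_classes",
    class_index: int | None = None,
    yates: bool = False,
) -> ComparisonResult:
    """Pearson chi-square comparison of one outcome across latent classes.

    ``outcome`` is a disposition name or ``"readmit"``.  ``all_classes``
    tests the full class x outcome contingency table; ``one_vs_rest`` tests
    the named class against the pooled remainder on a 2x2 table (readmission
    uses eligible-index denominators).
    """
    per_class = outcome_table.drop(index="overall")
    if outcome == "readmit":
        success = per_class["readmit_n"].to_numpy(dtype=float)
        total = per_class["eligible_index_n"].to_numpy(dtype=float)
    else:
        success = per_class[f"{outcome}_n"].to_numpy(dtype=float)
        total = per_class["n"].to_numpy(dtype=float)
    failure = total - success
    if comparison == "all_classes":
        return _chi2(np.column_stack([success, failure]), yates)
    if comparison == "one_vs_rest":
        if class_index is None:
            raise ValueError("class_index required for one_vs_rest")
        pos = per_class.index.get_loc(class_index)
        mask = np.zeros(len(per_class), dtype=bool)
        mask[pos] = True
        table = np.array([
            [success[mask].sum(), failure[mask].sum()],
            [success[~mask].sum(), failure[~mask].sum()],
        ])
        return _chi2(table, yates)
    raise ValueError(f"unknown comparison: {comparison!r}")


def naloxone_early_flag(encounter: pd.Series) -> bool:
    """Naloxone within the first three hours of the first recorded vital sign
    (inclusive boundary).  Administration before the first vital returns True
    with a warning (pre-triage administration)."""
    t = encounter.get("naloxone_time")
    if t is None or pd.isna(t):
        return False
    delta = pd.Timestamp(t) - pd.Timestamp(encounter["first_vital_time"])
    if delta < pd.Timedelta(0):
        warnings.warn(
            f"naloxone before first vital sign for encounter {encounter['encounter_id']}"
        )
        return True
    return delta <= _EARLY_NALOXONE
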