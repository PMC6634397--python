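"""Seeded synthetic EHR cohort with a latent 4-class opioid-misuse structure.

``generate_cohort`` emits six tables (encounters, urine drug screens,
medication events, diagnoses, census-tract attributes, ground truth) that
mirror the raw inputs of a rule-based misuse phenotyping study:

* Planted misuse encounters carry a latent class drawn from the configured
  class prevalences; their class-defining indicators (age band, comorbidity
  diagnosis tags, urine-drug-screen positives) are sampled from the
  per-class item-response probabilities and then *materialized* as raw
  artifacts — UDS panels, admission-med-list and dispense rows, diagnosis
  codes — so that downstream indicator reconstruction recovers exactly the
  sampled values.
* Every planted misuse encounter satisfies at least one operational misuse
  criterion: when the sampled indicators alone satisfy none, the generator
  adds an *explained* opiate-positive screen (opioid on the admission med
  list) and, if needed, an amphetamine positive absent from the admission
  list.  Neither artifact perturbs any class-defining indicator.
* Background encounters carry low marker rates; pediatric and transfer
  records are included so the phenotyper's exclusions are exercised.

Ground truth (true_misuse, true_class) is returned in a separate table; no
data table contains a latent-class field.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from ._util import sample_categorical, sample_categorical_by_class
from .config import (
    AGE_BANDS,
    DISPOSITIONS,
    INDICATOR_ITEMS,
    CohortConfig,
    default_registry,
)

__all__ = [
    "CohortTables",
    "generate_cohort",
    "generate_notes",
    "ground_truth_table",
    "plant_readmissions",
    "STUDY_START",
    "STUDY_END",
]

STUDY_START = pd.Timestamp("2007-01-01")
STUDY_END = pd.Timestamp("2017-09-30")

_HOUR = pd.Timedelta(hours=1)


@dataclass
class CohortTables:
    """The six output tables of one synthetic cohort."""

    encounters: pd.DataFrame
    uds: pd.DataFrame
    medications: pd.DataFrame
    diagnoses: pd.DataFrame
    tract: pd.DataFrame
    ground_truth: pd.DataFrame

    def __iter__(self):
        return iter(getattr(self, f.name) for f in fields(self))


_ENCOUNTER_COLS = [
    "encounter_id", "patient_id", "age_years", "admit_time", "discharge_time",
    "encounter_type", "service", "is_transfer", "disposition", "first_vital_time",
    "naloxone_time", "elixhauser_score", "insurance", "sex", "race",
]


def _empty_tables() -> CohortTables:
    enc = pd.DataFrame(columns=_ENCOUNTER_COLS)
    uds = pd.DataFrame(columns=["encounter_id", "order_time", "opiate_pos", "cocaine_pos",
                                "pcp_pos", "benzo_pos", "amphetamine_pos"])
    meds = pd.DataFrame(columns=["encounter_id", "drug_class", "source", "event_time"])
    dx = pd.DataFrame(columns=["encounter_id", "code"])
    tract = pd.DataFrame(columns=["patient_id", "pct_poverty", "pct_employed", "pct_college",
                                  "pct_homeowner", "median_earnings"])
    gt = pd.DataFrame(columns=["encounter_id", "true_misuse", "true_class"])
    return CohortTables(enc, uds, meds, dx, tract, gt)


def _pick_codes(rng: np.random.Generator, tag: str, k: int, registry) -> np.ndarray:
    codes = np.array(sorted(registry[tag]))
    return codes[rng.integers(0, len(codes), size=k)]


def generate_cohort(config: CohortConfig) -> CohortTables:
    """Generate the full cohort; bit-identical output for identical config+seed."""
    config.validate()
    n = config.n_encounters
    if n == 0:
        return _empty_tables()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    registry = default_registry()
    C = config.n_classes

    enc_id = np.arange(1, n + 1, dtype=np.int64)

    # --- patients: geometric encounter counts, mean encounters_per_patient ---
    p_geo = 1.0 / max(config.encounters_per_patient_mean, 1.0)
    sizes = rng.geometric(p_geo, size=n)
    cum = np.cumsum(sizes)
    n_pat = int(np.searchsorted(cum, n)) + 1
    sizes = sizes[:n_pat]
    sizes[-1] -= cum[n_pat - 1] - n
    patient_id = np.repeat(np.arange(1, n_pat + 1, dtype=np.int64), sizes)

    # --- timeline ---
    total_days = (STUDY_END - STUDY_START).days
    admit = STUDY_START + pd.to_timedelta(
        np.round(rng.random(n) * total_days * 24 * 60), unit="m"
    )
    los_hours = rng.gamma(shape=2.0, scale=36.0, size=n) + 6.0
    discharge = admit + pd.to_timedelta(np.round(los_hours * 60), unit="m")

    # --- exclusions and planting ---
    is_transfer = rng.random(n) < config.transfer_rate
    pediatric = rng.random(n) < config.pediatric_rate
    eligible = ~is_transfer & ~pediatric
    misuse = eligible & (rng.random(n) < config.misuse_prevalence)
    true_class = np.full(n, -1, dtype=np.int64)
    pi = np.asarray(config.class_prevalences, dtype=float)
    true_class[misuse] = sample_categorical(rng, pi, int(misuse.sum()))
    m_idx = np.flatnonzero(misuse)
    cls = true_class[m_idx]  # 0-based class of each misuse encounter
    m = m_idx.size

    # --- class-defining indicators for misuse encounters ---
    ind: dict[str, np.ndarray] = {}
    for item, _levels, _group in INDICATOR_ITEMS:
        ind[item] = sample_categorical_by_class(
            rng, np.asarray(config.item_response[item]), cls
        )

    # --- age ---
    bands = np.asarray(AGE_BANDS)
    overall_band_probs = np.array([0.066, 0.171, 0.194, 0.288, 0.281])
    overall_band_probs = overall_band_probs / overall_band_probs.sum()
    band = sample_categorical(rng, overall_band_probs, n)
    band[m_idx] = ind["age_band"]
    lo, hi = bands[band, 0], bands[band, 1]
    age = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(np.int64)
    age = np.clip(age, 18, None)
    ped_age = 1 + np.floor(rng.random(n) * 17).astype(np.int64)
    age[pediatric] = ped_age[pediatric]

    # --- demographics ---
    demo = config.demographics
    sex = np.where(rng.random(n) < 0.55, "M", "F")
    sex[m_idx] = np.where(rng.random(m) < np.asarray(demo["male"])[cls], "M", "F")
    race_levels = np.asarray(demo["race"]["levels"])
    race = race_levels[sample_categorical(rng, np.array([0.393, 0.488, 0.092, 0.027]), n)]
    race[m_idx] = race_levels[sample_categorical_by_class(rng, np.asarray(demo["race"]["rates"]), cls)]
    ins_levels = np.asarray(demo["insurance"]["levels"])
    insurance = ins_levels[sample_categorical(rng, np.array([0.242, 0.174, 0.361, 0.223]), n)]
    insurance[m_idx] = ins_levels[sample_categorical_by_class(rng, np.asarray(demo["insurance"]["rates"]), cls)]
    svc_levels = np.asarray(demo["service"]["levels"])
    service = svc_levels[sample_categorical(rng, np.array([0.50, 0.26, 0.05, 0.06, 0.03, 0.10]), n)]
    service[m_idx] = svc_levels[sample_categorical_by_class(rng, np.asarray(demo["service"]["rates"]), cls)]
    elix = rng.normal(3.0, 10.0, size=n)
    emeans = np.asarray(demo["elixhauser"])
    elix[m_idx] = rng.normal(emeans[cls, 0], emeans[cls, 1])
    elix = np.round(elix, 1)

    # --- urine drug screens -------------------------------------------------
    desc = config.descriptors
    # misuse panels
    op_pos = ind["uds_opiate_unexplained"].astype(bool)
    coc_pos = ind["uds_cocaine"].astype(bool)
    benzo_pos = ind["uds_benzo_unexplained"].astype(bool)
    pcp_pos = rng.random(m) < np.asarray(desc["pcp_pos"])[cls]
    amph_pos = rng.random(m) < np.asarray(desc["amph_pos"])[cls]

    # rescue: guarantee ≥1 criterion without touching class-defining indicators
    icd_pos = ind["opioid_misuse_icd"].astype(bool)
    needs_rescue = ~icd_pos & ~op_pos
    explained_opiate = needs_rescue.copy()          # opiate positive + opioid on admission list
    rescue_amph = needs_rescue & ~coc_pos & ~benzo_pos & ~pcp_pos & ~amph_pos
    amph_pos = amph_pos | rescue_amph
    panel_opiate = op_pos | explained_opiate

    any_pos = panel_opiate | coc_pos | benzo_pos | pcp_pos | amph_pos
    # top up testing to the per-class UDS-order rate
    rho = config.item_response
    p_any = 1.0 - (
        (1.0 - np.array([r[1] for r in rho["uds_opiate_unexplained"]]))
        * (1.0 - np.array([r[1] for r in rho["uds_cocaine"]]))
        * (1.0 - np.array([r[1] for r in rho["uds_benzo_unexplained"]]))
        * (1.0 - np.asarray(desc["pcp_pos"]))
        * (1.0 - np.asarray(desc["amph_pos"]))
    )
    target = np.asarray(desc["uds_ordered"])
    extra = np.clip((target - p_any) / np.maximum(1.0 - p_any, 1e-12), 0.0, 1.0)
    tested = any_pos | (rng.random(m) < extra[cls])

    # background panels: at most one positive marker each
    bg = config.background
    b_idx = np.flatnonzero(~misuse)
    nb = b_idx.size
    bg_ordered = rng.random(nb) < bg["uds_order_rate"]
    marker_probs = np.array([
        bg["opiate_pos_given_uds"], bg["cocaine_pos_given_uds"], bg["benzo_pos_given_uds"],
    ])
    marker_probs = np.append(marker_probs, 1.0 - marker_probs.sum())
    marker = sample_categorical(rng, marker_probs, nb)
    marker[~bg_ordered] = 3
    bg_unexplained = rng.random(nb) < bg["unexplained_given_opiate_pos"]

    uds_rows = []
    los_td = (discharge - admit)
    order_time = admit + los_td * (0.02 + 0.38 * rng.random(n))
    order_time = pd.DatetimeIndex(order_time).round("min")
    mi_tested = m_idx[tested]
    uds_rows.append(pd.DataFrame({
        "encounter_id": enc_id[mi_tested],
        "order_time": order_time[mi_tested],
        "opiate_pos": panel_opiate[tested],
        "cocaine_pos": coc_pos[tested],
        "pcp_pos": pcp_pos[tested],
        "benzo_pos": benzo_pos[tested],
        "amphetamine_pos": amph_pos[tested],
    }))
    bi_tested = b_idx[bg_ordered]
    bmk = marker[bg_ordered]
    uds_rows.append(pd.DataFrame({
        "encounter_id": enc_id[bi_tested],
        "order_time": order_time[bi_tested],
        "opiate_pos": bmk == 0,
        "cocaine_pos": bmk == 1,
        "pcp_pos": False,
        "benzo_pos": bmk == 2,
        "amphetamine_pos": False,
    }))
    uds = pd.concat(uds_rows, ignore_index=True).sort_values("encounter_id", kind="stable")
    uds = uds.reset_index(drop=True)

    # --- medication events --------------------------------------------------
    med_parts = []
    # opioid on the admission med list: rescued misuse + explained background opiate positives
    adm_opioid_ids = np.concatenate([
        enc_id[m_idx[explained_opiate]],
        enc_id[b_idx[(marker == 0) & ~bg_unexplained]],
    ])
    med_parts.append(pd.DataFrame({
        "encounter_id": adm_opioid_ids,
        "drug_class": "opioid",
        "source": "admission_mar",
        "event_time": pd.NaT,
    }))
    # benzodiazepine on the admission list: explained background benzo positives
    adm_benzo_ids = enc_id[b_idx[marker == 2]]
    med_parts.append(pd.DataFrame({
        "encounter_id": adm_benzo_ids,
        "drug_class": "benzodiazepine",
        "source": "admission_mar",
        "event_time": pd.NaT,
    }))
    # inpatient opioid dispensing strictly after the screen order (misuse subset)
    disp = rng.random(m) < 0.30
    di = m_idx[disp]
    disp_time = order_time[di] + (discharge.values[di] - order_time[di].values) * (
        0.1 + 0.8 * rng.random(di.size)
    )
    med_parts.append(pd.DataFrame({
        "encounter_id": enc_id[di],
        "drug_class": "opioid",
        "source": "inpatient_dispense",
        "event_time": pd.DatetimeIndex(disp_time).round("min"),
    }))
    meds = pd.concat(med_parts, ignore_index=True).sort_values("encounter_id", kind="stable")
    meds = meds.reset_index(drop=True)

    # --- diagnoses ----------------------------------------------------------
    dx_parts = []

    def _tag_rows(ids: np.ndarray, tag: str) -> None:
        if ids.size:
            dx_parts.append(pd.DataFrame({
                "encounter_id": ids,
                "code": _pick_codes(rng, tag, ids.size, registry),
            }))

    for item in ("liver", "alcohol_use_disorder", "psychoses", "depression", "chronic_pain"):
        _tag_rows(enc_id[m_idx[ind[item].astype(bool)]], item)
    _tag_rows(enc_id[m_idx[icd_pos]], "opioid_misuse_icd")
    _tag_rows(enc_id[m_idx[rng.random(m) < np.asarray(desc["drug_use_icd"])[cls]]], "drug_use")
    # background diagnoses
    _tag_rows(enc_id[b_idx[rng.random(nb) < bg["misuse_icd_rate"]]], "opioid_misuse_icd")
    _tag_rows(enc_id[b_idx[rng.random(nb) < 0.10]], "chronic_pain")
    _tag_rows(enc_id[b_idx[rng.random(nb) < 0.08]], "depression")
    _tag_rows(enc_id[b_idx[rng.random(nb) < bg["planned_readmission_tag_rate"]]], "planned_readmission")
    diagnoses = pd.concat(dx_parts, ignore_index=True).sort_values("encounter_id", kind="stable")
    diagnoses = diagnoses.reset_index(drop=True)

    # --- dispositions / naloxone / vitals ------------------------------------
    disposition = np.asarray(DISPOSITIONS)[
        sample_categorical(rng, np.asarray(config.outcome_rates["background_disposition"]), n)
    ]
    disposition[m_idx] = np.asarray(DISPOSITIONS)[
        sample_categorical_by_class(rng, np.asarray(config.outcome_rates["disposition"]), cls)
    ]
    first_vital = admit + pd.to_timedelta(np.round(5 + 55 * rng.random(n)), unit="m")
    first_vital = pd.DatetimeIndex(np.minimum(first_vital.values, discharge.values))
    nal = np.zeros(n, dtype=bool)
    nal[m_idx] = rng.random(m) < np.asarray(desc["naloxone"])[cls]
    nal_delay_h = np.where(rng.random(n) < 0.8, 3.0 * rng.random(n), 3.0 + 9.0 * rng.random(n))
    naloxone_time = pd.DatetimeIndex(first_vital) + pd.to_timedelta(np.round(nal_delay_h * 60), unit="m")
    naloxone_time = pd.DatetimeIndex(np.where(nal, naloxone_time.values, np.datetime64("NaT")))

    encounters = pd.DataFrame({
        "encounter_id": enc_id,
        "patient_id": patient_id,
        "age_years": age,
        "admit_time": admit,
        "discharge_time": discharge,
        "encounter_type": np.where(service == "ER", "ED", "inpatient"),
        "service": service,
        "is_transfer": is_transfer,
        "disposition": disposition,
        "first_vital_time": first_vital,
        "naloxone_time": naloxone_time,
        "elixhauser_score": elix,
        "insurance": insurance,
        "sex": sex,
        "race": race,
    })
    encounters = _fix_overlaps(encounters)
    # re-clip screen order times to the (possibly truncated) stay
    dis_map = encounters.set_index("encounter_id")["discharge_time"]
    uds["order_time"] = np.minimum(uds["order_time"].values, dis_map.loc[uds["encounter_id"]].values)
    meds_disp = meds["source"] == "inpatient_dispense"
    meds.loc[meds_disp, "event_time"] = np.minimum(
        meds.loc[meds_disp, "event_time"].values,
        dis_map.loc[meds.loc[meds_disp, "encounter_id"]].values,
    )

    # --- census-tract SES per patient ----------------------------------------
    tract = _tract_table(rng, config, encounters, enc_id, m_idx, cls, patient_id)

    ground_truth = pd.DataFrame({
        "encounter_id": enc_id,
        "true_misuse": misuse,
        "true_class": pd.array(np.where(misuse, true_class + 1, np.int64(0)), dtype="Int64"),
    })
    ground_truth.loc[~misuse, "true_class"] = pd.NA

    return CohortTables(encounters, uds, meds, diagnoses, tract, ground_truth)


def _fix_overlaps(encounters: pd.DataFrame) -> pd.DataFrame:
    """Truncate discharges so no patient's encounters overlap (half-open stays)."""
    df = encounters.sort_values(["patient_id", "admit_time"], kind="stable").reset_index(drop=True)
    same_pat = df["patient_id"].shift(-1) == df["patient_id"]
    next_admit = df["admit_time"].shift(-1)
    overlap = same_pat & (df["discharge_time"] >= next_admit)
    trunc = next_admit - _HOUR
    bad = overlap & (trunc <= df["admit_time"])
    trunc[bad] = df["admit_time"] + (next_admit - df["admit_time"]) / 2
    df.loc[overlap, "discharge_time"] = trunc[overlap]
    df.loc[overlap, "first_vital_time"] = np.minimum(
        df.loc[overlap, "first_vital_time"].values, df.loc[overlap, "discharge_time"].values
    )
    return df.sort_values("encounter_id", kind="stable").reset_index(drop=True)


def _tract_table(rng, config, encounters, enc_id, m_idx, cls, patient_id) -> pd.DataFrame:
    pat_class = pd.Series(-1, index=np.unique(patient_id))
    if m_idx.size:
        first = (
            pd.DataFrame({"patient_id": patient_id[m_idx], "cls": cls})
            .groupby("patient_id")["cls"].first()
        )
        pat_class.loc[first.index] = first.values
    pats = pat_class.index.to_numpy()
    pcls = pat_class.to_numpy()
    out = {"patient_id": pats}
    per_class = config.tract_params["per_class"]
    background = config.tract_params["background"]
    for attr, bg_ms in background.items():
        mean = np.full(pats.size, bg_ms[0], dtype=float)
        sd = np.full(pats.size, bg_ms[1], dtype=float)
        rows = np.asarray(per_class[attr], dtype=float)
        has = pcls >= 0
        mean[has] = rows[pcls[has], 0]
        sd[has] = rows[pcls[has], 1]
        vals = rng.normal(mean, sd)
        if attr.startswith("pct_"):
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.clip(vals, 0.0, None)
        out[attr] = np.round(vals, 1)
    return pd.DataFrame(out)[
        ["patient_id", "pct_poverty", "pct_employed", "pct_college", "pct_homeowner", "median_earnings"]
    ]


def ground_truth_table(cohort: CohortTables) -> pd.DataFrame:
    """One row per encounter (recovery tests join on ``encounter_id``)."""
    return cohort.ground_truth.copy()


# ---------------------------------------------------------------------------
# Notes
# ---------------------------------------------------------------------------

def generate_notes(
    encounters: pd.DataFrame,
    ground_truth: pd.DataFrame,
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Concept-bag notes for misuse encounters, drawn topic-first.

    Each note receives topic weights theta ~ Dirichlet(s * topic_mixtures[class])
    with concentration ``s = config.note_topic_concentration`` — so individual
    notes are concentrated on a few topics, as clinical notes are, while the
    *expected* topic distribution of a class equals its configured mixture —
    and then tokens are drawn topic ~ Cat(theta), concept ~ Cat(topic_word[topic]).
    Returns a table with columns ``note_id, encounter_id, concept_counts``
    (dict concept -> count).
    """
    for name, dist in config.topic_word.items():
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError(f"topic_word[{name!r}] rows must be normalized")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 23])
    )
    gt = ground_truth
    mis = gt[gt["true_misuse"].astype(bool)]
    enc_ids = mis["encounter_id"].to_numpy()
    cls = mis["true_class"].to_numpy(dtype=np.int64) - 1
    lo, hi = config.notes_per_encounter
    n_notes_per = lo + rng.integers(0, hi - lo + 1, size=enc_ids.size)
    note_enc = np.repeat(enc_ids, n_notes_per)
    note_cls = np.repeat(cls, n_notes_per)
    n_notes = note_enc.size
    lengths = np.maximum(rng.poisson(config.note_length_mean, size=n_notes), 5)

    topic_names = list(config.topic_word.keys())
    concept_lists = [np.array(sorted(config.topic_word[t].keys())) for t in topic_names]
    concept_probs = [
        np.array([config.topic_word[t][c] for c in cl])
        for t, cl in zip(topic_names, concept_lists)
    ]
    mix = np.asarray(config.topic_mixtures, dtype=float)

    K = mix.shape[1]
    # per-note topic weights: Dirichlet(s * class mixture) via gamma draws
    s = float(config.note_topic_concentration)
    theta = rng.gamma(np.maximum(s * mix[note_cls], 1e-12))
    theta /= theta.sum(axis=1, keepdims=True)
    topic_counts = rng.multinomial(lengths, theta)  # n_notes x K
    token_note = np.repeat(np.arange(n_notes), lengths)
    token_topic = np.repeat(np.tile(np.arange(K), n_notes), topic_counts.ravel())
    n_tokens = token_note.size
    # concept per token, by topic
    token_concept = np.empty(n_tokens, dtype=object)
    u2 = rng.random(n_tokens)
    for t in range(len(topic_names)):
        mask = token_topic == t
        cum = np.cumsum(concept_probs[t])
        cum[-1] = 1.0
        token_concept[mask] = concept_lists[t][np.searchsorted(cum, u2[mask], side="right")]

    counts_df = (
        pd.DataFrame({"note": token_note, "concept": token_concept})
        .groupby(["note", "concept"], sort=True).size()
    )
    concept_counts: list[dict[str, int]] = [dict() for _ in range(n_notes)]
    for (note_i, concept), cnt in counts_df.items():
        concept_counts[note_i][concept] = int(cnt)
    return pd.DataFrame({
        "note_id": np.arange(1, n_notes + 1, dtype=np.int64),
        "encounter_id": note_enc,
        "concept_counts": concept_counts,
    })


# ---------------------------------------------------------------------------
# Outcome planting
# ---------------------------------------------------------------------------

def plant_readmissions(
    cohort: CohortTables,
    config: CohortConfig,
    seed: int | None = None,
    study_end: pd.Timestamp = STUDY_END,
) -> pd.DataFrame:
    """Plant 30-day unplanned readmissions for misuse encounters.

    For every CMS-eligible index misuse encounter (not an in-hospital death,
    discharged ≥ 30 days before study end, not itself a planned admission) a
    future unplanned inpatient admission is planted with the configured
    per-true-class probability, 1-28 days after discharge.  Returns the
    encounter table augmented with the planted rows.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 37])
    )
    enc = cohort.encounters
    gt = cohort.ground_truth
    registry = default_registry()
    planned_codes = registry["planned_readmission"]
    planned_enc = set(
        cohort.diagnoses.loc[cohort.diagnoses["code"].isin(planned_codes), "encounter_id"]
    )
    merged = enc.merge(gt, on="encounter_id")
    mis = merged[merged["true_misuse"].astype(bool)].reset_index(drop=True)
    cls = mis["true_class"].to_numpy(dtype=np.int64) - 1
    eligible = (
        (mis["disposition"] != "death").to_numpy()
        & (mis["discharge_time"] <= study_end - pd.Timedelta(days=30)).to_numpy()
        & ~mis["encounter_id"].isin(planned_enc).to_numpy()
    )
    rates = np.asarray(config.outcome_rates["readmission"], dtype=float)
    hit = eligible & (rng.random(len(mis)) < rates[cls])
    src = mis[hit]
    k = len(src)
    if k == 0:
        return enc.copy()
    delay_days = 1 + rng.integers(0, 28, size=k)
    admit = src["discharge_time"].to_numpy() + delay_days * np.timedelta64(24 * 60, "m") \
        + (rng.integers(0, 12 * 60, size=k)) * np.timedelta64(1, "m")
    los = pd.to_timedelta(np.round(rng.gamma(2.0, 36.0, size=k) * 60 + 12 * 60), unit="m")
    new_id = enc["encounter_id"].max() + 1 + np.arange(k, dtype=np.int64)
    new = pd.DataFrame({
        "encounter_id": new_id,
        "patient_id": src["patient_id"].to_numpy(),
        "age_years": src["age_years"].to_numpy(),
        "admit_time": admit,
        "discharge_time": admit + los,
        "encounter_type": "inpatient",
        "service": "medicine",
        "is_transfer": False,
        "disposition": "home",
        "first_vital_time": admit + pd.Timedelta(minutes=15),
        "naloxone_time": pd.NaT,
        "elixhauser_score": src["elixhauser_score"].to_numpy(),
        "insurance": src["insurance"].to_numpy(),
        "sex": src["sex"].to_numpy(),
        "race": src["race"].to_numpy(),
    })
    out = pd.concat([enc, new], ignore_index=True)
    return _fix_overlaps(out)
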