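"""Shared fixtures: small seeded cohorts and an all-misuse corpus config."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from opioid_subtypes.config import CohortConfig, default_config


@pytest.fixture(scope="session")
def small_cohort():
    """A 20k-encounter default-calibrated cohort (shared, read-only)."""
    from opioid_subtypes.simulate import generate_cohort

    cfg = default_config(n_encounters=20_000, seed=123)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def misuse_only_config():
    """Config in which (almost) every encounter is a misuse encounter —
    convenient for note/topic experiments where only the misuse cohort matters."""
    cfg = default_config(n_encounters=1500, seed=7)
    d = cfg.to_dict()
    d.update(misuse_prevalence=0.999, transfer_rate=0.0, pediatric_rate=0.0,
             notes_per_encounter=(1, 2))
    return CohortConfig.from_dict(d)


@pytest.fixture(scope="session")
def misuse_corpus(misuse_only_config):
    """Cohort tables + notes + filtered corpus + restricted true phi."""
    from opioid_subtypes.simulate import generate_cohort, generate_notes
    from opioid_subtypes.topics import build_vocabulary, corpus_from_notes

    cfg = misuse_only_config
    tables = generate_cohort(cfg)
    notes = generate_notes(tables.encounters, tables.ground_truth, cfg)
    vocab = build_vocabulary(notes)
    corpus = corpus_from_notes(notes, vocab)
    names = list(cfg.topic_word.keys())
    idx = vocab.index()
    true_phi = np.zeros((len(names), vocab.size))
    for t, nm in enumerate(names):
        for c, p in cfg.topic_word[nm].items():
            if c in idx:
                true_phi[t, idx[c]] = p
    true_phi = true_phi / true_phi.sum(axis=1, keepdims=True)
    return cfg, tables, notes, corpus, true_phi


def one_encounter(encounter_id=1, **kw) -> pd.Series:
    base = dict(
        encounter_id=encounter_id, patient_id=1, age_years=40,
        admit_time=pd.Timestamp("2010-01-01 08:00"),
        discharge_time=pd.Timestamp("2010-01-04 12:00"),
        encounter_type="inpatient", service="medicine", is_transfer=False,
        disposition="home", first_vital_time=pd.Timestamp("2010-01-01 08:20"),
        naloxone_time=pd.NaT, elixhauser_score=0.0,
        insurance="private", sex="F", race="nh_white",
    )
    base.update(kw)
    return pd.Series(base)


def uds_panel(encounter_id=1, order_time="2010-01-01 10:00", **flags) -> pd.DataFrame:
    row = dict(encounter_id=encounter_id, order_time=pd.Timestamp(order_time),
               opiate_pos=False, cocaine_pos=False, pcp_pos=False,
               benzo_pos=False, amphetamine_pos=False)
    row.update(flags)
    return pd.DataFrame([row])


def med_event(encounter_id=1, drug_class="opioid", source="admission_mar", event_time=None) -> dict:
    return dict(encounter_id=encounter_id, drug_class=drug_class, source=source,
                event_time=pd.Timestamp(event_time) if event_time else pd.NaT)


EMPTY_MEDS = pd.DataFrame(columns=["encounter_id", "drug_class", "source", "event_time"])
EMPTY_DX = pd.DataFrame(columns=["encounter_id", "code"])
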