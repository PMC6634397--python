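"""Cohort configuration: the generating model behind the synthetic EHR.

The synthetic cohort is driven by a single :class:`CohortConfig` object that
holds, as generator ground truth, the quantities a latent-class subtyping
study estimates from real data:

* class prevalences ``pi`` of the four misuse subtypes,
* per-class item-response probabilities ``rho`` for the ten class-defining
  indicators (age band, six comorbidity/diagnosis flags, three urine-drug-
  screen flags),
* per-class topic mixtures over twenty clinical-note topics,
* per-class 30-day unplanned readmission and discharge-disposition rates.

Defaults are calibrated to the published characteristics of a large
single-center inpatient cohort of opioid misuse (n = 6,224 misuse encounters
out of 228,884; four subtypes).  ``default_config()`` returns these study
conditions; every field is overridable for experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "INDICATOR_ITEMS",
    "AGE_BANDS",
    "TOPIC_NAMES",
    "DISPOSITIONS",
    "CohortConfig",
    "default_config",
    "default_registry",
    "config_hash",
]

# ---------------------------------------------------------------------------
# Indicator layout (J = 10 items in 8 named class-defining variable groups;
# the three UDS items form one "urine drug screen results" group).
# ---------------------------------------------------------------------------

#: (item name, number of levels, variable-group label)
INDICATOR_ITEMS: tuple[tuple[str, int, str], ...] = (
    ("age_band", 5, "age"),
    ("liver", 2, "liver disease"),
    ("alcohol_use_disorder", 2, "alcohol use disorders"),
    ("psychoses", 2, "psychoses"),
    ("depression", 2, "depression"),
    ("chronic_pain", 2, "chronic pain"),
    ("opioid_misuse_icd", 2, "opioid-related hospitalization"),
    ("uds_opiate_unexplained", 2, "urine drug screen results"),
    ("uds_cocaine", 2, "urine drug screen results"),
    ("uds_benzo_unexplained", 2, "urine drug screen results"),
)

#: Age bands; ages are generated uniformly within the band.
AGE_BANDS: tuple[tuple[int, int], ...] = ((18, 25), (26, 35), (36, 45), (46, 55), (56, 90))

DISPOSITIONS: tuple[str, ...] = ("home", "psychiatric", "AMA", "death", "other")

SERVICES: tuple[str, ...] = ("ER", "medicine", "trauma", "surgery", "neurology", "other")

# ---------------------------------------------------------------------------
# Default latent-class truth.
# Class 1: high hospital utilization with known opioid-related conditions
# Class 2: illicit use, low SES, and psychoses
# Class 3: alcohol use disorders with complications
# Class 4: low hospital utilization and incidental opioid misuse
# ---------------------------------------------------------------------------

_DEFAULT_PI = (0.365, 0.128, 0.392, 0.115)

# Per item: per class, probability of each level (binary items: [P(0), P(1)]).
_DEFAULT_RHO: dict[str, tuple[tuple[float, ...], ...]] = {
    "age_band": (
        (0.103, 0.208, 0.181, 0.226, 0.281),
        (0.054, 0.204, 0.243, 0.383, 0.115),
        (0.024, 0.131, 0.208, 0.315, 0.322),
        (0.109, 0.148, 0.132, 0.284, 0.326),
    ),
    "liver": ((0.996, 0.004), (0.930, 0.070), (0.579, 0.421), (0.878, 0.122)),
    "alcohol_use_disorder": ((0.996, 0.004), (0.680, 0.320), (0.160, 0.840), (0.852, 0.148)),
    "psychoses": ((0.848, 0.152), (0.749, 0.251), (0.787, 0.213), (0.777, 0.223)),
    "depression": ((0.781, 0.219), (0.842, 0.158), (0.721, 0.279), (0.777, 0.223)),
    "chronic_pain": ((0.679, 0.321), (0.717, 0.283), (0.756, 0.244), (0.609, 0.391)),
    "opioid_misuse_icd": ((0.0, 1.0), (0.209, 0.791), (0.0, 1.0), (0.741, 0.259)),
    "uds_opiate_unexplained": ((0.922, 0.078), (0.649, 0.351), (0.963, 0.037), (0.501, 0.499)),
    "uds_cocaine": ((1.0, 0.0), (0.0, 1.0), (0.964, 0.036), (0.997, 0.003)),
    "uds_benzo_unexplained": ((1.0, 0.0), (0.835, 0.165), (0.991, 0.009), (0.332, 0.668)),
}

# Descriptor (non-indicator) marker rates per class: UDS panel ordered at all,
# phencyclidine positive, amphetamine positive, naloxone given.
_DEFAULT_DESCRIPTORS: dict[str, tuple[float, float, float, float]] = {
    "uds_ordered": (0.326, 1.0, 0.566, 1.0),
    "pcp_pos": (0.018, 0.035, 0.011, 0.021),
    "amph_pos": (0.011, 0.021, 0.008, 0.064),
    "naloxone": (0.079, 0.099, 0.046, 0.105),
    "drug_use_icd": (0.820, 0.917, 0.570, 0.314),
}

_DEFAULT_MALE = (0.508, 0.591, 0.736, 0.552)
_DEFAULT_RACE = {  # non-Hispanic Black / non-Hispanic White / Hispanic / other
    "levels": ("nh_black", "nh_white", "hispanic", "other"),
    "rates": (
        (0.418, 0.476, 0.085, 0.021),
        (0.586, 0.308, 0.083, 0.023),
        (0.324, 0.544, 0.099, 0.033),
        (0.328, 0.536, 0.098, 0.038),
    ),
}
_DEFAULT_INSURANCE = {
    "levels": ("medicare", "private", "medicaid", "uninsured_other"),
    "rates": (
        (0.300, 0.188, 0.359, 0.153),
        (0.113, 0.061, 0.503, 0.323),
        (0.225, 0.180, 0.326, 0.268),
        (0.256, 0.232, 0.329, 0.182),
    ),
}
_DEFAULT_SERVICE = {
    "levels": SERVICES,
    "rates": (
        (0.467, 0.269, 0.041, 0.069, 0.029, 0.126),
        (0.600, 0.201, 0.140, 0.005, 0.019, 0.035),
        (0.546, 0.280, 0.065, 0.047, 0.027, 0.036),
        (0.552, 0.172, 0.185, 0.014, 0.027, 0.050),
    ),
}
_DEFAULT_ELIXHAUSER = ((1.8, 12.3), (-0.7, 9.9), (6.2, 13.0), (5.9, 11.8))  # mean, SD

# Census-tract SES attributes: per class (mean, SD).
_DEFAULT_TRACT = {
    "pct_poverty": ((13.0, 11.8), (16.1, 12.3), (12.1, 10.9), (12.2, 10.7)),
    "pct_employed": ((38.4, 18.7), (37.7, 16.7), (37.9, 18.8), (38.7, 18.2)),
    "median_earnings": ((47916.0, 30177.0), (42728.0, 25078.0), (47639.0, 30980.0), (49736.0, 30934.0)),
    "pct_college": ((14.2, 9.6), (12.3, 8.0), (14.1, 9.5), (14.9, 9.6)),
    "pct_homeowner": ((47.9, 24.0), (46.1, 20.9), (47.3, 24.5), (49.2, 24.0)),
}
_BACKGROUND_TRACT = {
    "pct_poverty": (12.9, 11.4),
    "pct_employed": (38.1, 18.5),
    "median_earnings": (47351.0, 30037.0),
    "pct_college": (14.0, 9.4),
    "pct_homeowner": (47.6, 23.9),
}

# ---------------------------------------------------------------------------
# Outcomes (per class): 30-day unplanned readmission among eligible index
# encounters, and discharge-disposition distribution.
# ---------------------------------------------------------------------------

_DEFAULT_READMISSION = (0.139, 0.086, 0.123, 0.083)
_DEFAULT_DISPOSITION = (  # home, psychiatric, AMA, death, other
    (0.728, 0.030, 0.056, 0.020, 0.166),
    (0.688, 0.066, 0.123, 0.019, 0.104),
    (0.703, 0.063, 0.051, 0.030, 0.153),
    (0.671, 0.055, 0.049, 0.039, 0.186),
)
_BACKGROUND_DISPOSITION = (0.85, 0.015, 0.02, 0.015, 0.10)

# ---------------------------------------------------------------------------
# Topics: per-class mean topic probabilities (percent / 100), 20 topics.
# ---------------------------------------------------------------------------

TOPIC_NAMES: tuple[str, ...] = (
    "polysubstance_inhalational",
    "alcohol_withdrawal",
    "gi_pancreatitis",
    "mental_health",
    "physical_therapy",
    "neurology_seizures",
    "coronary_artery_disease",
    "procedural_pain",
    "nursing_assessment",
    "cancer_pain",
    "trauma",
    "lower_extremity",
    "respiratory_failure",
    "liver_disease",
    "infection",
    "constipation_pain_meds",
    "non_coronary_heart",
    "appendage_injury",
    "renal",
    "vitamin_therapy",
)

_DEFAULT_TOPIC_MIXTURES = (
    # class 1
    (15.2, 1.4, 10.1, 5.7, 6.8, 5.0, 6.7, 7.6, 5.8, 7.2, 2.5, 4.0, 3.1, 0.9, 3.7, 3.7, 2.5, 3.0, 2.4, 2.8),
    # class 2
    (22.5, 5.6, 5.7, 10.0, 4.5, 5.5, 4.6, 4.4, 4.1, 3.2, 7.4, 5.0, 3.4, 1.5, 3.3, 1.5, 2.2, 2.5, 2.2, 1.1),
    # class 3
    (7.9, 20.8, 8.0, 7.7, 5.7, 5.8, 5.0, 3.6, 5.1, 2.7, 3.4, 2.4, 3.9, 6.5, 2.4, 1.6, 1.8, 1.4, 1.8, 1.8),
    # class 4
    (11.3, 2.5, 7.4, 8.0, 7.5, 9.9, 6.1, 6.0, 3.9, 4.1, 7.3, 6.6, 3.8, 2.6, 2.7, 1.7, 2.4, 2.5, 2.1, 1.7),
)

# ---------------------------------------------------------------------------
# Code-set registry (synthetic stand-in code strings; tag semantics only).
# ---------------------------------------------------------------------------

_REGISTRY_TAGS = (
    "opioid_misuse_icd",
    "chronic_pain",
    "alcohol_use_disorder",
    "psychoses",
    "depression",
    "liver",
    "drug_use",
    "planned_readmission",
)


def default_registry() -> dict[str, frozenset[str]]:
    """Synthetic code-set registry: tag -> set of synthetic code strings."""
    return {tag: frozenset(f"{tag.upper()}_{i:02d}" for i in range(1, 4)) for tag in _REGISTRY_TAGS}


def _normalize_rows(rows: Sequence[Sequence[float]]) -> tuple[tuple[float, ...], ...]:
    out = []
    for r in rows:
        a = np.asarray(r, dtype=float)
        out.append(tuple(a / a.sum()))
    return tuple(out)


def _topic_word_defaults(topic_mixtures: Sequence[Sequence[float]], note_length_mean: float) -> dict[str, dict[str, float]]:
    """Build default topic-concept distributions with disjoint supports.

    Each topic owns a block of synthetic concept identifiers, uniform within
    the block.  Block sizes scale with the topic's mean mixture weight so
    that every concept's expected document frequency lands strictly inside
    the (10%, 70%) retention band used by the vocabulary filter.
    """
    mix = np.asarray(topic_mixtures, dtype=float)
    mix = mix / mix.sum(axis=1, keepdims=True)
    mean_weight = mix.mean(axis=0)
    topic_word: dict[str, dict[str, float]] = {}
    for t, name in enumerate(TOPIC_NAMES[: mix.shape[1]]):
        n_concepts = max(2, int(round(note_length_mean * mean_weight[t] / 0.6)))
        concepts = [f"CUI_{name}_{i:02d}" for i in range(n_concepts)]
        topic_word[name] = {c: 1.0 / n_concepts for c in concepts}
    return topic_word


@dataclass
class CohortConfig:
    """Full generating model for one synthetic cohort.

    ``class_prevalences`` and ``item_response`` are the latent-class truth;
    ``misuse_prevalence`` is the per-eligible-encounter probability of
    planting a misuse encounter (eligible = adult, non-transfer).
    """

    n_encounters: int = 228_884
    misuse_prevalence: float = 0.027
    class_prevalences: tuple[float, ...] = _DEFAULT_PI
    item_response: dict[str, tuple[tuple[float, ...], ...]] = field(
        default_factory=lambda: {k: _normalize_rows(v) for k, v in _DEFAULT_RHO.items()}
    )
    outcome_rates: dict[str, Any] = field(
        default_factory=lambda: {
            "readmission": _DEFAULT_READMISSION,
            "disposition": _normalize_rows(_DEFAULT_DISPOSITION),
            "background_disposition": tuple(np.asarray(_BACKGROUND_DISPOSITION) / np.sum(_BACKGROUND_DISPOSITION)),
        }
    )
    topic_mixtures: tuple[tuple[float, ...], ...] = _normalize_rows(_DEFAULT_TOPIC_MIXTURES)
    topic_word: dict[str, dict[str, float]] = field(default_factory=dict)
    notes_per_encounter: tuple[int, int] = (1, 3)
    note_length_mean: float = 60.0
    note_topic_concentration: float = 5.0
    tract_params: dict[str, Any] = field(
        default_factory=lambda: {"per_class": dict(_DEFAULT_TRACT), "background": dict(_BACKGROUND_TRACT)}
    )
    transfer_rate: float = 0.03
    pediatric_rate: float = 0.02
    encounters_per_patient_mean: float = 1.3
    descriptors: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(_DEFAULT_DESCRIPTORS))
    demographics: dict[str, Any] = field(
        default_factory=lambda: {
            "male": _DEFAULT_MALE,
            "race": _DEFAULT_RACE,
            "insurance": _DEFAULT_INSURANCE,
            "service": _DEFAULT_SERVICE,
            "elixhauser": _DEFAULT_ELIXHAUSER,
        }
    )
    # Background (non-misuse) marker rates.
    background: dict[str, float] = field(
        default_factory=lambda: {
            "uds_order_rate": 0.08,
            "opiate_pos_given_uds": 0.12,
            "unexplained_given_opiate_pos": 0.02,
            "cocaine_pos_given_uds": 0.03,
            "benzo_pos_given_uds": 0.05,  # always explained (on admission med list)
            "misuse_icd_rate": 0.0005,
            "planned_readmission_tag_rate": 0.01,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.topic_word:
            self.topic_word = _topic_word_defaults(self.topic_mixtures, self.note_length_mean)
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on invalid input."""
        if self.n_encounters < 0:
            raise ValueError("n_encounters must be nonnegative")
        if not (0.0 < self.misuse_prevalence < 1.0) and self.n_encounters > 0:
            if not (0.0 <= self.misuse_prevalence <= 1.0):
                raise ValueError("misuse_prevalence must lie in [0, 1]")
        pi = np.asarray(self.class_prevalences, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
            raise ValueError("class_prevalences must be nonnegative and sum to 1")
        n_classes = len(pi)
        for item, rows in self.item_response.items():
            if len(rows) != n_classes:
                raise ValueError(f"item_response[{item!r}] must have one row per class")
            for c, row in enumerate(rows):
                r = np.asarray(row, dtype=float)
                if abs(r.sum() - 1.0) > 1e-9 or (r < 0).any():
                    raise ValueError(f"item_response[{item!r}] class {c + 1} row is not a distribution")
        mix = np.asarray(self.topic_mixtures, dtype=float)
        if mix.shape[0] != n_classes:
            raise ValueError("topic_mixtures must have one row per class")
        if np.abs(mix.sum(axis=1) - 1.0).max() > 1e-9 or (mix < 0).any():
            raise ValueError("topic_mixtures rows must be distributions")
        for name, dist in self.topic_word.items():
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in dist.values()):
                raise ValueError(f"topic_word[{name!r}] is not a distribution")
        for key in ("readmission",):
            rates = np.asarray(self.outcome_rates[key], dtype=float)
            if ((rates < 0) | (rates > 1)).any():
                raise ValueError(f"outcome_rates[{key!r}] must lie in [0, 1]")
        for c, row in enumerate(self.outcome_rates["disposition"]):
            r = np.asarray(row, dtype=float)
            if abs(r.sum() - 1.0) > 1e-9 or (r < 0).any():
                raise ValueError(f"outcome_rates['disposition'] class {c + 1} row is not a distribution")
        for name, rate in (("transfer_rate", self.transfer_rate), ("pediatric_rate", self.pediatric_rate)):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_prevalences)

    @property
    def n_topics(self) -> int:
        return len(self.topic_mixtures[0])

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CohortConfig":
        kwargs = dict(d)
        for key in ("class_prevalences", "notes_per_encounter"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "item_response" in kwargs:
            kwargs["item_response"] = {
                k: tuple(tuple(row) for row in v) for k, v in kwargs["item_response"].items()
            }
        if "topic_mixtures" in kwargs:
            kwargs["topic_mixtures"] = tuple(tuple(row) for row in kwargs["topic_mixtures"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/tuples for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def expected_background_flag_rate(cfg: CohortConfig) -> float:
    """Probability a background (non-misuse, non-excluded) encounter is flagged.

    Background panels carry at most one positive marker, so only the
    unexplained-opiate criterion and the misuse ICD tag can fire.
    """
    bg = cfg.background
    p_crit2 = bg["uds_order_rate"] * bg["opiate_pos_given_uds"] * bg["unexplained_given_opiate_pos"]
    p_crit3 = bg["misuse_icd_rate"]
    return 1.0 - (1.0 - p_crit2) * (1.0 - p_crit3)


def default_config(
    n_encounters: int = 228_884, seed: int = 0, target_flagged_fraction: float = 0.027, **overrides: Any
) -> CohortConfig:
    """Study-condition defaults with the planted-misuse rate solved so that
    the expected overall flagged fraction equals ``target_flagged_fraction``.

    Flagged = planted misuse (always criteria-positive by construction) plus
    background false positives, over all ``n_encounters`` including the
    excluded pediatric/transfer records which are never flagged.
    """
    probe = CohortConfig(n_encounters=0, seed=seed, **overrides)
    p_excl = 1.0 - (1.0 - probe.transfer_rate) * (1.0 - probe.pediatric_rate)
    b = expected_background_flag_rate(probe)
    p_mis = (target_flagged_fraction / (1.0 - p_excl) - b) / (1.0 - b)
    if not 0.0 < p_mis < 1.0:
        raise ValueError("target_flagged_fraction incompatible with exclusion/background rates")
    return CohortConfig(n_encounters=n_encounters, misuse_prevalence=p_mis, seed=seed, **overrides)


def config_hash(cfg: CohortConfig) -> str:
    """Stable short hash of a config (for run manifests)."""
    payload = json.dumps(_plain(cfg.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
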