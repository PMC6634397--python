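"""End-to-end orchestration: simulate -> phenotype -> LCA -> topics -> outcomes.

One :class:`PipelineConfig` and one seed drive the full run; the global seed
is expanded into per-stage seeds by a fixed derivation
(``SeedSequence([seed, stage_index])``, reduced mod 2**31) so that stages
can be re-run in isolation.  Every stage writes its outputs under the run
directory and consumes only files produced by earlier stages or the config;
a manifest records the config hash, per-stage seeds and row counts.
Identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .config import AGE_BANDS, CohortConfig, config_hash, default_config
from .indicators import age_band_index, build_indicator_matrix
from .lca import (
    assign_classes,
    class_separation,
    default_indicator_spec,
    match_classes,
    params_from_config,
    posterior_matrix,
    select_model,
)
from .outcomes import (
    compare_classes,
    disposition_table,
    flag_unplanned_readmission_30d,
    naloxone_early_flag,
    planned_encounter_ids,
)
from .phenotype import CodeSetRegistry, build_cohort, evaluate_all, misuse_confusion
from .simulate import STUDY_END, STUDY_START, generate_cohort, generate_notes, plant_readmissions
from .topics import (
    build_vocabulary,
    class_topic_matrix,
    corpus_from_notes,
    encounter_topic_distribution,
    fit_topic_model,
    select_topic_count,
)

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "run_pipeline",
    "characteristics_report",
    "fit_curve_report",
    "poverty_category",
]


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return int(np.random.SeedSequence([int(seed), int(stage_index)]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    cohort: CohortConfig = dc_field(default_factory=lambda: default_config(n_encounters=20_000))
    mode: str = "encounter_level"
    c_range: tuple[int, ...] = tuple(range(1, 9))
    lca_starts: int = 20
    lca_tol: float = 1e-8
    topic_k: int | None = 20
    k_range: tuple[int, ...] = ()
    passes: int = 100
    alpha: float = 0.1
    beta: float = 0.01
    seed: int = 0
    registry: CodeSetRegistry = dc_field(default_factory=CodeSetRegistry)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, write all outputs, return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config_hash(config.cohort),
        "seed": config.seed,
        "stage_seeds": {},
        "row_counts": {},
        "study_period": [str(STUDY_START.date()), str(STUDY_END.date())],
        "mode": config.mode,
    }

    # stage 1: simulate
    cohort_cfg = config.cohort
    s1 = stage_seed(config.seed, 1)
    cohort_cfg = CohortConfig(**{**cohort_cfg.to_dict(), "seed": s1}) if cohort_cfg.seed != s1 else cohort_cfg
    manifest["stage_seeds"]["simulate"] = cohort_cfg.seed
    tables = generate_cohort(cohort_cfg)
    io_mod.write_tables(tables, outdir)
    cohort_cfg.to_yaml(str(outdir / "config.yaml"))
    manifest["row_counts"]["encounters"] = int(len(tables.encounters))

    # stage 2: phenotype
    evaluations = evaluate_all(
        tables.encounters, tables.uds, tables.medications, tables.diagnoses, config.registry
    )
    evaluations.to_csv(outdir / "evaluations.csv", index=False)
    cohort = build_cohort(tables.encounters, evaluations, mode=config.mode)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    manifest["row_counts"]["cohort"] = int(len(cohort))
    manifest["phenotype_recovery"] = misuse_confusion(evaluations, tables.ground_truth)
    if len(cohort) == 0:
        io_mod.write_manifest(outdir / "manifest.json", manifest)
        warnings.warn("no misuse encounters; downstream stages skipped")
        return manifest

    # stage 3: latent class analysis
    s3 = stage_seed(config.seed, 3)
    manifest["stage_seeds"]["lca"] = s3
    spec = default_indicator_spec()
    ind = build_indicator_matrix(cohort, tables.uds, tables.medications, tables.diagnoses, config.registry)
    ind.to_csv(outdir / "indicators.csv")
    selection = select_model(
        ind.to_numpy(), c_range=config.c_range, n_starts=config.lca_starts,
        tol=config.lca_tol, seed=s3, item_names=spec.names, n_levels=list(spec.n_levels),
    )
    fit_curve = fit_curve_report(selection)
    fit_curve.to_csv(outdir / "fit_curve.csv", index=False)
    best = selection.fits[selection.c_values.index(selection.selected)]
    best.params.to_json(str(outdir / "lca_params.json"))
    post = posterior_matrix(ind.to_numpy(), best.params)
    labels = assign_classes(post)
    # stable presentation order: match fitted classes to the generating truth
    if best.params.n_classes == cohort_cfg.n_classes:
        perm = match_classes(best.params, params_from_config(cohort_cfg))
        relabel = np.empty_like(perm)
        relabel[perm] = np.arange(len(perm))
        labels = relabel[labels]
        post = post[:, perm]
    pd.DataFrame(post, index=ind.index).to_csv(outdir / "posterior.csv")
    label_s = pd.Series(labels + 1, index=ind.index, name="class")
    label_s.to_csv(outdir / "assignments.csv")
    manifest["selected_classes"] = selection.selected
    manifest["selection_rationale"] = selection.rationale
    manifest["class_separation"] = {
        int(c) + 1: [round(m, 4), round(s, 4)] for c, (m, s) in class_separation(post, labels).items()
    }

    # stage 4: topics
    s4 = stage_seed(config.seed, 4)
    manifest["stage_seeds"]["topics"] = s4
    notes = generate_notes(tables.encounters, tables.ground_truth, cohort_cfg, seed=s4)
    io_mod.write_notes_jsonl(notes, outdir / "notes.jsonl")
    notes_cohort = notes[notes["encounter_id"].isin(set(cohort["encounter_id"]))]
    vocab = build_vocabulary(notes_cohort)
    pd.DataFrame({"concept": vocab.concepts, "doc_freq": vocab.doc_freq}).to_csv(
        outdir / "vocabulary.csv", index=False
    )
    corpus = corpus_from_notes(notes_cohort.reset_index(drop=True), vocab)
    if config.k_range:
        curve, K = select_topic_count(
            corpus, config.k_range, passes=config.passes,
            alpha=config.alpha, beta=config.beta, seed=s4,
        )
        curve.to_csv(outdir / "coherence_curve.csv", index=False)
    else:
        K = config.topic_k or cohort_cfg.n_topics
    model = fit_topic_model(corpus, K, passes=config.passes, alpha=config.alpha, beta=config.beta, seed=s4)
    pd.DataFrame(model.phi, columns=vocab.concepts).to_csv(outdir / "phi.csv", index=False)
    enc_topics = encounter_topic_distribution(model, corpus)
    enc_topics.to_csv(outdir / "encounter_topics.csv")
    ct = class_topic_matrix(enc_topics, label_s)
    ct.to_csv(outdir / "class_topics.csv")
    manifest["row_counts"]["notes"] = int(len(notes))
    manifest["topics_k"] = int(K)

    # stage 5: outcomes
    s5 = stage_seed(config.seed, 5)
    manifest["stage_seeds"]["outcomes"] = s5
    full_enc = plant_readmissions(tables, cohort_cfg, seed=s5)
    planned = planned_encounter_ids(tables.diagnoses, config.registry)
    flags = flag_unplanned_readmission_30d(full_enc, planned, STUDY_END)
    flags.to_csv(outdir / "readmission_flags.csv", index=False)
    cohort_flags = flags[flags["encounter_id"].isin(set(cohort["encounter_id"]))]
    otable = disposition_table(cohort, label_s, cohort_flags)
    otable.to_csv(outdir / "outcome_table.csv")
    comparisons = {}
    for outcome in ("readmit", "home", "psychiatric", "AMA", "death", "other"):
        res = compare_classes(otable, outcome, "all_classes")
        comparisons[outcome] = {"statistic": res.statistic, "pvalue": res.pvalue}
    io_mod.write_manifest(outdir / "comparisons.json", comparisons)
    manifest["row_counts"]["planted_encounters"] = int(len(full_enc) - len(tables.encounters))

    # stage 6: characteristics report
    report = characteristics_report(cohort, label_s, tables, config.registry)
    report.to_csv(outdir / "characteristics.csv", index=False)

    io_mod.write_manifest(outdir / "manifest.json", manifest)
    return manifest


def poverty_category(pct_poverty) -> np.ndarray:
    """Census-tract poverty category: high >= 20.0%, middle 10.0-19.9%, low <= 9.9%."""
    p = np.asarray(pct_poverty, dtype=float)
    return np.where(p >= 20.0, "high", np.where(p >= 10.0, "middle", "low"))


def characteristics_report(
    cohort: pd.DataFrame,
    class_labels: pd.Series,
    tables,
    registry: CodeSetRegistry | None = None,
) -> pd.DataFrame:
    """Per-class patient characteristics table (tidy long format).

    Columns: characteristic, level, stat, overall, class_<c>...  Missing
    attribute columns are listed in ``.attrs['missing']`` and skipped.
    """
    registry = registry or CodeSetRegistry()
    labels = class_labels.reindex(cohort["encounter_id"])
    classes = sorted(int(c) for c in pd.unique(labels.dropna()))
    groups = {"overall": np.ones(len(cohort), dtype=bool)}
    for c in classes:
        groups[f"class_{c}"] = (labels == c).to_numpy()
    missing: list[str] = []
    rows: list[dict] = []

    def add(characteristic: str, level: str, stat: str, values: dict) -> None:
        rows.append({"characteristic": characteristic, "level": level, "stat": stat, **values})

    def pct_row(characteristic: str, level: str, flags: np.ndarray) -> None:
        add(characteristic, level, "pct",
            {g: 100.0 * flags[m].mean() if m.any() else np.nan for g, m in groups.items()})

    add("n", "", "count", {g: int(m.sum()) for g, m in groups.items()})

    try:
        band = age_band_index(cohort["age_years"].to_numpy())
        band_names = [f"{lo}-{hi}" for lo, hi in AGE_BANDS]
        band_names[0], band_names[-1] = "<=25", ">=56"
        for b, name in enumerate(band_names):
            pct_row("age", name, band == b)
    except KeyError:
        missing.append("age_years")
    for col, characteristic in (("sex", "sex"), ("race", "race"),
                                ("insurance", "insurance"), ("service", "service")):
        if col not in cohort.columns:
            missing.append(col)
            continue
        for level in sorted(pd.unique(cohort[col].astype(str))):
            pct_row(characteristic, level, (cohort[col].astype(str) == level).to_numpy())
    if "elixhauser_score" in cohort.columns:
        vals = cohort["elixhauser_score"].to_numpy(dtype=float)
        add("elixhauser", "", "mean", {g: float(vals[m].mean()) for g, m in groups.items()})
        add("elixhauser", "", "sd", {g: float(vals[m].std()) for g, m in groups.items()})
    else:
        missing.append("elixhauser_score")

    eid = cohort["encounter_id"]
    dx = tables.diagnoses
    for tag in sorted(registry.code_sets):
        if tag == "planned_readmission":
            continue
        tagged = set(dx.loc[dx["code"].isin(registry.codes(tag)), "encounter_id"])
        pct_row("comorbidity", tag, eid.isin(tagged).to_numpy())

    uds = tables.uds
    tested = set(uds["encounter_id"])
    pct_row("uds", "tested", eid.isin(tested).to_numpy())
    for col, name in (("opiate_pos", "opiate"), ("cocaine_pos", "cocaine"), ("pcp_pos", "pcp"),
                      ("benzo_pos", "benzodiazepine"), ("amphetamine_pos", "amphetamine")):
        pos = set(uds.loc[uds[col].astype(bool), "encounter_id"])
        pct_row("uds_positive", name, eid.isin(pos).to_numpy())

    if "naloxone_time" in cohort.columns:
        given = cohort["naloxone_time"].notna().to_numpy()
        pct_row("naloxone", "given", given)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            early = np.array([naloxone_early_flag(r) for _, r in cohort.iterrows()])
        pct_row("naloxone", "early", early)
    else:
        missing.append("naloxone_time")

    # prior encounters within 1 year (from the full encounter table)
    enc_all = tables.encounters[["encounter_id", "patient_id", "admit_time"]]
    m = cohort[["encounter_id", "patient_id", "admit_time"]].merge(
        enc_all, on="patient_id", suffixes=("", "_other")
    )
    prior = m[(m["admit_time_other"] < m["admit_time"])
              & (m["admit_time_other"] >= m["admit_time"] - pd.Timedelta(days=365))]
    prior_counts = prior.groupby("encounter_id").size()
    k = eid.map(prior_counts).fillna(0).to_numpy()
    pct_row("prior_encounters_1y", "0", k == 0)
    pct_row("prior_encounters_1y", "1-2", (k >= 1) & (k <= 2))
    pct_row("prior_encounters_1y", ">=3", k >= 3)

    tract = tables.tract.set_index("patient_id")
    joined = cohort[["patient_id"]].join(tract, on="patient_id")
    for attr in ("pct_poverty", "pct_employed", "pct_college", "pct_homeowner", "median_earnings"):
        if attr not in joined.columns:
            missing.append(attr)
            continue
        vals = joined[attr].to_numpy(dtype=float)
        add("tract", attr, "mean", {g: float(np.nanmean(vals[m_])) for g, m_ in groups.items()})
        add("tract", attr, "sd", {g: float(np.nanstd(vals[m_])) for g, m_ in groups.items()})
    if "pct_poverty" in joined.columns:
        cat = poverty_category(joined["pct_poverty"].to_numpy())
        for level in ("high", "middle", "low"):
            pct_row("poverty_category", level, cat == level)

    out = pd.DataFrame(rows)
    out.attrs["missing"] = missing
    return out


def fit_curve_report(selection) -> pd.DataFrame:
    """Fit-statistic table (one row per C) with the selection rationale attached."""
    if len(selection.fits) < 2:
        raise ValueError("need fits for at least 2 class counts")
    df = pd.DataFrame({
        "C": selection.c_values,
        "loglik": [f.loglik for f in selection.fits],
        "k": [f.n_params for f in selection.fits],
        "bic": [f.bic for f in selection.fits],
        "abic": [f.abic for f in selection.fits],
        "caic": [f.caic for f in selection.fits],
        "converged": [f.converged for f in selection.fits],
    })
    df.attrs["selected"] = selection.selected
    df.attrs["rationale"] = selection.rationale
    return df
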