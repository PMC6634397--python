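"""Apply the operational opioid-misuse definition to a synthetic cohort.

Three criteria flag an encounter: (1) eligible opiate-positive screen with
unexplained polysubstance positivity, (2) eligible opiate-positive screen
without an admission opioid prescription, (3) an opioid-related
hospitalization diagnosis code.  Transfers and patients under 18 are
excluded.  Because ground truth exists for synthetic data, sensitivity and
specificity of the rules can be reported.
"""

from opioid_subtypes import default_config, evaluate_all, generate_cohort
from opioid_subtypes.phenotype import build_cohort, misuse_confusion

cfg = default_config(n_encounters=50_000, seed=1)
tables = generate_cohort(cfg)
evaluations = evaluate_all(tables.encounters, tables.uds, tables.medications, tables.diagnoses)

n = len(evaluations)
flagged = int(evaluations["is_misuse"].sum())
print(f"flagged {flagged:,} of {n:,} encounters ({100 * flagged / n:.2f}%)")
for crit in ("criterion1", "criterion2", "criterion3"):
    print(f"  {crit}: {int(evaluations[crit].sum()):,} encounters")
excl = evaluations["exclusion_reason"].value_counts()
print("exclusions:", dict(excl))

stats = misuse_confusion(evaluations, tables.ground_truth)
print(f"sensitivity {stats['sensitivity']:.3f}, specificity {stats['specificity']:.4f} "
      f"(tp={stats['tp']}, fp={stats['fp']}, fn={stats['fn']})")

cohort = build_cohort(tables.encounters, evaluations, mode="encounter_level")
patient = build_cohort(tables.encounters, evaluations, mode="patient_level")
print(f"analysis cohort: {len(cohort):,} encounters; "
      f"patient-level sensitivity cohort: {len(patient):,} (latest encounter per patient)")
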