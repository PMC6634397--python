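"""Generate a small synthetic EHR cohort and look at what it contains.

The generator plants opioid-misuse encounters with a hidden 4-class
structure; everything downstream (phenotyping, LCA, topics, outcomes)
consumes only the raw tables, never the hidden labels.
"""

from opioid_subtypes import default_config, generate_cohort

cfg = default_config(n_encounters=20_000, seed=0)
tables = generate_cohort(cfg)

print(f"encounters: {len(tables.encounters):,}")
print(f"urine drug screens: {len(tables.uds):,}")
print(f"medication events: {len(tables.medications):,}")
print(f"diagnosis rows: {len(tables.diagnoses):,}")
gt = tables.ground_truth
print(f"planted misuse encounters: {int(gt['true_misuse'].sum()):,} "
      f"({100 * gt['true_misuse'].mean():.2f}% of all encounters)")
shares = gt.loc[gt["true_misuse"], "true_class"].value_counts(normalize=True).sort_index()
print("hidden class shares among misuse encounters:")
for c, s in shares.items():
    print(f"  class {c}: {100 * s:.1f}%")
print("\nThe planted rate is solved so that the *flagged* fraction, after the")
print("rule engine runs and background false positives are added, lands at 2.7%.")
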