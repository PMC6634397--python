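# opioid-subtypes

Latent-class subtyping of opioid misuse from EHR-style tables: a tested,
reusable re-implementation of a prognostic-enrichment analysis for
hospitalized patients, built around a calibrated synthetic EHR cohort.

## Who this is for

Clinical informaticians and biostatisticians who want to (a) identify
opioid-misuse encounters from structured EHR data with a transparent rule
engine, (b) discover misuse subtypes with latent class analysis, (c)
validate subtypes against clinical-note content with topic models, and (d)
compare hospital outcomes across subtypes — or who want a fully seeded
synthetic substrate on which to exercise such a pipeline end to end.

## The model

**Phenotyping.** An encounter is flagged as opioid misuse if any of:
(1) an eligible urine drug screen positive for an opiate *and* for
phencyclidine, cocaine, or a benzodiazepine/amphetamine absent from the
admission medication list; (2) an eligible opiate-positive screen without
an admission opioid prescription; (3) an opioid-related hospitalization
diagnosis code.  A screen is eligible only if no opioid or benzodiazepine
was dispensed by the pharmacy at or before its order time.  Transfers and
patients under 18 are excluded.

**Subtyping.** For encounter *i* with categorical indicators
*y<sub>i1</sub> … y<sub>iJ</sub>* (J = 10: a 5-level age band, six binary
diagnosis items, three binary drug-screen items), the latent class model is

&nbsp;&nbsp;&nbsp;&nbsp;P(y<sub>i</sub>) = Σ<sub>c</sub> π<sub>c</sub> Π<sub>j</sub> ρ<sub>c,j,y<sub>ij</sub></sub>

with class prevalences π and item-response probabilities ρ, fitted by EM
with random restarts for C = 1..8 and compared via
BIC = −2ℓ + k ln n, aBIC = −2ℓ + k ln((n+2)/24), cAIC = −2ℓ + k(ln n + 1),
where k = (C−1) + C Σ<sub>j</sub>(R<sub>j</sub>−1).  Encounters are
assigned to their maximum-posterior class.

**Validation.** Concept-bag notes are filtered to concepts appearing in
strictly between 10% and 70% of notes, modeled with latent Dirichlet
allocation (collapsed Gibbs), and each class is summarized by the mean
topic probability over its encounters.  Outcomes use CMS-style 30-day
unplanned readmission rules (planned readmissions cancel the window,
same-day admissions never count, one outcome per index) and discharge
dispositions, compared across classes by Pearson chi-square.

The synthetic generator inverts the published summary surfaces: class
prevalences (36.5/12.8/39.2/11.5%), per-class indicator rates, per-class
topic mixtures and per-class outcome rates are generator truth, so every
stage can be recovery-tested against what was planted.

## Worked example

```bash
python examples/lca_subtypes.py
```

prints (seeded, reproducible):

```
 C     loglik    k      BIC     aBIC     cAIC
 1   -36195.5   13   72504.5  72463.2  72517.5
 2   -35023.7   27   70283.2  70197.4  70310.2
 3   -34487.4   41   69333.1  69202.8  69374.1
 4   -34121.0   55   68722.5  68547.7  68777.5
 5   -34110.6   69   68824.0  68604.7  68893.0
 ...
selected: 4 classes (BIC minimum at C=4)
matched prevalence estimates (%): [37.28 11.99 39.59 11.14]  generating: [36.5 12.8 39.2 11.5]
mean assigned-class posterior per class: {1: 0.96, 2: 0.92, 3: 0.97, 4: 0.9}
```

Reading: on 6,224 encounters simulated from the calibrated 4-class truth,
BIC bottoms out at exactly four classes; the matched prevalence estimates
sit within ~1 percentage point of the generating values; and mean
assigned-class posteriors near 1 indicate clean class separation.  The
other scripts in `examples/` walk through cohort simulation, phenotyping
(with sensitivity/specificity against planted truth), topic-model
validation, and the readmission/disposition comparison.

A thin CLI wraps the same library:

```bash
opioid-subtypes run-all --n 20000 --seed 0 --outdir run/
```

writes every stage output (tables, fit curve, posteriors, class-topic
matrix, outcome table, characteristics report, manifest) under `run/`.

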