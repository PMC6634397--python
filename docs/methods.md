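# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the recovery tests do and do not demonstrate.

## The synthetic cohort as the study substrate

Real single-center EHR data of this kind cannot be shared, so the package
ships a generator whose *parameters are the published summary surfaces*: a
cohort of hospital encounters in which ~2.7% are flagged by the misuse
definition, misuse encounters carry one of four latent subtypes with
prevalences 36.5/12.8/39.2/11.5%, each subtype has its own indicator
distribution (the published per-class column percentages used directly as
item-response probabilities), its own topic mixture over 20 note topics, and its own
30-day readmission and discharge-disposition rates.  Every downstream
stage is then a recovery experiment: the quantity the pipeline estimates
has a known planted value.

Key generator design points:

- **Definition-aligned planting.** Sampled indicators do not always satisfy
  a misuse criterion (e.g. a low-utilization encounter with only an
  unexplained benzodiazepine positive).  Such encounters receive an
  *explained* opiate-positive screen (opioid on the admission list) and, if
  needed, an amphetamine positive absent from the admission list — both
  invisible to the ten class-defining indicators — so that every planted
  encounter trips at least one criterion.  Consequence: phenotyper
  sensitivity on synthetic data is ~1.0 by construction.  The real-world
  definition had sensitivity 88.6%; that measurement error is *not*
  emulated, and passing recovery tests say nothing about it.
- **Calibrated flagged fraction.** The flagged cohort is the analysis
  population, so the planted per-eligible-encounter misuse rate is solved
  analytically from the target flagged fraction (2.7%), the
  pediatric/transfer exclusion rates (2%/3%), and the background
  false-positive rate.  Background encounters carry low marker rates (8%
  screen orders; 12% of those opiate-positive, 2% of *those* unexplained;
  0.05% stray misuse codes), kept small enough (~2.5% cohort
  contamination) that the planted class structure dominates the flagged
  population; they exist so specificity is a real, measurable quantity.
- **Age** is drawn uniformly within the five study bands; **timestamps**
  live on a fictional 2007–2017 calendar with minute resolution;
  per-patient encounter counts are geometric with mean 1.3 (a default not
  anchored in the source material); overlapping stays are truncated to
  keep each patient's timeline consistent (half-open intervals).
- **Notes.** Each misuse encounter gets 1–3 notes of ~60 concept tokens.
  A note's topic weights are drawn from Dirichlet(s·m<sub>c</sub>) around
  its class mixture m<sub>c</sub> (concentration s = 5), then tokens are
  drawn topic-first.  The Dirichlet step makes individual notes
  topic-concentrated — which is both how clinical notes behave and the
  regime in which LDA is identifiable — while leaving the class-level
  expected topic distribution equal to the configured mixture, which is
  what the class-topic recovery tests check.  Default topic-concept
  distributions are uniform over per-topic blocks of synthetic concept
  identifiers, with block sizes scaled to the topic's mean weight so that
  every concept's document frequency falls strictly inside the (10%, 70%)
  retention band.
- **Outcomes.** Dispositions are drawn per class at the configured rates.
  Readmissions are planted at the outcomes stage: each CMS-eligible index
  misuse encounter receives, with its class's probability, a future
  unplanned inpatient admission 1–28 days after discharge.  Rates are
  planted among *eligible index* encounters because that is the
  denominator behind the published per-class percentages; the pooled
  "rest" comparison is reported over all class members, matching how the
  published pooled figure was formed.

**No leakage:** the hidden class and misuse labels live only in the
ground-truth table; the five data tables contain no latent fields (unit
tested).

## Phenotyping rules

"Admission medication record" means `source == "admission_mar"`; inpatient
dispensing matters only for screen-eligibility timing.  A dispense at
exactly the order time counts as dispensed-before (conservative).  With
multiple panels per encounter, criteria are satisfied if *any eligible*
panel satisfies them.  Naloxone administration and overdose codes are
descriptors, not criteria (they could not be reliably discriminated in the
source setting).  The engine is verified against an independent
brute-force transcription of the rules on all 4,096 combinations of screen
flags × medication states × diagnosis tag.

## Latent class analysis

EM runs on the collapsed table of unique response patterns (exact and
fast).  Initialization: ρ from Dirichlet(1), π uniform; defaults 20
restarts, tol 1e-8 relative log-likelihood, max 5000 iterations.  M-steps
are exact, so the log-likelihood trajectory is non-decreasing
(property-tested at 1e-10); the returned parameters are floored at 1e-6
and renormalized once at exit so posterior evaluation on unseen patterns
never hits log(0).  The returned log-likelihood is computed under the
floored parameters.

**Model selection** defaults to the BIC minimum over the sweep; when BIC is
still decreasing at the top of the range, a relative-elbow rule (stop when
the improvement to the next model falls below 1% of |BIC|) picks the point
of diminishing returns.  The full fit table is always emitted — on real
data, prevalence balance and interpretability belong in the decision, and
an automatic rule is only a proxy.

**Label matching** minimizes total L1 distance between item-response
profiles via the Hungarian algorithm (equivalent to exhaustive search for
this additive cost; cross-checked against enumeration in tests).

Two statistical caveats the recovery tests surfaced, documented here
because they are properties of the method, not bugs:

- *Modal-assignment bias.* Classes 1 and 3 differ mainly on the
  alcohol/liver items, so class-3 encounters carrying neither tag (~9% of
  the class) are modally assigned to class 1.  Assignment *shares* are
  therefore biased (~+4pp on class 1) even when the mixture weights π̂ are
  nearly unbiased; prevalence recovery is assessed and reported via π̂.
- *A weakly identified ridge.* The same proximity gives the likelihood a
  flat ridge along which prevalence mass trades between classes 1 and 3;
  the MLE π̂ for those classes has a standard error of roughly 1.5–2
  percentage points at n = 6,224 — several times the naive multinomial SE.

## Topic modeling

Collapsed Gibbs sampling with symmetric priors (α = 0.1 document-topic,
β = 0.01 topic-concept), 250 full passes by default, deterministic given a
seed (per-pass uniforms come from a seeded generator).  Plain random token
initialization reliably lands in split/duplicate-topic local optima on
block-structured corpora (the largest topic splits in two while the two
smallest merge — moves Gibbs essentially cannot undo because separating
duplicate topics is an unbiased random walk).  Two measures address this:
tokens are seeded from a spectral clustering of the concept co-occurrence
graph (`init="cooccurrence"`, the default; `init="random"` gives the
vanilla chain), and the best of `n_starts` (default 3) chains by collapsed
joint log p(w, z) is kept.

Topic-count selection uses UMass coherence (document co-occurrence with +1
smoothing) over each topic's top-10 concepts.  Coherence plateaus for
K ≥ the true topic count on separable corpora, so the selected K is the
smallest within 2% (relative) of the best score rather than the raw
argmax.  The published corpus-specific values (20 topics, coherence 0.51
on 422,147 real notes) depend on data this package cannot reproduce;
selection logic is instead validated on separable synthetic corpora.

Note→encounter aggregation is the unweighted mean of θ over the
encounter's notes; encounters whose notes were emptied by the vocabulary
filter get a uniform distribution with a warning.

## Outcomes

Day arithmetic uses calendar dates, not timestamps.  For an eligible index
(not a death, not discharged within 30 days of study end, not itself
planned), subsequent same-patient admissions are scanned in admit order:
same-calendar-day admissions are skipped; the first admission with
0 < Δdays ≤ 30 decides the outcome (planned → cancelled, unplanned →
counted once).  The engine matches an exhaustive day-grid oracle over all
admission sequences of length ≤ 4.  Chi-square comparisons are Pearson
without continuity correction (a Yates-corrected variant is available);
readmission percentages are reported over both eligible-index and
all-encounter denominators, labeled as such.

## Problem sizes used by tests and the acceptance script

Generation and phenotyping run at the full 228,884-encounter scale
(seconds, vectorized).  LCA recovery runs at the published cohort size
n = 6,224 with 20 restarts per class count.  Topic-model recovery runs on
a ~1,500-encounter, ~2,250-note corpus with 100 Gibbs passes — large
enough that every class-topic cell's Monte-Carlo error is well under the
0.05 assessment band, and small enough to keep the suite fast.

## Known limitations

- Measurement error of the misuse definition (the real 88.6%/78.5%
  sensitivity/specificity) is not modeled; synthetic recovery therefore
  overstates real-world phenotype quality.
- ICD codes are synthetic stand-ins with tag semantics only; no real
  ICD-9/10 vocabularies, no free text, no cTAKES stage.
- Census-tract attributes are drawn per patient from class-conditional
  normals; no spatial structure.
- No latent-class regression (covariates on membership), no bootstrap
  likelihood-ratio test, no missing-data EM; indicator matrices must be
  complete.
- A production-scale note corpus (hundreds of thousands of notes, tens of
  thousands of concepts) is out of reach here; topic results are validated
  at reduced scale.
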