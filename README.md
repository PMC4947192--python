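# sltplan

Case-based generation of five-area speech-and-language therapy (SLT) plans.

Speech and language pathologists (SLPs) design semiannual therapy plans
covering five speech-language areas — hearing; oral structure & function;
linguistic formulation; expressive language & articulation; receptive
language — but rarely have the time to search a growing catalogue of
activities and exercises for each new patient. `sltplan` implements a
case-based recommender for this task: given a corpus of prior patient cases
(medical record, cognitive-development ages, a binary 102-parameter SLT
evaluation, and the therapy plan an SLP designed), it retrieves the most
similar prior cases *per area* and assembles a five-subplan therapy plan
with full provenance, so the clinician can see which cases it was adapted
from and why.

## Method

Every case `S` carries a binary medical-feature vector, four
cognitive-development ages (cognitive age, language-development gap,
expressive and receptive language age, all in months), and per-area binary
evaluation vectors. Two distances drive retrieval for an area `A`:

* **level 1** — mean-Manhattan binary distance over the medical features
  relevant to `A`:
  `d₁(Sᵢ, Sⱼ; A) = (1/|F_A|) Σ_{f ∈ F_A} |xᵢf − xⱼf|`;
* **level 2** — mean-Manhattan distance over `A`'s evaluation dimensions
  plus an age scale factor:
  `d₂(Sᵢ, Sⱼ; A) = (1/|D_A|) Σ_{d ∈ D_A} |eᵢd − eⱼd|
   + λ · (1/4) Σ_c min(|aᵢc − aⱼc| / T, 1)`,
  with `λ = 1` and `T = 216` months by default.

Training builds, for each area, a two-level medoid hierarchy with a
from-scratch Partition Around Medoids (PAM, BUILD + SWAP with seeded
restarts): first-level clusters group patients with similar area-relevant
medical profiles; each first-level cluster is re-clustered by the
fine-grained level-2 metric. Medoids are always real cases, never averages.
A new case descends the hierarchy (nearest first-level medoid, nearest
second-level medoid) and its K nearest neighbours in that cluster supply
the area subplan — copied from the single nearest case, or combined as
superset / intersection / symmetric difference across equally distant
cases. The coincidence percent shown in provenance is
`(1 − mean-Manhattan) × 100` over the area's evaluation dimensions.

Because real clinical corpora cannot be shipped, `sltplan.simulate` draws
seeded synthetic cohorts from latent condition templates (cerebral palsy,
Down syndrome, intellectual disability, autistic disorder, fetal alcohol
syndrome, mixed language disorder) with independent feature-flip noise, and
`sltplan.evaluate` runs a k-fold cross-validation harness that scores
generated subplans against each held-out case's stored subplan by Jaccard
overlap of activity IDs.

## Worked example

```python
from sltplan import (SimConfig, TherapyPlanRecommender, default_catalogue,
                     generate_corpus, generate_new_cases, cross_validate)

cat = default_catalogue()
cfg = SimConfig(seed=0)                  # 117-case cohort, 2% flip noise
corpus, _ = generate_corpus(cfg, cat)
rec = TherapyPlanRecommender(random_state=0).fit(corpus)

queries, truth = generate_new_cases(cfg, cat, n_new=13)
plan = rec.predict_one(queries[0])
sp = plan.subplans["hearing"]
print(sp.activities)
# ['ACT-H-C0-00', 'ACT-H-C0-01', 'ACT-H-C0-02', 'ACT-H-C0-03',
#  'ACT-H-C0-04', 'ACT-H-GEN-04']
p = sp.provenance[0]
print(p.source_case_id, p.coincidence_percent, p.matched_features[:2])
# case-013 100.0 ['cochleo-palpebral reflex present', 'startle response to sound']
```

The hearing subplan was copied from prior case `case-013`, whose hearing
evaluation coincides 100% with the query's (all five auditory items agree);
the listed activities are that case's stored hearing activities.

Four-fold cross-validation on the same cohort (τ = 0.5):

```python
report = cross_validate(corpus, cat, k_folds=4, tau=0.5, seed=0, random_state=0)
print(report.per_area_validity.round(1))
#                                     round 1  round 2  round 3  round 4  average
# hearing                               100.0     96.6    100.0     96.6     98.3
# oral structure & function             100.0     96.6     96.6    100.0     98.3
# linguistic formulation                100.0    100.0    100.0     93.1     98.3
# expressive language & articulation     93.3     93.1     93.1     93.1     93.2
# receptive language                    100.0     96.6    100.0     93.1     97.4
print(report.whole_plan_validity.round(1))
# round 1 93.3, round 2 82.8, round 3 89.7, round 4 75.9, average 85.4
```

A subplan is *valid* when its activity-set Jaccard against the held-out
case's stored subplan reaches τ; a whole plan is valid only if all five
subplans are, so whole-plan validity is always bounded by the worst area.

The same pipeline is available from the shell:

```sh
sltplan simulate --seed 0 --out corpus.jsonl --truth truth.json --new-cases 13
sltplan train --corpus corpus.jsonl --out hierarchy.json --seed 0
sltplan plan --hierarchy hierarchy.json --corpus corpus.jsonl \
             --case corpus.jsonl.new --out plans.json --report plans.md
sltplan cross-validate --corpus corpus.jsonl --k 4 --tau 0.5 --seed 7 --out report/
```

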