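# Methods

## Data model

A patient case holds: personal data (chronological age in integer months,
gender), a medical record (ICD-10-CM diagnosis codes plus a binary vector
over a catalogue of 25 clinical findings), a cognitive-development record
(cognitive age, language-development gap, expressive and receptive language
age, all integer months), a five-area binary SLT evaluation totalling 102
parameters, and — for training cases — a therapy plan of five subplans
(activity and exercise identifier lists). Ages are kept in integer months
and round-trip a `"Y years, M months"` text form; integer storage keeps the
age scale factor free of float drift.

The packaged default catalogue splits the 102 evaluation parameters
5 / 25 / 10 / 52 / 10 across hearing, oral structure & function, linguistic
formulation, expressive language & articulation, and receptive language.
The hearing block is the five standard subjective auditory items
(cochleo-palpebral reflex, startle response, head turn to sound,
identification of sound objects, localisation without visual cue); the
other blocks follow the usual clinical category lists (oromotor structure
and function items; respiration/phonation items; vocal development, social
communication, semantics, morphosyntax and phoneme-pronunciation items;
attention, comprehension and integration items). The exact composition of
a deployed 102-parameter battery varies between services; the catalogue is
a data file (`sltplan/data/default_catalogue.json`) precisely so a
deployment can substitute its own. Medical findings are grouped into five
disjoint area-relevant blocks of five (`features_MR(A)`), with diagnoses
carried by ICD-10-CM codes; disjoint blocks make the level-1 metric's
locality transparent and per-area template separation constructible.

## Distance metrics

For an area `A` with medical-feature index set `F_A` and evaluation
dimensions `D_A`:

* level 1: `d₁ = meanManhattan(x_i[F_A], x_j[F_A])` — used to form
  first-level clusters of patients whose area-relevant medical profile is
  similar even when the underlying diagnoses differ.
* level 2: `d₂ = meanManhattan(e_i[D_A], e_j[D_A]) + λ·(1/4)·Σ_c min(|Δa_c|/T, 1)`
  over the four cognitive ages — used inside first-level clusters to
  separate fine-grained skill profiles.

The scale factor is additive with default weight `λ = 1` and normalisation
`T = 216` months (18 years, the top of the paediatric range): each age
difference is divided by `T` and capped at 1, so the age term is
commensurate with the [0, 1] binary summand, one extreme developmental gap
cannot dominate, and `λ = 0` recovers the pure evaluation distance. The
additive capped-mean form was an open design choice; it was fixed once for
its boundedness and graceful degradation properties.

The coincidence percent reported in plan provenance is
`(1 − meanManhattan) × 100` over the relevant index set only — the age
scale factor never enters the figure a clinician sees. With the default
catalogue, full agreement on the five hearing items gives 100%, and a
single (three) disagreement(s) in a 10-dimension area gives 90% (70%).

## Clustering

Partition Around Medoids in the classic BUILD + SWAP form: BUILD greedily
adds the medoid that most reduces summed distance; SWAP repeatedly applies
the best cost-decreasing (medoid, non-medoid) exchange (gains evaluated
vectorised over candidates) until stable. All ties — BUILD candidates, SWAP
pairs, nearest-medoid assignment — resolve to the lowest index; the
hierarchy builder sorts cases lexicographically by case ID first, so every
tie-break is reproducible without randomness.

Best-improvement SWAP can stall in a swap-stable local optimum (observed on
roughly 4% of tiny random instances). The fitter therefore runs additional
SWAP descents from seeded random initial medoid sets (default 10 restarts)
and keeps the lowest-cost solution, preferring the deterministic BUILD
solution on ties; each descent still terminates with no improving single
swap. With restarts the result matched exhaustive search on 2000/2000
random instances with n ≤ 8, k ≤ 3. Restarts are cheap at corpus scale
(n ≈ 100) because swap gains are evaluated with O(k·n²) vectorised passes.

Cluster counts are config knobs; when set to `"auto"` (default) k is chosen
by maximum mean silhouette width over 2 … min(8, n−1), ties to the smallest
k, via scikit-learn's silhouette on the precomputed distance matrix. An
all-zero distance matrix short-circuits to the smallest k with a warning.
First-level clusters with fewer than three members are kept whole as a
single second-level cluster. The hierarchy serialises to JSON (medoids,
assignments, metric config) so planning can run without re-clustering.

## Retrieval and plan assembly

Classification of a new case is hierarchical per area: nearest first-level
medoid under `d₁`, nearest second-level medoid under `d₂`, then K nearest
members of that second-level cluster under `d₂` (K = 1 by default, with the
final rank expanded across its tie group; ties detected at absolute
tolerance 1e−9, appropriate because the distances are rationals assembled
from small integer sums). If the second-level cluster has fewer than K
members the search falls back to the whole first-level cluster. This
guided search can in principle miss the global nearest neighbour; the test
suite quantifies the miss rate against a brute-force oracle on a
well-separated cohort (≤ 10% tolerated there, typically 0).

Assembly modes: `nearest` copies the top neighbour's subplan verbatim;
`superset`, `intersection` and `disjunction` combine the rank-1 tie group's
activity/exercise sets (union, common items, symmetric difference),
preserving first-seen order for determinism. Every subplan records
provenance: source case IDs, coincidence percent, and the evaluation
dimensions on which query and source agree.

## Synthetic cohorts

The generator assumes a latent-template model: each condition owns a
medical-finding template, per-area evaluation templates, per-area
activity/exercise sets, and age distributions. Cases are drawn by flipping
each binary feature independently (defaults: 2% for evaluations and
medical findings), sampling ages from per-condition normals clipped to
0–216 months, and perturbing the plan (10% chance each of dropping one item
and of adding one general-purpose item per subplan, per kind). Defaults:
117 cases split 22 cerebral palsy / 19 Down syndrome / 10 intellectual
disability / 9 autistic disorder / 5 fetal alcohol syndrome / 52 mixed
language disorder; 13 plan-less query cases; 5 template activities and 5
exercises per area. Templates are greedily sampled under a pairwise
minimum Hamming separation (default 2) on every area's medical block and
evaluation dimensions, making low-noise cohorts identifiable by level-1
clustering. Ground truth (condition, template plan) is returned in a
sidecar mapping and never stored inside a case.

The per-condition age means/sds are plausible paediatric stand-ins, not
estimates from any published caseload; the condition mix and cohort sizes
are the study conditions the harness is run under. The model captures only
what the recommender consumes — binary agreement patterns and age gaps. It
does not emulate comorbidity structure, ordinal severities, longitudinal
change, or realistic activity catalogues, so passing tests demonstrate
correct mechanics and recoverability under the stated noise model, not
clinical validity on real children.

## Evaluation harness

k-fold cross-validation (default k = 4; a 117-case corpus deals into folds
of 29/29/29/30 after a seeded shuffle): each round trains the recommender
on the other folds and generates plans for the held-out cases with their
stored plans hidden. Scoring is the Jaccard overlap of activity-ID sets
against the stored subplan (empty ∪ empty defined as 1); exercises get a
second, separate Jaccard. A subplan is valid when Jaccard ≥ τ (default
0.5); a whole plan is valid only when all five subplans are. Jaccard
validity is a computable proxy for clinician Likert ratings of generated
plans, which require expert judgment and are out of scope; the proxy
mirrors the per-subplan, binary structure of such ratings but its
percentages are not comparable to human-rated ones. Folds are unstratified
by default; a condition-stratified deal is available when ground-truth
labels are supplied. A leakage audit counts held-out case IDs appearing
among medoids or retrieved neighbours (must be zero) and is asserted in the
harness's CLI.

## Numerical and degenerate-input choices

* Binary vectors are validated strictly ({0,1} only, no imputation of
  missing dimensions — no principled imputation rule exists for pass/fail
  SLT items).
* Distance matrices must be symmetric with zero diagonal (1e−12 tolerance).
* Tie tolerance for neighbour ranking: 1e−9 absolute.
* PAM swap acceptance threshold: 1e−12 (strict descent), restart wins only
  on strict improvement.
* Corpora of fewer than two cases, k > n fold or cluster requests, and
  evaluation vectors of the wrong length are rejected with named errors.

## Known limitations

* Retrieval searches one second-level cluster per area by design; rare
  global-nearest misses are possible and quantified, not eliminated.
* The silhouette-based k selection can pick the upper bound of its range on
  cohorts with many small homogeneous groups; this affects cluster
  granularity, not retrieval correctness, since retrieval re-ranks within
  the selected cluster.
* The default catalogue's dimension names are a faithful-in-shape stand-in
  for a deployed battery; coincidence denominators depend on the per-area
  dimension counts, so a different split changes reported percentages.
* Plans adapted from a single nearest case inherit that case's scope; no
  template-based generalisation across cases is attempted.
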