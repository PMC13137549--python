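# Methods

## The model

`caremap` treats community age-friendly service need identification as a
deterministic translation from capability states to services, refined by a
population signal. Each subject i is encoded by two ordinal vectors on a
shared five-point scale (0 = no capability / heaviest need, 4 = full
capability / lightest need):

- `A_i ∈ {0,…,4}^28` — individual functional capability, the *source* of
  potential service needs;
- `B_i ∈ {0,…,4}^8` — family caregiving capability, a *moderator* that
  determines how much of the need must be met by external community
  services rather than within the household.

Registry order is the binding coordinate convention: indicator ids are
snake_case tokens fixed in the published table order, and all portraits,
community matrices and rule files share it.

### Stage 1 — total rule matrices

A mapping matrix assigns every (indicator, score level) pair a nonempty
list of service items; totality (|registry| × 5 rules, no duplicates, no
gaps) is validated at load time, so stage 1 can never fail at runtime.
Intervention intensity is grade = 5 − score level: a score of 4 triggers
grade-1 preventive items, a score of 0 triggers grade-5 full-care items.
This numeric convention is ours — the source tables order their columns
from lightest to heaviest but print no grade numbers.

Candidates from the individual and family matrices are merged by a
normalized service identity (casefolded, whitespace-collapsed label +
category); collisions keep the higher intensity grade and the union of
triggers. The merge is commutative and idempotent, and merged candidates
are sorted by identity key so the stage-1 output is a pure function of the
portraits.

### Stage 2 — collaborative-filtering re-ranking

Stage 2 is a permutation: it re-orders stage-1 candidates and never adds or
removes any. Each candidate's priority is

```
total = w_sev · severity + w_fam · family_deficit + w_sup · support
```

with default weights (0.5, 0.3, 0.2), all components in [0, 1]:

- **severity** = (4 − s)/4 for the most severe trigger score s;
- **family_deficit** = (4 − mean(B))/4 for purely individually-triggered
  candidates and (4 − s_f)/4 for candidates with a family trigger s_f
  (most severe if several). This makes the moderation direction explicit:
  lowering family capability can only raise individually-triggered totals
  when the support term is held fixed, and under the default weights a
  full family degradation (all-4 → all-0) raises them regardless, because
  the 0.3 family gain exceeds the maximal 0.2 support swing.
- **support** = Σ_j sim_j · 1[key ∈ S_j] / Σ_j sim_j over the k nearest
  neighbors j, where S_j is neighbor j's own stage-1 candidate key set.
  No service-utilization data exists, so neighbor needs are themselves
  rule-derived — prototype semantics for the recommendation layer.

Similarity operates on the concatenated dual vector (28 + 8 scores, each
divided by 4). Two metrics are available: cosine (default;
similarity of a zero vector with anything is defined as 0) and inverse
Euclidean 1/(1 + ‖u − v‖). Neighbor selection takes the top k = 5 above a
minimum similarity (default 0), breaking ties by lexicographically smaller
subject id; ranking ties break by higher intensity grade, then a canonical
category order, then label. Every tie-break is deterministic — repeated
runs are byte-identical, and the config's seed field is reserved for
future stochastic variants.

Totals are stratified with closed lower bounds: high ≥ 2/3, medium ≥ 1/3,
else low. Thresholds are configurable but must be strictly ordered in
(0, 1).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| weights (w_sev, w_fam, w_sup) | 0.5, 0.3, 0.2 | linear score fusion; must sum to 1 |
| metric | cosine | profile-shape similarity; `inverse_euclidean` is level-sensitive |
| k_neighbors | 5 | CF neighborhood size |
| min_similarity | 0.0 | neighbor eligibility floor |
| stratification | 2/3, 1/3 | closed lower bounds of high/medium |
| high-risk policy | m=3, s=1 | flag subjects with ≥ m indicators scored ≤ s |

The fusion form, weights, metric and k are our design choices: the
two-stage architecture (rules decide *what*, similarity refines *ranking*)
is given, but no numeric parameters are published. They are exposed in
`SimilarityConfig` and the YAML run config rather than hard-coded.

## Synthetic communities

No assessment dataset is published, so the generator emulates one. Each
subject draws a 36-dimensional latent Gaussian with an exchangeable
correlation ρ_w = 0.6 inside each portrait block and ρ_c = 0.3 across
blocks (positive semidefiniteness is checked eagerly); each coordinate is
thresholded into 0..4 at the normal quantiles of the cumulative
Binomial(4, m/4) distribution, m = 2.5 by default. This closed-form
calibration makes every marginal exactly Binomial(4, m/4) — unimodal with
mean m, which is what routine community assessments look like — without
numeric search. Optional mixture clusters shift the latent mean to emulate
frailer/fitter subpopulations.

What the generator does *not* emulate: real domain-specific correlation
structure (the exchangeable ρ values are placeholders; no empirical
magnitudes are published), demographic covariates driving capability,
informant/rater noise, and missing data (validation rejects missing scores
by design; there is no imputation path). Passing tests therefore
demonstrate the engine's correctness and invariants, not predictive
validity on real populations.

A note on cluster recovery: the generator's clusters are latent *level*
shifts, and cosine similarity deliberately normalizes level away — its
neighbor purity plateaus well below 1 even for widely separated clusters.
The cluster-recovery demonstration therefore uses the inverse-Euclidean
metric, which is exactly the level-sensitive option the config exposes;
with ±1.5 sd shifts, n = 100, k = 5, over 90% of neighbor sets are
cluster-pure across seeds. Cosine remains the default for profile-shape
similarity between real portraits.

## Fixtures and provenance

The family rule matrix fixture (`family_v1`, 40 rules) is a full
transcription of the published family caregiving table. The individual
fixture (`individual_demo`, 140 rules) transcribes the three published
illustrative indicators (eating, personal grooming, bathing) and completes
the remaining 25 indicators with template items; the CSV marks every row
`transcribed` or `synthetic`, and tests asserting published content use
only transcribed cells. The five worked-example portrait vectors are
shipped verbatim and re-validated by the test suite. Service categories
use a controlled ten-item vocabulary (daily living assistance, nursing,
rehabilitation, safety/home modification, nutrition, psychological
support, social participation, financial/welfare linkage, caregiver
training, monitoring), assigned by us when tagging fixture items.

## Numerical and degenerate-input choices

- Scores must be integers in 0..4; integral floats and digit strings are
  accepted (CSV round-trips), anything else is a validation error with row
  context. Out-of-range values are never clipped.
- similarity(0-vector, ·) = 0 under cosine, avoiding 0/0; self-similarity
  of any nonzero vector is exactly 1.
- An empty CF population is not an error: support is 0 everywhere and the
  output equals the rule-only ranking.
- Totality errors name the first missing cells; assessment errors name the
  failing row and column.
- Output files are written atomically (temp file + rename): a failing run
  leaves no partial artifact.

## Problem sizes

The test suite and the acceptance script use n = 1000 subjects for
generator calibration, n = 2000 for marginal/correlation checks, n = 100
for cluster recovery, a 20-subject population for the end-to-end worked
example, and 1000 random trials for each oracle-equivalence check; the
whole suite runs in a few seconds.

## Known limitations

- The individual rule fixture beyond its three transcribed indicators is
  synthetic; community deployments must author their full matrix (the CSV
  schema and totality validator support this directly).
- Rule levels are treated as replacement, not cumulative: a score of 2
  triggers only the level-2 items, not also those for levels 1 and 0.
- Collaborative filtering re-ranks rule-derived needs rather than observed
  utilization; with richer data the support term should be re-estimated.
- Demographics are contextual only — they enter neither validation nor
  similarity.
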