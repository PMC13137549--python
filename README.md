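# caremap

**Dual capability portraits for identifying community age-friendly service needs.**

Community elderly-care planners need to decide *which* services an older
adult needs and *how urgently*, but self-reported demand misses latent needs
and single-dimension assessments ignore the caregiving household. `caremap`
implements a decision-support engine built on two digital capability
portraits per subject:

- an **individual functional capability** vector
  `A_i = (a_i1, …, a_i28)` — 28 indicators covering basic ADL, continence
  and toileting, mobility, cognitive orientation and function,
  communication, behavioural/emotional status, consciousness and sensory
  function, instrumental and social function, and health status;
- a **family caregiving capability** vector `B_i = (b_i1, …, b_i8)` — 8
  indicators across economic capacity, caregiving capacity and emotional
  support capacity.

Every indicator is scored on the same five-point ordinal scale, 0 (no
capability, heaviest need) to 4 (full capability, lightest need). Stacking
the vectors of all N community members gives community matrices
`A (N×28)` and `B (N×8)` for distribution profiling and high-risk
screening.

Need identification is a two-stage hybrid:

1. **Rule-based mapping (deterministic).** Total mapping matrices assign
   service items with intervention intensity grades (1 lightest … 5
   heaviest, grade = 5 − score) to every (indicator, score level) pair:
   28×5 = 140 rules for the individual matrix, 8×5 = 40 for the family
   matrix. Each portrait coordinate triggers exactly one rule, producing
   the candidate need list.
2. **Collaborative-filtering re-ranking.** Candidates are *never* added or
   removed; they are re-prioritized by

   `total = 0.5·severity + 0.3·family_deficit + 0.2·support`

   where severity = (4 − trigger score)/4, family_deficit =
   (4 − mean family score)/4 for individually-triggered items (the
   household moderator: weaker family caregiving raises the priority of
   external services), and support is the similarity-weighted share of the
   k = 5 most similar subjects (cosine over the concatenated, 0–1 scaled
   36-vector) whose own rule-based needs contain the same service. Totals
   are stratified into high (≥ 2/3), medium (≥ 1/3) and low priority.

A latent-Gaussian threshold generator produces synthetic communities of
correlated ordinal portraits, so every stage is testable and demonstrable
without any real assessment data.

## Worked example

The package ships the published demonstration vectors; `examples/` contains
one narrative script per capability. The end-to-end run
(`python examples/03_recommend_worked_example.py`) takes the demonstration
subject A = (1,1,1,1,2,2,1,1,1,2,1,2,3,3,1,1,1,1,2,1,1,3,2,1,2,1,1,1),
B = (0,2,1,1,1,1,1,2) against a 20-subject synthetic community and prints:

```
subject zhang: 47 recommendations
weights (severity, family, support) = (0.5, 0.3, 0.2)

priority  total   sev   fam   sup  service
high      0.800  1.00  1.00  0.00  Emergency financial aid (intensity 5/5)
high      0.800  1.00  1.00  0.00  Government safety-net support (intensity 5/5)
high      0.800  1.00  1.00  0.00  Medical assistance (intensity 5/5)
high      0.800  1.00  1.00  0.00  Minimum living guarantee (intensity 5/5)
high      0.680  0.75  0.75  0.40  Comprehensive age-friendly renovation plans (intensity 4/5)
high      0.680  0.75  0.75  0.40  Fall risk management (intensity 4/5)
medium    0.640  0.75  0.75  0.20  Emotional support (intensity 4/5)
...
```

The four grade-5 items come from the family's financial-resources score of
0; their family_deficit is that trigger's own severity (1.0). Every
individually-triggered item carries family_deficit (4 − 1.125)/4 = 0.71875
because the family mean score is 1.125 — the weak caregiving household
uniformly raises the urgency of external services. Items with nonzero
support are also common among the subject's five nearest capability
neighbors.

The same pipeline is scriptable from the shell:

```bash
caremap simulate --n 200 --seed 7 --out pop.csv
caremap validate --assessments pop.csv
caremap recommend --assessments pop.csv --subject S0001 --out rec.json
caremap summary --assessments pop.csv --out summary.json
```

All commands are deterministic: repeated runs produce byte-identical files.

## Layout

- `src/caremap/registry.py` — indicator registries (28 individual, 8 family)
- `src/caremap/portraits.py` — validated portrait vectors
- `src/caremap/community.py` — community matrices, profiles, high-risk flags
- `src/caremap/rules.py` — total mapping matrices, stage-1 rule mapping
- `src/caremap/recommend.py` — similarity, neighbor support, hybrid ranking
- `src/caremap/synth.py` — synthetic communities and worked-example fixtures
- `src/caremap/io.py`, `src/caremap/cli.py` — CSV/JSON/YAML I/O and the CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
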