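"""Stage 1: deterministic rule-based mapping of capability states to needs.

Loads the family caregiving rule matrix (8 indicators x 5 score levels = 40
total rules), looks up a few cells, and maps the worked-example family
portrait B = (0,2,1,1,1,1,1,2) into its candidate service needs.
"""
from caremap import (
    example_portraits,
    load_mapping_matrix,
    load_registry,
    lookup,
    map_portrait,
)

fam_reg = load_registry("family_v1")
fam_matrix = load_mapping_matrix("family_v1", fam_reg)
print(f"family matrix: {len(fam_matrix)} rules (totality: every indicator x level)")

for indicator, score in [("daily_caregiving_time", 0), ("caregiving_skills", 4)]:
    items = lookup(fam_matrix, indicator, score)
    print(f"  {indicator} @ score {score} -> {[i.label for i in items]}")

zhang_family = example_portraits()["zhang_family"]
candidates = map_portrait(zhang_family, fam_matrix)
print(f"\nCandidate needs for family portrait {zhang_family.scores}:")
for c in candidates:
    print(
        f"  [{c.trigger_indicator}={c.trigger_score}] {c.item.label} "
        f"(category: {c.item.category}, intensity {c.item.intensity_grade}/5)"
    )
print(
    "\nIntensity grade 5 - score: a score of 0 (no capability) triggers the"
    " heaviest, grade-5 interventions."
)
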