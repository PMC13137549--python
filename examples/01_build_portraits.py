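"""Build capability portraits and a community-level profile.

Validates the built-in worked-example score vectors against the indicator
registries, stacks them into a community matrix, and prints the per-indicator
distribution plus the subjects flagged as potentially high-risk.
"""
from caremap import (
    HighRiskPolicy,
    assemble_community_matrix,
    community_profile,
    example_portraits,
    flag_high_risk,
    load_registry,
    validate_portrait,
)

ind_reg = load_registry("individual_v1")
examples = example_portraits()

# re-validate the stored vectors: length 28, every score an integer 0..4
a1 = validate_portrait(ind_reg, "subject_001", examples["A_1"].scores)
a100 = validate_portrait(ind_reg, "subject_100", examples["A_100"].scores)
print(f"{a1.subject_id}: {a1.scores}")
print(f"{a100.subject_id}: {a100.scores}")

matrix = assemble_community_matrix([a1, a100])
profile = community_profile(matrix, ind_reg)
print("\nPer-indicator distribution (first 5 of 28 indicators, N=2):")
print(profile.head(5).to_string())

flagged = flag_high_risk(matrix, HighRiskPolicy(min_indicators=3, max_score=1))
print(f"\nHigh-risk (>=3 indicators scored <=1): {flagged}")
print("Low scores mean low capability, so both subjects need attention.")
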