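{
  "kind": "family",
  "indicators": [
    {
      "id": "financial_resources",
      "name": "Financial resources",
      "domain": "Economic capacity"
    },
    {
      "id": "medical_expenditure_burden",
      "name": "Medical expenditure burden",
      "domain": "Economic capacity"
    },
    {
      "id": "housing_conditions",
      "name": "Housing conditions",
      "domain": "Economic capacity"
    },
    {
      "id": "daily_caregiving_time",
      "name": "Daily caregiving time",
      "domain": "Caregiving capacity"
    },
    {
      "id": "caregiving_skills",
      "name": "Caregiving skills",
      "domain": "Caregiving capacity"
    },
    {
      "id": "communication_interaction",
      "name": "Communication and interaction",
      "domain": "Emotional support capacity"
    },
    {
      "id": "participation_in_decision_making",
      "name": "Participation in decision-making",
      "domain": "Emotional support capacity"
    },
    {
      "id": "family_conflict_level",
      "name": "Family conflict level",
      "domain": "Emotional support capacity"
    }
  ]
}
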