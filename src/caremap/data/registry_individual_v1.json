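{
  "kind": "individual",
  "indicators": [
    {
      "id": "eating",
      "name": "Eating",
      "domain": "Basic ADL"
    },
    {
      "id": "personal_grooming",
      "name": "Personal grooming",
      "domain": "Basic ADL"
    },
    {
      "id": "bathing",
      "name": "Bathing",
      "domain": "Basic ADL"
    },
    {
      "id": "dressing_upper_body",
      "name": "Dressing (upper body)",
      "domain": "Basic ADL"
    },
    {
      "id": "dressing_lower_body",
      "name": "Dressing (lower body & footwear)",
      "domain": "Basic ADL"
    },
    {
      "id": "urinary_continence",
      "name": "Urinary continence",
      "domain": "Continence & toileting"
    },
    {
      "id": "bowel_continence",
      "name": "Bowel continence",
      "domain": "Continence & toileting"
    },
    {
      "id": "toileting",
      "name": "Toileting",
      "domain": "Continence & toileting"
    },
    {
      "id": "bed_mobility",
      "name": "Bed mobility",
      "domain": "Mobility"
    },
    {
      "id": "bed_chair_transfer",
      "name": "Bed-chair transfer",
      "domain": "Mobility"
    },
    {
      "id": "walking_level_ground",
      "name": "Walking on level ground",
      "domain": "Mobility"
    },
    {
      "id": "stair_climbing",
      "name": "Stair climbing",
      "domain": "Mobility"
    },
    {
      "id": "time_orientation",
      "name": "Time orientation",
      "domain": "Cognitive orientation"
    },
    {
      "id": "spatial_orientation",
      "name": "Spatial orientation",
      "domain": "Cognitive orientation"
    },
    {
      "id": "person_orientation",
      "name": "Person orientation",
      "domain": "Cognitive orientation"
    },
    {
      "id": "memory",
      "name": "Memory",
      "domain": "Cognitive function"
    },
    {
      "id": "comprehension",
      "name": "Comprehension",
      "domain": "Communication"
    },
    {
      "id": "expression",
      "name": "Expression",
      "domain": "Communication"
    },
    {
      "id": "aggressive_behavior",
      "name": "Aggressive behavior",
      "domain": "Behavioral & emotional status"
    },
    {
      "id": "depressive_symptoms",
      "name": "Depressive symptoms",
      "domain": "Behavioral & emotional status"
    },
    {
      "id": "level_of_consciousness",
      "name": "Level of consciousness",
      "domain": "Consciousness & sensory function"
    },
    {
      "id": "vision",
      "name": "Vision",
      "domain": "Consciousness & sensory function"
    },
    {
      "id": "hearing",
      "name": "Hearing",
      "domain": "Consciousness & sensory function"
    },
    {
      "id": "managing_daily_affairs",
      "name": "Managing daily affairs",
      "domain": "Instrumental & social function"
    },
    {
      "id": "using_transportation",
      "name": "Using transportation",
      "domain": "Instrumental & social function"
    },
    {
      "id": "social_interaction",
      "name": "Social interaction",
      "domain": "Instrumental & social function"
    },
    {
      "id": "digital_literacy",
      "name": "Digital literacy",
      "domain": "Instrumental & social function"
    },
    {
      "id": "chronic_disease_status",
      "name": "Chronic disease status",
      "domain": "Health status"
    }
  ]
}
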