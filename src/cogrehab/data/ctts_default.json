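{
  "description": "Illustrative training-task repository: one model per task family (cancellation, action-sequencing, categorization, calculation, driving). Parameter bounds are the hard per-kind limits; coverage ranges and training weights are engine defaults, not clinically validated values.",
  "tasks": [
    {
      "id": "rehab_search",
      "kind": "search",
      "contexts": ["kitchen", "supermarket", "warehouse"],
      "coverage": {"attention": [20, 80], "memory": [30, 80]},
      "training_weights": {"attention": 0.6, "memory": 0.4},
      "parameters": {"targets": [1, 12], "elements_per_section": [4, 20], "sections": [1, 8]},
      "nominal_minutes": 11
    },
    {
      "id": "rehab_organize",
      "kind": "organize",
      "contexts": ["kitchen"],
      "coverage": {"executive": [20, 85], "memory": [25, 75]},
      "training_weights": {"executive": 0.7, "memory": 0.3},
      "parameters": {"steps": [2, 12]},
      "nominal_minutes": 11
    },
    {
      "id": "rehab_categorize",
      "kind": "categorize",
      "contexts": ["kitchen", "supermarket"],
      "coverage": {"executive": [15, 80], "language": [20, 80]},
      "training_weights": {"executive": 0.5, "language": 0.5},
      "parameters": {"items": [2, 60], "containers": [2, 4]},
      "nominal_minutes": 11
    },
    {
      "id": "rehab_pay",
      "kind": "pay",
      "contexts": ["supermarket", "finances"],
      "coverage": {"executive": [25, 90], "attention": [25, 80]},
      "training_weights": {"executive": 0.6, "attention": 0.4},
      "parameters": {"amounts": [1, 10], "coin_types": [2, 8]},
      "nominal_minutes": 11
    },
    {
      "id": "rehab_drive",
      "kind": "drive",
      "contexts": ["transportation"],
      "coverage": {"attention": [30, 90]},
      "training_weights": {"attention": 1.0},
      "parameters": {"obstacles": [1, 20], "speed": [1, 10]},
      "nominal_minutes": 11
    }
  ]
}
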