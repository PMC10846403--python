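{
  "description": "Default NPA instrument registry. Ranges for total scores follow the instruments' published maxima; MoCA item ranges are the standard item maxima. Reverse-scored instruments (depression scales, the IAFAI incapacity index) carry higher_is_better=false.",
  "instruments": [
    {
      "id": "MoCA",
      "subscores": [
        {"id": "total", "min": 0, "max": 30},
        {"id": "temporal_spatial_orientation", "min": 0, "max": 6},
        {"id": "delayed_recall", "min": 0, "max": 5},
        {"id": "digit_reverse", "min": 0, "max": 1},
        {"id": "digit_direct", "min": 0, "max": 1},
        {"id": "calculus", "min": 0, "max": 3},
        {"id": "target_detection", "min": 0, "max": 1},
        {"id": "phonemic_verbal_fluency", "min": 0, "max": 1},
        {"id": "naming_repetition", "min": 0, "max": 5}
      ]
    },
    {
      "id": "CDR",
      "subscores": [
        {"id": "cognitive_cluster", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "orientation", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "immediate_memory", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "memory_delayed_recall", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "personal_care", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "home_hobbies", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "community_affairs", "min": 0, "max": 3, "higher_is_better": false},
        {"id": "judgment_problem_solving", "min": 0, "max": 3, "higher_is_better": false}
      ]
    },
    {
      "id": "FCSRT",
      "subscores": [
        {"id": "immediate_memory", "min": 0, "max": 48},
        {"id": "delayed_recall", "min": 0, "max": 16}
      ]
    },
    {
      "id": "ROCFT",
      "subscores": [
        {"id": "copy", "min": 0, "max": 36},
        {"id": "recall_3min", "min": 0, "max": 36}
      ]
    },
    {
      "id": "WMSIII",
      "subscores": [
        {"id": "visual_reproduction_immediate", "min": 0, "max": 104},
        {"id": "visual_reproduction_delayed", "min": 0, "max": 104},
        {"id": "visual_reproduction_recognition", "min": 0, "max": 48},
        {"id": "visual_reproduction_total", "min": 0, "max": 104}
      ]
    },
    {
      "id": "WAISIII",
      "subscores": [
        {"id": "digit_symbol_coding", "min": 0, "max": 133},
        {"id": "symbol_search", "min": 0, "max": 60},
        {"id": "vocabulary", "min": 0, "max": 66}
      ]
    },
    {
      "id": "VerbalFluency",
      "subscores": [
        {"id": "phonemic", "min": 0, "max": 57},
        {"id": "semantic", "min": 0, "max": 27},
        {"id": "phonemic_semantic", "min": 0, "max": 84}
      ]
    },
    {
      "id": "ToulousePieron",
      "subscores": [
        {"id": "total", "min": 0, "max": 37.5}
      ]
    },
    {
      "id": "IAFAI",
      "subscores": [
        {"id": "basic_adl", "min": 0, "max": 100, "higher_is_better": false},
        {"id": "instrumental_familiar", "min": 0, "max": 100, "higher_is_better": false},
        {"id": "instrumental_advanced", "min": 0, "max": 100, "higher_is_better": false}
      ]
    },
    {
      "id": "PRECiS",
      "subscores": [
        {"id": "total", "min": 27, "max": 135, "higher_is_better": false}
      ]
    },
    {
      "id": "GDS30",
      "subscores": [
        {"id": "total", "min": 0, "max": 30, "higher_is_better": false}
      ]
    },
    {
      "id": "BDIII",
      "subscores": [
        {"id": "total", "min": 0, "max": 63, "higher_is_better": false}
      ]
    }
  ]
}
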