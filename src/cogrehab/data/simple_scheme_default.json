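{
  "description": "Simplified screening-battery profiling scheme: five macro-domains on a 0-10 scale, each the mean of min-max-normalized subdomain scores.",
  "domains": {
    "general_cognition": {
      "total": [
        {"instrument": "MoCA", "subscore": "total", "min": 0, "max": 30}
      ]
    },
    "memory": {
      "immediate_verbal": [
        {"instrument": "FCSRT", "subscore": "immediate_memory", "min": 0, "max": 48}
      ],
      "immediate_visual": [
        {"instrument": "ROCFT", "subscore": "recall_3min", "min": 0, "max": 36}
      ],
      "delayed_verbal": [
        {"instrument": "FCSRT", "subscore": "delayed_recall", "min": 0, "max": 16}
      ]
    },
    "executive_functions": {
      "working_memory": [
        {"instrument": "WAISIII", "subscore": "digit_symbol_coding", "min": 0, "max": 133}
      ],
      "processing_speed": [
        {"instrument": "WAISIII", "subscore": "symbol_search", "min": 0, "max": 60},
        {"instrument": "WAISIII", "subscore": "digit_symbol_coding", "min": 0, "max": 133}
      ],
      "verbal_initiative": [
        {"instrument": "VerbalFluency", "subscore": "phonemic", "min": 0, "max": 57},
        {"instrument": "VerbalFluency", "subscore": "semantic", "min": 0, "max": 27}
      ],
      "inhibition": [
        {"instrument": "VerbalFluency", "subscore": "phonemic", "min": 0, "max": 57},
        {"instrument": "VerbalFluency", "subscore": "semantic", "min": 0, "max": 27}
      ],
      "visuoconstructive": [
        {"instrument": "ROCFT", "subscore": "copy", "min": 0, "max": 36}
      ]
    },
    "language": {
      "expression": [
        {"instrument": "VerbalFluency", "subscore": "phonemic", "min": 0, "max": 57},
        {"instrument": "VerbalFluency", "subscore": "semantic", "min": 0, "max": 27}
      ],
      "comprehension": [
        {"instrument": "WAISIII", "subscore": "vocabulary", "min": 0, "max": 66}
      ]
    },
    "attention": {
      "divided": [
        {"instrument": "WAISIII", "subscore": "symbol_search", "min": 0, "max": 60}
      ],
      "sustained": [
        {"instrument": "ToulousePieron", "subscore": "total", "min": 0, "max": 37.5}
      ]
    }
  }
}
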