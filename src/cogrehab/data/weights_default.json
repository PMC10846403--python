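{
  "description": "Default expert-elicited weight table mapping NPA instrument sub-scores to cognitive domains/subdomains. Weights are raw percentages; renormalization to fractions per domain happens at load.",
  "entries": [
    {"domain": "general_cognition", "instrument": "MoCA", "subscore": "total", "weight_pct": 100},
    {"domain": "general_cognition", "instrument": "CDR", "subscore": "cognitive_cluster", "weight_pct": 100},

    {"domain": "orientation", "instrument": "CDR", "subscore": "orientation", "weight_pct": 33.33},
    {"domain": "orientation", "instrument": "MoCA", "subscore": "temporal_spatial_orientation", "weight_pct": 12.5},

    {"domain": "memory.immediate_verbal", "instrument": "FCSRT", "subscore": "immediate_memory", "weight_pct": 100},
    {"domain": "memory.immediate_verbal", "instrument": "CDR", "subscore": "immediate_memory", "weight_pct": 33.33},
    {"domain": "memory.immediate_verbal", "instrument": "MoCA", "subscore": "delayed_recall", "weight_pct": 12.5},

    {"domain": "memory.immediate_visual", "instrument": "ROCFT", "subscore": "recall_3min", "weight_pct": 100},
    {"domain": "memory.immediate_visual", "instrument": "WMSIII", "subscore": "visual_reproduction_immediate", "weight_pct": 100},

    {"domain": "memory.delayed_verbal", "instrument": "FCSRT", "subscore": "delayed_recall", "weight_pct": 100},
    {"domain": "memory.delayed_verbal", "instrument": "CDR", "subscore": "memory_delayed_recall", "weight_pct": 33.33},

    {"domain": "memory.delayed_visual", "instrument": "WMSIII", "subscore": "visual_reproduction_delayed", "weight_pct": 100},
    {"domain": "memory.delayed_visual", "instrument": "WMSIII", "subscore": "visual_reproduction_recognition", "weight_pct": 100},

    {"domain": "executive.working_memory", "instrument": "WAISIII", "subscore": "digit_symbol_coding", "weight_pct": 50},
    {"domain": "executive.working_memory", "instrument": "MoCA", "subscore": "digit_reverse", "weight_pct": 12.5},
    {"domain": "executive.working_memory", "instrument": "MoCA", "subscore": "calculus", "weight_pct": 6.25},
    {"domain": "executive.working_memory", "instrument": "MoCA", "subscore": "target_detection", "weight_pct": 4.2},

    {"domain": "executive.processing_speed", "instrument": "WAISIII", "subscore": "symbol_search", "weight_pct": 50},
    {"domain": "executive.processing_speed", "instrument": "WAISIII", "subscore": "digit_symbol_coding", "weight_pct": 50},
    {"domain": "executive.processing_speed", "instrument": "VerbalFluency", "subscore": "phonemic_semantic", "weight_pct": 33.33},
    {"domain": "executive.processing_speed", "instrument": "MoCA", "subscore": "phonemic_verbal_fluency", "weight_pct": 4.2},

    {"domain": "executive.verbal_fluency", "instrument": "VerbalFluency", "subscore": "phonemic_semantic", "weight_pct": 33.33},
    {"domain": "executive.verbal_fluency", "instrument": "MoCA", "subscore": "phonemic_verbal_fluency", "weight_pct": 4.2},

    {"domain": "executive.inhibition", "instrument": "VerbalFluency", "subscore": "phonemic_semantic", "weight_pct": 33.33},
    {"domain": "executive.inhibition", "instrument": "MoCA", "subscore": "target_detection", "weight_pct": 4.2},
    {"domain": "executive.inhibition", "instrument": "MoCA", "subscore": "phonemic_verbal_fluency", "weight_pct": 4.2},

    {"domain": "executive.visuoconstructive", "instrument": "ROCFT", "subscore": "copy", "weight_pct": 100},
    {"domain": "executive.visuoconstructive", "instrument": "WMSIII", "subscore": "visual_reproduction_total", "weight_pct": 100},

    {"domain": "language.comprehension", "instrument": "WAISIII", "subscore": "vocabulary", "weight_pct": 50},

    {"domain": "language.expression", "instrument": "MoCA", "subscore": "naming_repetition", "weight_pct": 12.5},

    {"domain": "attention.divided", "instrument": "WAISIII", "subscore": "symbol_search", "weight_pct": 50},

    {"domain": "attention.sustained", "instrument": "ToulousePieron", "subscore": "total", "weight_pct": 100},
    {"domain": "attention.sustained", "instrument": "MoCA", "subscore": "target_detection", "weight_pct": 4.2},
    {"domain": "attention.sustained", "instrument": "MoCA", "subscore": "calculus", "weight_pct": 6.25},
    {"domain": "attention.sustained", "instrument": "MoCA", "subscore": "digit_direct", "weight_pct": 12.5},

    {"domain": "premorbid_intelligence", "instrument": "WAISIII", "subscore": "vocabulary", "weight_pct": 50},

    {"domain": "functionality.basic_adl", "instrument": "IAFAI", "subscore": "basic_adl", "weight_pct": 100},
    {"domain": "functionality.basic_adl", "instrument": "CDR", "subscore": "personal_care", "weight_pct": 100},

    {"domain": "functionality.instrumental_familiar", "instrument": "IAFAI", "subscore": "instrumental_familiar", "weight_pct": 100},
    {"domain": "functionality.instrumental_familiar", "instrument": "CDR", "subscore": "home_hobbies", "weight_pct": 100},

    {"domain": "functionality.instrumental_advanced", "instrument": "IAFAI", "subscore": "instrumental_advanced", "weight_pct": 100},
    {"domain": "functionality.instrumental_advanced", "instrument": "CDR", "subscore": "community_affairs", "weight_pct": 100},
    {"domain": "functionality.instrumental_advanced", "instrument": "CDR", "subscore": "judgment_problem_solving", "weight_pct": 100},

    {"domain": "functionality.perceived_impact", "instrument": "PRECiS", "subscore": "total", "weight_pct": 100},

    {"domain": "depressive_symptomatology", "instrument": "GDS30", "subscore": "total", "weight_pct": 100}
  ]
}
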