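{
  "tokens": {
    "para": {"category": "partitioning_a"},
    "parb": {"category": "partitioning_b"},
    "virb4": {"category": "t4ss_atpase"},
    "trbe": {"category": "t4ss_atpase"},
    "vird4": {"category": "t4ss_coupling"},
    "trag": {"category": "t4ss_coupling"},
    "virb1": {"category": "t4ss_other"},
    "virb2": {"category": "t4ss_other"},
    "virb3": {"category": "t4ss_other"},
    "virb5": {"category": "t4ss_other"},
    "virb6": {"category": "t4ss_other"},
    "virb8": {"category": "t4ss_other"},
    "virb9": {"category": "t4ss_other"},
    "virb10": {"category": "t4ss_other"},
    "virb11": {"category": "t4ss_other"},
    "mobf": {"category": "relaxase", "family": "MOBF"},
    "mobh": {"category": "relaxase", "family": "MOBH"},
    "mobp": {"category": "relaxase", "family": "MOBP"},
    "mobq": {"category": "relaxase", "family": "MOBQ"},
    "mobc": {"category": "relaxase", "family": "MOBC"},
    "mobv": {"category": "relaxase", "family": "MOBV"},
    "trai": {"category": "relaxase", "family": "MOBP"},
    "moba": {"category": "relaxase", "family": "MOBQ"},
    "repa": {"category": "replicase"},
    "repb": {"category": "replicase"},
    "repc": {"category": "replicase"},
    "repabc": {"category": "replicase"},
    "dnaa": {"category": "replicase"},
    "repl": {"category": "replicase"},
    "repq": {"category": "replicase"},
    "repy": {"category": "replicase"},
    "repw": {"category": "replicase"}
  },
  "mob_priority": ["MOBF", "MOBH", "MOBP", "MOBQ", "MOBC", "MOBV"]
}
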