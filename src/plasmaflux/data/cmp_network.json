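{
  "name": "central-metabolic-pathway (CMP) network, 10 reactions",
  "reference_reaction": "r1",
  "metabolites": [
    {"id": "glc", "name": "glucose", "role": "boundary_measured"},
    {"id": "g6p", "name": "glucose-6-phosphate", "role": "internal_pss"},
    {"id": "f6p", "name": "fructose-6-phosphate", "role": "internal_pss"},
    {"id": "gap", "name": "glyceraldehyde-3-phosphate", "role": "internal_pss"},
    {"id": "pep", "name": "phosphoenolpyruvate", "role": "internal_pss"},
    {"id": "pyr", "name": "pyruvate", "role": "internal_pss"},
    {"id": "accoa", "name": "acetyl-CoA", "role": "internal_pss"},
    {"id": "lac", "name": "lactate", "role": "boundary_measured"},
    {"id": "bhb", "name": "beta-hydroxybutyrate", "role": "boundary_measured"},
    {"id": "nadh", "name": "NADH", "role": "boundary_measured"},
    {"id": "r5p", "name": "ribose-5-phosphate", "role": "sink_unmeasured"},
    {"id": "tca_out", "name": "TCA-cycle end products", "role": "sink_unmeasured"}
  ],
  "reactions": [
    {"id": "r1", "substrates": [["glc", 1]], "products": [["g6p", 1]],
     "pathway": "glycolysis", "reversible": false},
    {"id": "r2", "substrates": [["g6p", 1]], "products": [["f6p", 1]],
     "pathway": "glycolysis", "reversible": false},
    {"id": "r3", "substrates": [["g6p", 1]], "products": [["r5p", 1]],
     "pathway": "pentose_phosphate", "reversible": false},
    {"id": "r4", "substrates": [["f6p", 1]], "products": [["gap", 2]],
     "pathway": "glycolysis", "reversible": false},
    {"id": "r5", "substrates": [["gap", 1]], "products": [["pep", 1], ["nadh", 1]],
     "pathway": "glycolysis", "reversible": false},
    {"id": "r6", "substrates": [["pep", 1]], "products": [["pyr", 1]],
     "pathway": "glycolysis", "reversible": false},
    {"id": "r7", "substrates": [["pyr", 1], ["nadh", 1]], "products": [["lac", 1]],
     "pathway": "fermentation", "reversible": false},
    {"id": "r8", "substrates": [["pyr", 1]], "products": [["accoa", 1]],
     "pathway": "TCA", "reversible": false},
    {"id": "r9", "substrates": [["accoa", 1]], "products": [["tca_out", 1]],
     "pathway": "TCA", "reversible": false},
    {"id": "r10", "substrates": [["accoa", 1], ["nadh", 1]], "products": [["bhb", 1]],
     "pathway": "ketogenesis", "reversible": false}
  ]
}
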