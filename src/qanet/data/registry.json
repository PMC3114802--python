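{
  "comment": "Model registry for the qa-cluster mass-action genetic network and its regulatory variants. Species and reaction blocks are expanded per gene by the builder; everything listed here is data and can be edited without code changes. Expected counts are enforced at build time.",
  "time_unit": "hr",
  "core": {
    "genes": ["qa-1F", "qa-1S", "qa-2", "qa-3", "qa-4", "qa-x", "qa-y"],
    "proteins": {
      "qa-1F": "QA-1F",
      "qa-1S": "QA-1S",
      "qa-2": "QA-2",
      "qa-3": "QA-3",
      "qa-4": "QA-4",
      "qa-x": "QA-X",
      "qa-y": "QA-Y"
    },
    "activator": "QA-1F",
    "extra_species": [
      {"name": "QA_ext", "role": "metabolite"},
      {"name": "QA_in", "role": "metabolite"},
      {"name": "DHQ", "role": "metabolite"},
      {"name": "DHS", "role": "metabolite"},
      {"name": "PCA", "role": "metabolite"},
      {"name": "SA", "role": "metabolite"},
      {"name": "sucrose", "role": "metabolite"},
      {"name": "cplx_1F_1S", "role": "complex"},
      {"name": "cplx_1F_suc", "role": "complex"},
      {"name": "cplx_1S_QA", "role": "complex"}
    ],
    "extra_reactions": [
      {"label": "T_y", "reactants": ["QA_ext"], "products": ["QA_in"], "catalysts": ["QA-Y"]},
      {"label": "P_3", "reactants": ["QA_in"], "products": ["DHQ"], "catalysts": ["QA-3"]},
      {"label": "P_2", "reactants": ["DHQ"], "products": ["DHS"], "catalysts": ["QA-2"]},
      {"label": "P_4", "reactants": ["DHS"], "products": ["PCA"], "catalysts": ["QA-4"]},
      {"label": "P_x", "reactants": ["DHS"], "products": ["SA"], "catalysts": ["QA-X"]},
      {"label": "I1", "reactants": ["QA-1F", "QA-1S"], "products": ["cplx_1F_1S"], "catalysts": []},
      {"label": "I1r", "reactants": ["cplx_1F_1S"], "products": ["QA-1F", "QA-1S"], "catalysts": []},
      {"label": "I3", "reactants": ["QA-1F", "sucrose"], "products": ["cplx_1F_suc"], "catalysts": []},
      {"label": "I3r", "reactants": ["cplx_1F_suc"], "products": ["QA-1F", "sucrose"], "catalysts": []},
      {"label": "I2", "reactants": ["QA-1S", "QA_in"], "products": ["cplx_1S_QA"], "catalysts": []},
      {"label": "I2r", "reactants": ["cplx_1S_QA"], "products": ["QA-1S", "QA_in"], "catalysts": []},
      {"label": "D_suc", "reactants": ["sucrose"], "products": [], "catalysts": []}
    ]
  },
  "qag_genes": [
    "ncu01517", "ncu01830", "ncu03643", "ncu05499", "ncu02704", "ncu08315",
    "ncu06675", "ncu05134", "ncu09491", "ncu05627", "ncu05897", "ncu09525",
    "ncu02364", "ncu06881", "ncu00801", "ncu04072", "ncu00591", "ncu00992",
    "ncu09133", "ncu05755", "ncu07888", "ncu04914", "ncu06524", "ncu05291",
    "ncu00121", "ncu05775", "ncu01231", "ncu08771", "ncu10021", "ncu03415",
    "ncu09429", "ncu09873", "ncu06815", "ncu04872", "ncu05315", "ncu08541"
  ],
  "regulator_block": {
    "gene": "ncu03643",
    "protein": "P_ncu03643",
    "toggle_targets": ["ncu03643", "ncu05897"]
  },
  "variants": {
    "all1F-2E": {"qag_activator": "QA-1F", "ncu3643_activator": "QA-1F", "overrides": {}},
    "all3643-2E": {"qag_activator": "P_ncu03643", "ncu3643_activator": "QA-1F", "overrides": {}},
    "all3643self-2E": {"qag_activator": "P_ncu03643", "ncu3643_activator": "P_ncu03643", "overrides": {}},
    "2genes-2E": {"qag_activator": "QA-1F", "ncu3643_activator": "QA-1F",
                  "overrides": {"ncu05897": "P_ncu03643", "ncu01517": "P_ncu03643"}},
    "1F-3643-2E A": {"qag_activator": "add_both", "ncu3643_activator": "QA-1F", "overrides": {}},
    "1F-3643-2E B": {"qag_activator": "add_both", "ncu3643_activator": "P_ncu03643", "overrides": {}},
    "1F-3643-2E C": {"qag_activator": "add_both", "ncu3643_activator": "dual", "overrides": {}}
  },
  "expected_counts": {
    "core": {"species": 38, "reactions": 54},
    "all1F-2E": {"species": 147, "reactions": 204},
    "all3643-2E": {"species": 147, "reactions": 204},
    "all3643self-2E": {"species": 147, "reactions": 204},
    "2genes-2E": {"species": 147, "reactions": 204},
    "1F-3643-2E A": {"species": 147, "reactions": 239},
    "1F-3643-2E B": {"species": 147, "reactions": 239},
    "1F-3643-2E C": {"species": 147, "reactions": 239}
  }
}
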