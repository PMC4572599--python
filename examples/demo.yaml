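# Demo pipeline: physics chain plus synthetic assay analysis.
seed: 7
output_dir: out
stages:
  spectrum:
    source: 160kV
  attenuate:
    source: 160kV
    pt_mg_per_ml: 7.0
    tumor: [10.0, 11.0]
  defsim:
    source: 160kV
    pt_mg_per_ml: 7.0
    tumor: [10.0, 12.0]
    n_photons: 100000
  simulate_assay:
    concentrations: [0.0, 2.0]
    sources: {"160kV": 1.6, "6MV": 1.0}
    replicates: 3
  survival:
    ratio_by: source
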