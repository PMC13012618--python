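# End-to-end demo on a planted-path synthetic ensemble: generate, build the
# GC network, trace pathways, detect communities, report recovery.
seed: 7
output_dir: allonet_demo
stages: [synth_ensemble, network, paths, communities, report]
ensemble:
  kind: planted_path
  n_residues: 30
  n_frames: 800
  source: 5
  sink: 25
  n_intermediates: 4
  rho: 0.8
network:
  cutoff_nm: 0.45
  persistence: 0.75
paths:
  n_suboptimal: 20
communities:
  seed: 0
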