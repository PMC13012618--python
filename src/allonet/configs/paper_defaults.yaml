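# Canonical analysis parameters for the Hsp70/J-domain study conditions.
# Network edges: heavy atoms within 0.45 nm for at least 75% of frames;
# differential contacts flagged above 40 percentage points; H-bond angle
# floor 150 deg; ligand-binding / interlobe roles at 50% persistence;
# communities below 1% of nodes discarded; 20 suboptimal paths; umbrella
# ladder of ten windows spanning 0.3-1.2 nm with a 1500 kJ/mol/nm^2 spring
# at 310 K; T199-close state < 0.4 nm, T199-far state > 0.65 nm.
seed: 0
output_dir: allonet_out
stages: [synth_ensemble, network, paths, communities, report]
network:
  cutoff_nm: 0.45
  persistence: 0.75
  k_neighbours: 7
paths:
  n_suboptimal: 20
communities:
  seed: 0
  min_fraction: 0.01
contacts:
  threshold_pp: 40.0
  classification_persistence: 0.5
umbrella:
  potential: harmonic
  params: {kappa: 100.0, xi0: 0.6}
  windows: [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2]
  spring_constant_kj_mol_nm2: 1500.0
  n_samples: 5000
  temperature_K: 310.0
wham:
  n_bins: 100
  tolerance_kt: 1.0e-8
  n_boot: 0
  states:
    close: [0.0, 0.4]
    far: [0.65, 10.0]
sensitivity:
  cutoffs_nm: [0.42, 0.45, 0.48]
  persistences: [0.65, 0.75, 0.85]
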