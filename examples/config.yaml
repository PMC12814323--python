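# Full-pipeline configuration, synthetic input at desk scale.
# Run: microswitch run-all --config examples/config.yaml --outdir out --seed 1
synthetic:
  n_ensembles: 2
  replicas_per_ensemble: 3
  n_frames: 5000
  n_residues: 10
  residue_names: [LEU, VAL, TRP, LEU, VAL, SER, ALA, GLY, ALA, ALA]
  n_microstates: 5
  coupled_residues: [[0, 1.0]]   # residue 0 fully coupled; others are controls

n_components: 10
cluster_dims: 5
k_range: [4, 5, 6]
minor_threshold: 0.05
contact_cutoff: 4.0
dwell_dominance: 0.9
oblique_angle: 60.0
conditioning_residue: 0
ecc_label: ens0

kinetics:
  k_on_star: 1.0
  k_off: 0.1
  exchange_rate: 100.0
  ligand_concentration: 1.0
  scenario: on_only
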