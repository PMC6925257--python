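# Bundled study presets: the plasmid species/cost model and the three
# simulation protocols at their published scale, each with a reduced "desk"
# variant (scaled_down: true) for quick runs and tests.
fitness:
  copy_number: 18
  costs:
    ancestral: 0.0306
    satellite: 0.0
    deletion: 0.0050
protocols:
  equilibrium:
    dilution_factor: 2.0
    n_generations: 500
    n_cells: 10000
    n_replicates: 10
    selection_on: true
  delay:
    dilution_factor: 1.072
    n_generations: 50
    n_cells: 20000
    n_replicates: 200
  establishment:
    dilution_factor: 2000.0
    generations_per_cycle: 11
    establishment_multiple: 20.0
    n_trials: 1000000
desk:
  equilibrium:
    n_cells: 2000
    n_generations: 300
    n_replicates: 4
  delay:
    n_replicates: 50
    n_cells: 5000
  establishment:
    n_trials: 100000
repeat_params:
  min_length: 7
  max_indels: 1
  max_mismatches: 5
  min_identity: 0.75
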