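# Small optimization budget for quick demonstrations: a 10-member bank,
# three annealing iterations and light refinement.  Delete any key to fall
# back to the protocol default (bank 30/50, 50 iterations, 10 trials/seed).
csa:
  bank_size: 10
  n_seeds: 4
  n_iterations: 3
  trials_per_seed: 1
  refine_steps: 2
  refine_maxfev: 20
  refine_cycles: 1
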