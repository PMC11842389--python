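# Example training configuration for `safwre train --config`.
# CLI flags override any value set here.
optimizer:
  algorithm: csa        # csa | ga | pso | sa | ssa | tso
  population_size: 50
  iterations: 50
  runs: 1               # >1 reruns with seed, seed+1, ... and keeps the best
  seed: 42
  algo_params: {}       # algorithm constants, e.g. {c: 0.8} for csa
objective:
  n_folds: 5
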