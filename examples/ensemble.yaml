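# Monte Carlo ensemble at low founder density on the production geometry.
# The ensemble block's afs_only switch skips the PDE (geometry-only runs).
geometry:
  R: 72.0
  R0: 14.0
  target_element_area: 1.44   # coarsened ensemble mesh; 0.36 = full resolution
model:
  mode: isogenic              # or antagonistic, with r/d/c/k below
solver:
  end_time: 25.0
ensemble:
  N: 6
  n_reps: 100
  base_seed: 0
  ratio_rule: fixed_half
output:
  directory: runs/n6_isogenic
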