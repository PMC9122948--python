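# One realisation from the homogeneous high-density start.
geometry: {R: 72.0, R0: 14.0, target_element_area: 0.36}
model: {mode: isogenic}
solver: {end_time: 25.0}
initial_condition: {kind: homogeneous, level1: 0.5, level2: 0.5}
output: {directory: runs/homogeneous}
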