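# A small thermalized DPD fluid carrying a diffusing solute.
universe: {dims: [8, 8, 8], boundary: periodic, cutoff: 1.0, dt: 0.01, seed: 7}
types:
  - {name: f, mass: 1.0, species: [solute]}
dpd:
  - {types: [f, f], alpha: 15.0, gamma: 4.5, sigma: 3.0, rc: 1.0}
particles:
  - {type: f, count: 200}
flux:
  - {kind: fick, species: solute, types: [f, f], k: 0.5, cutoff: 1.0}
run: {steps: 1000, stride: 50}
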