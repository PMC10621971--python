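# Two Newtonian particles bound by a harmonic potential.
universe: {dims: [10, 10, 10], boundary: reflective, cutoff: 3.0, dt: 0.005, seed: 1}
types:
  - {name: osc, mass: 1.0}
potentials:
  spring: {kind: harmonic, k: 1.0, r0: 1.0, r_max: 3.0}
bindings:
  - {potential: spring, types: [osc, osc]}
particles:
  - {type: osc, position: [4.35, 5.0, 5.0]}
  - {type: osc, position: [5.65, 5.0, 5.0]}
run: {steps: 2000, stride: 20}
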