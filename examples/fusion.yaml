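# Two pre-assembled 500-cell spheroids fusing by Morse adhesion.
fixture: {name: fusion, params: {n_per_spheroid: 500, seed: 0}}
run: {steps: 5000, stride: 250}
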