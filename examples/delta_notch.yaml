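# Delta-Notch lateral inhibition on a 12x12 hexagonal monolayer.
fixture: {name: delta_notch, params: {nx: 12, ny: 12, seed: 0}}
run: {steps: 1600, stride: 40}
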