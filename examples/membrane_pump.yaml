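# Active pumping of a solute across a deformable membrane.
fixture: {name: membrane_pump, params: {seed: 0}}
run: {steps: 2000, stride: 50}
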