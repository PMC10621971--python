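# Two-dimensional colonic-crypt agent-based model (one replicate).
fixture: {name: crypt, params: {seed: 0}}
run: {steps: 20000, stride: 200}
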