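n_isolates: 6
max_meioses: 400
seed: 3
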