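{embed_dim: 31, embed_seed: 0, kind: spiral, n_points: 10000, noise_sd: 0.1, turns: 3.0}
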