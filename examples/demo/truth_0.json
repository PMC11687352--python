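{"arrestment": 1.0, "immigration": 1.0, "beta": 5.0, "landscape_seed": 1610069009, "track_seed": 1835504127}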