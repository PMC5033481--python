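atom,oxidized,reduced
S(t)_cys69,-0.632,-0.820
S(t)_cys90,-0.569,-0.677
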