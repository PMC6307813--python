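stage	male_edges	female_edges
normal	6	1421
possible_AD	0	1794
probable_AD	0	729
definite_AD	553	5806
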