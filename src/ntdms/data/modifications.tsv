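# name	mono_delta	avg_delta	site_rule
acetylation	42.01057	42.0367	N-terminus
phosphorylation	79.96633	79.9799	S/T/Y
met1-excision	-131.04049	-131.19606	N-terminus
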