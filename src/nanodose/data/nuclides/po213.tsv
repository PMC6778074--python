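# Po-213 (3.72 us), alpha decay to Pb-209.
halflife_s	3.72e-6
mode	Pb-209	1.0
alpha	8376	0.9999
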