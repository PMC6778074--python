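# Po-215 (1.781 ms), alpha decay to Pb-211.
halflife_s	0.001781
mode	Pb-211	1.0
alpha	7386.1	0.9999
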