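# Y-90 (64.05 h), near-pure beta- emitter to stable Zr-90.
halflife_s	230580
mode	Zr-90	1.0
beta-	2280.1	0.9988
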