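# Pb-207: stable chain terminator.
stable	true
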