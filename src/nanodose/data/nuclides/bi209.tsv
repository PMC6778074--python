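# Bi-209: effectively stable (2e19 yr alpha half-life ignored).
stable	true
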