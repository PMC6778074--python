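# Tl-209 (2.16 min), beta- decay to Pb-209.
halflife_s	129.6
mode	Pb-209	1.0
beta-	1825	0.986
gamma	117.21	0.843
gamma	465.14	0.969
gamma	1567.1	0.997
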