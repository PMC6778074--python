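# Pb-209 (3.234 h), pure beta- decay to Bi-209 (treated as stable).
halflife_s	11642.4
mode	Bi-209	1.0
beta-	644	1.0
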