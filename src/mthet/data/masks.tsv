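start	end
66	71
300	316
513	525
3106	3107
12418	12425
16181	16194
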