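term	coefficient
(Intercept)	111.83
cg02228185	-64.57
cg25809905	-42.57
cg17861230	75.15
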