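species	n2	n3
peach	1484	256
cacao	1111	172
grape	945	150
castor_bean	851	119
strawberry	606	57
papaya	474	34
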