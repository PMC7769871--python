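category,weight_kg
piglet,4
weaner,12
fattener,50
sow,220
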