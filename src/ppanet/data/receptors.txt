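TNFR1
TNFR2
IL1R1
IL1R2
TLR4
ST2L
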