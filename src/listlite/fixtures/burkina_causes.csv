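cause,fraction_percent
malaria,24
pneumonia,18
diarrhea,12
neonatal,22
other,24
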