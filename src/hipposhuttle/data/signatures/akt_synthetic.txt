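# SYNTHETIC placeholder signature gene list (one gene per line).
# Replace with the published AKT signature for real analyses.
AKT_g00
AKT_g01
AKT_g02
AKT_g03
AKT_g04
AKT_g05
AKT_g06
AKT_g07
AKT_g08
AKT_g09
AKT_g10
AKT_g11
AKT_g12
AKT_g13
AKT_g14
AKT_g15
AKT_g16
AKT_g17
AKT_g18
AKT_g19
AKT_g20
AKT_g21
AKT_g22
AKT_g23
AKT_g24
AKT_g25
AKT_g26
AKT_g27
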