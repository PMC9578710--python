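# SYNTHETIC placeholder signature gene list (one gene per line).
# Replace with the published YAP signature for real analyses.
YAP_g00
YAP_g01
YAP_g02
YAP_g03
YAP_g04
YAP_g05
YAP_g06
YAP_g07
YAP_g08
YAP_g09
YAP_g10
YAP_g11
YAP_g12
YAP_g13
YAP_g14
YAP_g15
YAP_g16
YAP_g17
YAP_g18
YAP_g19
YAP_g20
YAP_g21
YAP_g22
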