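# Default background reference m/z values for the image-correlation filter.
#
# matrix: DHB (2,5-dihydroxybenzoic acid) cluster/fragment ions commonly seen
#   in positive-mode MALDI: [M+H-H2O]+, [M+H]+, [M+Na]+, [M-H+2Na]+ and the
#   dehydrated dimer [2M+H-2H2O]+.
# tape: placeholder adhesive-tape (siloxane-like) ion series; adjust to the
#   adhesive actually used when analysing real data.
matrix:
  - 137.024
  - 155.034
  - 177.016
  - 199.006
  - 273.040
tape:
  - 207.033
  - 281.051
  - 355.069
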