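# Domain architecture of the mitochondrial leucyl-tRNA synthetase
# (LARS2 product), elements in N-to-C order.  Residue ranges are
# approximate (consistent with the variant-to-domain assignments in the
# modeling analysis); the element names and their order are exact.
name	start	end
HIGH motif	85	100
catalytic domain	101	285
editing domain	286	450
LS domain	570	650
KMSKS motif	651	662
anticodon domain	700	780
C-terminal domain	781	903
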