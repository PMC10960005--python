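# Default polyA-signal hexamer catalog, one per line, priority order.
# The two canonical signals lead; the remainder are the standard
# single-substitution variants observed in human 3' ends.
AATAAA
ATTAAA
TATAAA
AGTAAA
AAGAAA
AATATA
AATACA
CATAAA
GATAAA
AATGAA
TTTAAA
ACTAAA
AATAGA
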