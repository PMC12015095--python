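# Hormone response element motifs: name <TAB> IUPAC <TAB> class (ARE|ERE)
# The two canonical motifs are shipped; append further ARE variants below.
ARE_canonical	AGAACANNNTGTTCT	ARE
ERE_canonical	GGTCANNNTGACC	ERE
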