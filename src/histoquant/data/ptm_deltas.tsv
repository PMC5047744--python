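mod	formula	description
ac	C2H2O	lysine epsilon-amine acetylation
me1	CH2	lysine mono-methylation (propionylatable)
me2	C2H4	lysine di-methylation
me3	C3H6	lysine tri-methylation
propionyl	C3H4O	propionic-anhydride derivatization of free/mono-methyl lysines and peptide N-termini
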