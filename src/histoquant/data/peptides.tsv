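id	protein	family	start	sequence	mod_sites
H3_18-26	H3	H3_18-26	18	KQLATKAAR	18:K:un|ac;23:K:un|ac
H3_9-17	H3	H3_9-17	9	KSTGGKAPR	9:K:un|ac;14:K:un|ac
H3_73-83	H3	H3_73-83	73	EIAQDFKTDLR	79:K:un|me1|me2|me3
H3.3_27-40	H3.3	H3.3_27-40	27	KSAPSTGGVKKPHR	27:K:un|ac|me1|me2|me3;36:K:un|me1|me2|me3
H3_27-40	H3.1/H3.2	H3_27-40	27	KSAPATGGVKKPHR	27:K:un|ac|me1|me2|me3;36:K:un|me1|me2|me3
H4_4-17	H4	H4_4-17	4	GKGGKGLGKGGAKR	5:K:un|ac;8:K:un|ac;12:K:un|ac;16:K:un|ac
H2A_12-17_T	H2A type 1-B/E	H2A_12-17	12	AKAKTR
H2A_12-17_S	H2A type 2-A	H2A_12-17	12	AKAKSR
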