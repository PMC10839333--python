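# Synthetic stand-in for an in-house lipid standards database:
# 21 commercial molecules across 11 lipid classes, reconstituted in CDCl3
# at 10 mM (36.7 mM for the TG standard). Reference areas are not stored;
# they are computed at load time by simulating each representative
# standard solution. representative=1 marks the record used to quantify
# the matching class (classes without a quantified marker keep 0).
molecule	lipid_class	conc_mM	peak_id	representative
glyceryl trioleate	TG	36.7	TG_glycerol_4.2	1
glyceryl tripalmitate	TG	10.0	TG_glycerol_4.2	0
1-palmitoyl-2-oleoyl-PC	PC_LPC	10.0	choline_3.48	1
dipalmitoyl-PC	PC_LPC	10.0	choline_3.48	0
1-palmitoyl-LPC	LPC	10.0	choline_3.48	0
dioleoyl-PE	PE	10.0	PE_3.40	1
dipalmitoyl-PE	PE	10.0	PE_3.40	0
cholesterol	TC	10.0	TC_0.68	1
cholesteryl oleate	CE	10.0	TC_0.68	0
cholesteryl palmitate	CE	10.0	TC_0.68	0
myristic acid	FA	10.0	CH3_0.90	0
palmitic acid	FA	10.0	CH3_0.90	0
stearic acid	FA	10.0	CH3_0.90	0
oleic acid	FA	10.0	CH3_0.90	1
linoleic acid	FA	10.0	CH3_0.90	0
alpha-linolenic acid	OMEGA3	10.0	CH3_0.98	1
eicosapentaenoic acid	OMEGA3	10.0	CH3_0.98	0
docosahexaenoic acid	OMEGA3	10.0	CH3_0.98	0
sphingomyelin	SM	10.0	choline_3.48	0
soy phosphatidylinositol	PI	10.0	CH2_1.3	0
brain phosphatidylserine	PS	10.0	PE_3.40	0
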