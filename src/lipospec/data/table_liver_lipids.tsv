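# Lipid-class quantification in the liver of 10-month mice (mM per mg
# dry weight), group means and SDs with the published fold change
# (CpKO/WT) and p-value display. n = 5 per group.
peak_ppm	functional_group	lipid_class	cpko_mean	cpko_sd	wt_mean	wt_sd	fc_ko_wt	p_display
4.30-4.12	(-C1H2);(-C3H2)	TG	0.2011	0.0172	0.1579	0.0281	1.273	0.0191
3.48	(-N(CH3)3)	PC_LPC	0.0036	0.0022	0.0060	0.0064	0.596	NS
3.40	(-CH2-NH3+)	PE	0.0269	0.0043	0.0357	0.0176	0.756	NS
0.98	(-CH3)	OMEGA3	0.0449	0.0065	0.0359	0.0051	1.250	0.0418
0.90	(-CH3)	FA	0.6416	0.0811	0.5433	0.0496	1.181	0.0494
0.68	(-CH3)	TC	0.0186	0.0053	0.0167	0.0035	1.112	NS
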