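# Lipid-class quantification in perigonadal adipose tissue of 10-month
# mice (mM per mg fresh weight), group means and SDs with the published
# fold change (CpKO/WT) and p-value display. n = 5 per group.
peak_ppm	functional_group	lipid_class	cpko_mean	cpko_sd	wt_mean	wt_sd	fc_ko_wt	p_display
4.30-4.12	(-C1H2);(-C3H2)	TG	0.7776	0.1008	0.8148	0.0894	0.9543	NS
3.48	(-N(CH3)3)	PC_LPC	0.0012	0.0006	0.0008	0.0003	1.4844	NS
3.40	(-CH2-NH3+)	PE	0.0019	0.0024	0.0042	0.0024	0.4564	NS
0.98	(-CH3)	OMEGA3	0.0543	0.0111	0.0563	0.0108	0.9646	NS
0.90	(-CH3)	FA	1.7879	0.2284	1.8749	0.2090	0.9536	NS
0.68	(-CH3)	TC	0.0026	0.0004	0.0026	0.0005	0.9962	NS
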