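# In vivo liver MRS measurands (arbitrary units) in CpKO and WT mice at
# 6 and 10 months of age: group means and SDs, published fold changes
# (CpKO/WT per age; 10-month/6-month per genotype) and p-value displays.
# n = 5 per group.
measurand	cpko6_mean	cpko6_sd	wt6_mean	wt6_sd	fc6_ko_wt	p6_display	cpko10_mean	cpko10_sd	wt10_mean	wt10_sd	fc10_ko_wt	p10_display	fc_cpko_10v6	p_cpko_aging_display	fc_wt_10v6	p_wt_aging_display
IHLC	0.082	0.028	0.041	0.023	2.00	0.0342	0.154	0.07	0.102	0.036	1.51	NS	1.88	0.0645	2.49	0.0131
TG	0.00086	0.0009	0.0003	0.0002	3.07	0.0635	0.00141	0.0011	0.0009	0.0002	1.62	NS	1.64	NS	3.11	0.0014
SI	10.50	5.12	9.88	2.46	1.06	NS	8.34	4.46	10.50	2.62	0.79	NS	0.79	NS	1.06	NS
ndb	0.56	0.35	0.47	0.55	1.19	NS	0.78	0.54	0.88	0.93	0.89	NS	1.39	NS	1.87	NS
UFA	0.84	0.13	0.69	0.25	1.53	NS	0.58	0.21	1.04	0.29	0.56	0.0225	0.69	0.0486	1.51	NS
SFA	0.14	0.14	0.31	0.25	0.45	NS	0.42	0.21	0.17	0.17	2.47	0.0766	2.97	0.0422	0.54	NS
PUFA	0.70	0.46	0.52	0.08	1.35	NS	0.22	0.09	0.39	0.41	0.56	NS	0.31	0.0079	0.75	NS
MUFA	0.34	0.31	0.41	0.11	0.84	NS	0.31	0.22	0.50	0.42	0.61	NS	0.91	NS	1.22	NS
MCL	18.06	5.15	16.37	3.57	1.10	NS	15.16	5.60	18.71	3.34	0.81	NS	0.84	NS	1.14	NS
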