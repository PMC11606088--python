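trait	n_cross	n_long	sd_y	sd_change	medium_marginal	allele_freq	age_diff	r_y1y2	r2_gxage_pct	r2_change_pct	min_gxage
Weight	371541	52658	15.1	0.9	0.3	0.30	7.5	0.90	0.009	0.047	0.024
BMI	371416	52628	4.34	0.32	0.1	0.30	7.5	0.91	0.013	0.041	0.0069
DBP	346259	42150	10.95	1.58	0.2	0.30	7.5	0.65	0.008	0.007	0.018
SBP	346256	42144	19.77	2.76	0.4	0.30	7.5	0.65	0.010	0.009	0.032
PP	346256	42144	13.28	2.06	0.3	0.30	7.5	0.65	0.012	0.009	0.022
HDL_ln	359117	12180	0.26	0.04	0.005	0.30	4.3	0.62	0.009	0.007	0.00042
LDL	389885	15015	35.58	7.84	0.8	0.30	4.3	0.62	0.012	0.004	0.055
TG_ln	390270	15056	0.51	0.11	0.01	0.30	4.3	0.62	0.009	0.003	0.00079
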