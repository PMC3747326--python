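group	n	case_gif	mean_control_gif	empirical_significance
metastatic_at_dx	2	781.25	2117.19	0.800
other_primary	3	2213.54	5604.17	0.700
gleason_gt7	6	3307.29	3876.04	0.780
long_survival	4	195.31	2932.29	1.000
high_bmi	4	1562.50	1890.63	0.740
lethal	8	5970.98	5098.21	0.260
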