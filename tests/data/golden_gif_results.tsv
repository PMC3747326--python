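group	n	case_gif	mean_control_gif	empirical_significance
all	18	3990.50	2864.79	<0.02
metastatic_at_dx	2	781.25	3421.88	0.840
other_primary	3	2213.54	2992.19	0.560
gleason_gt7	6	3307.29	2872.40	0.380
long_survival	4	195.31	2475.26	1.000
high_bmi	4	1562.50	2345.05	0.560
lethal	8	5970.98	2896.76	0.040
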