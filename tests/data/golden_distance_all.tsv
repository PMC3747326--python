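distance	case_contribution	mean_control_contribution
1	551.4706	270.2206
2	510.6209	376.8382
3	837.4183	480.5964
4	878.2680	529.4628
5	500.4085	462.2141
6	370.2002	429.3301
7	234.8856	232.2304
8	107.2304	83.8950
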