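odds_ratio	p_ref	power_raw	power_bh	n_replicates
1.0	0.05	0.038	0.002	500
1.0	0.2	0.034	0.0	500
1.0	0.3	0.068	0.004	500
1.5	0.05	0.128	0.018	500
1.5	0.2	0.256	0.04	500
1.5	0.3	0.376	0.032	500
5.0	0.05	0.93	0.78	500
5.0	0.2	1.0	0.986	500
5.0	0.3	0.998	0.978	500
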