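mirna_id	de_p_value	n_targets	nod	nod_p_value
mir-198	6.80e-03	174	13	2.98e-08
mir-765	1.39e-05	98	10	1.19e-07
mir-671-5p	5.96e-04	68	10	1.19e-07
mir-630	9.69e-04	121	5	4.37e-03
mir-371-5p	2.11e-03	63	5	4.37e-03
mir-575	4.07e-03	65	4	1.75e-02
mir-202	1.40e-03	82	4	1.75e-02
mir-483-5p	1.44e-04	74	4	1.75e-02
mir-513a-5p	3.01e-04	23	3	4.78e-02
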