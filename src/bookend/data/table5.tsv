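molecule	expt	mm_qm	mm_mmp_qm	nbb
water	−6.31	−4.4±0.2	−4.5±0.2	−4.4±0.2
methanol	−5.10	−2.7±0.1	−2.9±0.1	−2.8±0.1
ethanol	−5.05	−3.0±0.3	−3.1±0.3	−3.1±0.3
methanethiol	−1.24	−0.7±0.1	−0.7±0.1	−0.7±0.1
acetamide	−9.68	−12.7±0.4	−12.5±0.4	−12.5±0.4
tetrahydrofuran	−3.47	−3.9±0.5	−4.1±0.4	−4.2±0.4
benzene	−0.86	−2.0±0.2	−2.1±0.2	−2.0±0.2
phenol	−6.61	−5.0±0.5	−5.2±0.3	−5.2±0.3
aniline	−5.49	−5.1±0.5	−5.8±0.2	−5.8±0.2
ethane	1.83	1.8±0.1	1.8±0.1	1.8±0.1
hexane	2.48	1.7±0.3	1.6±0.4	1.6±0.4
cyclohexane	1.23	1.0±0.2	0.9±0.2	0.9±0.2
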