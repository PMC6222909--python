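molecule	expt	om2	hf	mp2	m062x	b3lyp	blyp	am1
water	−6.31	−2.8±0.2	−6.3±0.2	−4.4±0.2	−5.4±0.2	−4.6±0.2	−3.2±0.2	−1.8±0.2
methanol	−5.10	−3.2±0.2	−4.7±0.3	−4.6±0.4	−4.3±0.2	−3.7±0.2	−3.3±0.3	−1.7±0.2
ethanol	−5.05	−2.9±0.4	−3.5±0.4	−3.6±0.2	−3.2±0.3	−2.7±0.2	−2.3±0.4	−0.7±0.5
methanethiol	−1.24	−1.0±0.2	−2.8±0.4	−1.8±0.2	−2.0±0.3	−1.4±0.3	−0.1±0.4	−2.0±0.2
acetamide	−9.68	−7.5±2.7	−2.6±2.2	−2.8±1.3	−1.9±1.6	−1.5±1.6	−0.6±1.7	−3.0±2.9
tetrahydrofuran	−3.47	−3.8±0.5	−2.6±0.3	−2.3±0.2	−1.6±0.2	−1.2±0.2	−0.5±0.3	−1.6±0.5
benzene	−0.86	−2.3±0.3	−1.1±0.4	−0.9±0.2	−0.7±0.3	−0.4±0.2	0.0±0.2	−0.3±0.3
phenol	−6.61	−8.1±0.8	−9.9±1.2	−10.4±0.4	−9.5±0.9	−8.8±0.7	−8.4±0.4	−3.8±0.4
aniline	−5.49	−5.8±0.6	−7.4±1.1	−7.1±0.4	−7.1±0.7	−6.1±0.5	−5.5±0.5	−3.2±0.5
ethane	1.83	1.9±0.1	2.2±0.2	2.4±0.2	2.3±0.2	2.4±0.2	2.9±0.2	2.5±0.2
hexane	2.48	2.4±0.3	2.5±0.6	2.7±0.3	2.9±0.3	2.9±0.3	3.3±0.3	2.7±0.3
cyclohexane	1.23	1.8±0.3	1.9±0.3	2.0±0.2	2.1±0.2	2.2±0.2	2.5±0.2	1.9±0.3
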