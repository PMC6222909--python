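molecule	expt	om2	blyp	b3lyp	m062x	mp2	am1	hf
water	−6.31	−4.4±0.2	−8.1±0.2	−8.8±0.2	−9.6±0.2	−8.8±0.2	−2.3±0.2	−10.0±0.2
methanol	−5.10	−4.2±0.4	−5.1±0.2	−5.1±0.1	−5.5±0.1	−5.8±0.1	−1.6±0.1	−6.3±0.2
ethanol	−5.05	−6.7±1.3	−8.5±1.8	−7.0±1.8	−7.2±1.8	−8.1±2.0	−2.0±0.4	−6.6±0.8
methanethiol	−1.24	−0.8±0.2	−2.6±0.4	−3.0±0.3	−3.2±0.2	−3.2±0.3	−4.0±0.2	−3.5±0.1
acetamide	−9.68	−12.7±0.6	−11.4±0.9	−12.2±0.6	−12.9±0.6	−13.8±0.5	−8.4±0.4	−14.8±0.7
tetrahydrofuran	−3.47	−4.5±0.6	−3.4±0.3	−4.2±0.2	−4.6±0.3	−5.3±0.3	−2.2±0.5	−5.9±0.4
benzene	−0.86	−2.1±0.2	−0.5±0.2	−0.9±0.2	−1.4±0.2	−1.5±0.2	0.1±0.3	−1.8±0.2
phenol	−6.61	−5.5±0.5	−6.0±0.4	−6.9±0.3	−7.7±0.3	−7.7±0.4	−2.7±0.3	−8.3±0.5
aniline	−5.49	−6.0±0.4	−7.3±0.8	−7.9±0.4	−8.7±0.3	−9.0±0.4	−3.6±0.6	−8.8±0.3
ethane	1.83	1.8±0.1	2.0±0.1	1.9±0.1	1.9±0.1	1.7±0.1	2.1±0.1	1.9±0.1
n-hexane	2.48	1.8±0.4	2.3±0.3	2.1±0.3	1.9±0.3	1.5±0.3	2.5±0.4	2.1±0.4
cyclohexane	1.23	0.9±0.5	1.2±0.2	1.1±0.2	1.1±0.2	0.8±0.2	1.3±0.3	1.0±0.5
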