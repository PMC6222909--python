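molecule	expt	dg_fc	dg_drude	ddg_fc_minus_drude
water	−6.31	−6.91 ± 0.04	−5.77 ± 0.02	−1.14
methanol	−5.10	−4.68 ± 0.02	−4.90 ± 0.03	0.21
ethanol	−5.05	−4.62 ± 0.08	−4.65 ± 0.05	0.02
methanethiol	−1.24	−0.23 ± 0.01	−1.04 ± 0.03	0.80
acetamide	−9.68	−8.15 ± 0.06	−10.64 ± 0.06	2.50
tetrahydrofuran	−3.47	−2.55 ± 0.05	−3.12 ± 0.03	0.57
benzene	−0.86	−0.29 ± 0.03	−1.36 ± 0.05	1.07
phenol	−6.61	−4.72 ± 0.07	−7.07 ± 0.03	2.35
aniline	−5.49	−5.05 ± 0.04	−6.13 ± 0.05	1.08
ethane	1.83	2.23 ± 0.01	2.16 ± 0.02	0.07
hexane	2.48	2.77 ± 0.07	2.54 ± 0.08	0.23
cyclohexane	1.23	1.77 ± 0.04	2.15 ± 0.04	−0.38
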