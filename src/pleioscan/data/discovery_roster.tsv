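study	n	n_female	age_mean	age_sd	bmi_mean	bmi_sd	whr_women_mean	whr_women_sd	whr_men_mean	whr_men_sd	crp_mean	crp_sd
SOL	11986	7026	46.1	13.8	29.8	6.0	90.0	7.2	95.4	6.8	3.9	5.9
BioMe	10727	6766	51.6	16.2	29.5	6.6	.	.	.	.	4.1	4.4
WHI	5386	5386	60.2	6.8	29.1	6.3	82.0	8.0	.	.	5.0	6.6
MEC	7772	3555	60.0	7.1	27.9	4.8	88.1	7.6	95.6	6.4	3.9	4.4
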