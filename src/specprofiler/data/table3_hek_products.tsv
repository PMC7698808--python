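# Reference data: CPZ cleavage products identified in the HEK293T
# peptide-library screen. cleaved_aa is the residue removed from the
# precursor to generate the observed peptide.
type	precursor	sequence	cleaved_aa	Z	T	obs_m	theor_m	ppm	ratio_100nM	ratio_10nM	ratio_1nM	ratio_0.1nM
Product	Heat shock 10 kDa protein 1	AVGSGSKGKGGEIQPVSV	K	3	3	1655.89	1655.89	2	1.30	1.16	1.28	0.93
Product	Peptidylprolyl isomerase A	ADKVPKTAENF	R	3	3	1218.62	1218.62	-3	1.36	1.09	1.13	1.09
Product	Nucleophosmin	EKTPKTPKGPSSVEDIKA	K	5	5	1911.00	1911.03	-18	1.46	1.00	1.23	1.15
Product	FK506 Binding Protein	VFDVELL	K	1	1	833.45	833.45	2	1.50	1.28	n.d.	1.25
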