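# Reference data: Michaelis-Menten constants for hydrolysis of the
# fluorescent substrate dansyl-Phe-Ala-Arg by B-type metallocarboxypeptidases.
# Km in uM, kcat in 1/s, kcat/Km in 1/(uM s); se columns are reported
# standard errors (n.d. where not reported).
enzyme	Km	Km_se	kcat	kcat_se	kcat_over_Km	kcat_over_Km_se
CPZ	1905	360	5.3	0.6	0.0028	0.0008
CPZdFz	1667	385	6.2	0.8	0.0039	0.0014
CPD_domain_I	319	37	8.5	0.5	0.027	0.003
CPD_domain_II	844	139	7.0	0.9	0.008	0.001
CPE	34	n.d.	13	n.d.	0.38	n.d.
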