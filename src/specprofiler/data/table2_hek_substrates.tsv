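# Reference data: good and weak CPZ substrates identified in the HEK293T
# peptide-library screen (5-plex TMAB labeling; 100/10/1/0.1 nM enzyme vs
# no-enzyme control). Masses in Da; ratios are enzyme/no-enzyme peak
# intensities.
type	precursor	sequence	Z	T	obs_m	theor_m	ppm	ratio_100nM	ratio_10nM	ratio_1nM	ratio_0.1nM
Good	Histidine triad nucleotide-binding protein 1	Ac-ADEIAKAQVAR	2	1	1212.66	1212.65	14	0.02	0.94	1.08	1.00
Good	Eukaryotic translation initiation factor 5A	SAMoxTEEAAVAIKAMAK	3	3	1636.81	1636.82	-5	0.07	0.15	0.95	0.95
Good	Vimentin	AELEQLKGQGKSR	4	3	1442.78	1442.78	-3	0.18	1.00	1.03	0.95
Good	Hematological and neurological expressed 1 protein	Ac-TTTTTFKGVDPNSRNSSR	3	1	2010.00	2009.98	13	0.31	0.89	1.24	1.07
Weak	Eukaryotic translation initiation factor 5A	NMDVPNIKR	3	2	1085.56	1085.57	-6	0.45	n.d.	n.d.	0.82
Weak	Ubiquitin-60S ribosomal protein L40	IIEPSLR	2	1	826.49	826.49	0	0.60	1.00	1.13	1.04
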