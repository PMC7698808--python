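# Reference data: CPZ substrates and products identified in the tryptic
# peptide-library screen (4-plex TMAB labeling; 1/10/100 nM enzyme vs
# no-enzyme control). The theor_m values of the GQEFTITGQKR and LF rows are
# internally inconsistent with their own ppm columns (typographic) and are
# excluded from mass validation.
type	precursor	sequence	cleaved_aa	Z	T	obs_m	theor_m	ppm	ratio_100nM	ratio_10nM	ratio_1nM
Good	Thyroglobulin	GQEFTITGQKR	-	2	2	1263.66	1263.60	-2	0.38	1.13	0.97
Weak	Thyroglobulin	ALEQATR	-	2	1	787.42	787.42	3	0.57	1.04	1.00
Weak	Thyroglobulin	AVKQFEESQGR	-	3	2	1277.64	1277.64	0	0.68	0.86	0.95
Weak	Bovine serum albumin	KVPQVSTPTLVEVSR	-	3	2	1638.93	1638.93	-2	0.70	0.90	0.95
Weak	Bovine serum albumin	KQTALVELLK	-	3	3	1141.69	1141.71	-22	0.73	0.80	0.89
Weak	Thyroglobulin	LPESK	-	2	2	572.31	572.32	-24	0.77	0.83	0.83
Product	Thyroglobulin	GQEFTITGQK	R	2	2	1107.56	1107.56	-4	1.52	0.78	1.04
Product	Thyroglobulin	LF	R	1	1	278.16	278.15	14	1.56	0.88	0.88
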