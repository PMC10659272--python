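donor_id	group	age_years	sex	n_nuclei	n_scwgs_cells
d01	infant	0.4	M	22444	4
d02	infant	0.6	M	18086	7
d03	adult	15	F	29076	4
d04	adult	27	M	27686	5
d05	adult	28	M	19741	5
d06	adult	38	M	20881	4
d07	adult	42	F	36777	4
d08	adult	49	F	22868	5
d09	adult	57	F	20700	4
d10	elderly	82	M	28566	4
d11	elderly	87	M	14230	4
d12	elderly	93	M	16159	5
d13	elderly	104	F	13600	4
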