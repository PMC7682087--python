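# Nine per-residue physicochemical property scales from the AAindex1
# database (https://www.genome.jp/aaindex/), one row per property.
# Columns follow the fixed encoder alphabet ACDEFGHIKLMNPQRSTVWYX.
# The X column is the dummy padding residue and is set to 0 for every
# property (configurable at load time).
#
# property	accession	reference
# hydrophilicity	HOPT810101	Hopp & Woods 1981
# mean_polarity	RADA880108	Radzicka & Wolfenden 1988
# isoelectric_point	ZIMJ680104	Zimmerman, Eliezer & Simha 1968
# refractivity	MCMT640101	McMeekin, Groves & Hipp 1964
# average_flexibility	BHAR880101	Bhaskaran & Ponnuswamy 1988
# buried_volume	CHOC750101	Chothia 1975
# electron_ion_interaction	VELV850101	Veljkovic et al. 1985 / Cosic 1994
# transfer_free_energy_surface	BULH740101	Bull & Breese 1974
# consensus_hydrophobicity	EISD840101	Eisenberg et al. 1984
#
# name	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y	X
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3	0
mean_polarity	-0.06	1.36	-0.80	-0.77	1.27	-0.41	0.49	1.31	-1.18	1.21	1.27	-0.48	0.0	-0.73	-0.84	-0.50	-0.27	1.09	0.88	0.33	0
isoelectric_point	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66	0
refractivity	4.34	35.77	12.00	17.26	29.40	0.00	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53	0
average_flexibility	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420	0
buried_volume	91.5	117.7	124.5	155.1	203.4	66.4	167.3	168.8	171.3	167.9	170.8	135.2	129.3	161.1	202.1	99.1	122.1	141.7	237.6	203.6	0
electron_ion_interaction	0.0373	0.0829	0.1263	0.0058	0.0946	0.0050	0.0242	0.0000	0.0371	0.0000	0.0823	0.0036	0.0198	0.0761	0.0959	0.0829	0.0941	0.0057	0.0548	0.0516	0
transfer_free_energy_surface	0.610	0.360	0.610	0.510	-1.520	0.810	0.690	-1.450	0.460	-1.650	-0.660	0.890	-0.170	0.970	0.690	0.420	0.290	-0.750	-1.200	-1.430	0
consensus_hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26	0
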