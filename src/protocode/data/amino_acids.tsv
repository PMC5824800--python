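name3	name1	vdw_volume	pka	logp	mol_weight	sc_c	sc_n	sc_o	sc_s	sc_benzene	bb_ia	bb_iva	polar_requirement	aa_class	aars_class	transfer_weight
Ala	A	67.0	2.34	-2.85	89.09	1	0	0	0	0	1	0	7.0	simple	II	9.5
Arg	R	148.0	2.17	-4.20	174.20	1	1	0	0	0	1	0	9.1	complex	I	5.5
Asn	N	96.0	2.02	-3.82	132.12	1	1	1	0	0	1	0	10.0	complex	II	3.9
Asp	D	91.0	1.88	-3.89	133.10	1	0	1	0	0	1	0	13.0	simple	II	5.4
Cys	C	86.0	1.96	-2.49	121.16	1	0	0	1	0	1	0	4.8	sulfur	I	1.2
Gln	Q	114.0	2.17	-3.64	146.15	1	1	1	0	0	1	0	8.6	complex	I	3.9
Glu	E	109.0	2.19	-3.69	147.13	1	0	1	0	0	1	0	12.5	simple	I	6.3
Gly	G	48.0	2.34	-3.21	75.07	0	0	0	0	0	1	0	7.9	simple	II	7.4
His	H	118.0	1.82	-3.32	155.15	1	1	0	0	0	1	0	8.4	complex	II	2.1
Ile	I	124.0	2.36	-1.70	131.17	1	0	0	0	0	1	0	4.9	simple	I	6.0
Leu	L	124.0	2.36	-1.52	131.17	1	0	0	0	0	1	0	4.9	simple	I	10.4
Lys	K	135.0	2.18	-3.05	146.19	1	1	0	0	0	1	0	10.1	complex	II	5.3
Met	M	124.0	2.28	-1.87	149.21	1	0	0	1	0	1	0	5.3	sulfur	I	2.9
Phe	F	135.0	1.83	-1.38	165.19	1	0	0	0	1	1	0	5.0	complex	II	3.9
Pro	P	90.0	1.99	-2.54	115.13	1	0	0	0	0	0	1	6.6	simple	II	4.4
Ser	S	73.0	2.21	-3.07	105.09	1	0	1	0	0	1	0	7.5	simple	II	5.8
Thr	T	93.0	2.09	-2.94	119.12	1	0	1	0	0	1	0	6.6	simple	II	5.4
Trp	W	163.0	2.38	-1.05	204.23	1	1	0	0	1	1	0	5.2	complex	I	1.1
Tyr	Y	141.0	2.20	-2.26	181.19	1	0	1	0	1	1	0	5.4	complex	I	2.9
Val	V	105.0	2.32	-2.26	117.15	1	0	0	0	0	1	0	5.6	simple	I	7.2
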