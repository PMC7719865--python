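panu3_chrom	panu3_start_mb	panu3_end_mb	panu2_start_mb	panu2_end_mb	type	linkage_support	bng_support	ld_support
NC_018164.2	88.05	104.99	87.61	104.98	Inv	start	yes	unknown
NC_018167.2	29.38	44.71	29.25	44.53	Inv	start+end	yes	start+end
NC_018156.2	4.04	8.67	4.18	8.63	Inv	no	yes	no
NC_018162.2	82.42	86.47	81.91	84.01	Trans	start+end	no	no
NC_018166.2	104.28	108.05	103.66	107.44	Inv	no	yes	no
NC_018165.2	15.93	19.48	15.85	19.40	Inv	no	no	no
NC_018166.2	96.94	100.12	96.39	99.54	Trans	start+end	yes	start+end
NC_018160.2	36.05	36.75	35.88	36.55	Trans	no	yes	start
NC_018163.2	23.19	23.66	0.00	0.47	Trans	no	yes	no
NC_018164.2	4.05	4.49	3.99	4.45	Trans	no	yes	no
NC_018165.2	100.91	101.18	100.31	100.59	Trans	no	yes	no
NC_018152.2	166.73	166.89	169.86	170.10	Trans	start+end	yes	end
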