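panubis1_chrom	panubis1_start_mb	panubis1_end_mb	genbank_chrom	panu3_chrom	panu3_start_mb	panu3_end_mb
NC_044992.1	28.89	45.01	CM001506.2	NC_018167.2	29.38	44.79
NC_044995.1	0.00	13.00	CM001509.2	NC_018170.2	0.00	13.31
NC_044987.1	101.26	106.48	CM001504.2	NC_018165.2	101.44	107.53
NC_044978.1	176.83	181.37	CM001495.2	NC_018156.2	175.08	180.09
NC_044986.1	86.61	90.73	CM001499.2	NC_018160.2	85.56	90.30
NC_044988.1	0.00	3.50	CM001505.2	NC_018166.2	0.00	3.78
NC_044996.1	86.67	89.58	CM001511.2	NC_018172.2	86.91	90.23
NC_044982.1	154.35	156.82	CM001497.2	NC_018158.2	155.71	158.53
NC_044984.1	7.96	10.58	CM001501.2	NC_018162.2	8.03	10.83
NC_044991.1	33.09	35.09	CM001500.2	NC_018161.2	32.46	35.05
NC_044996.1	93.67	95.52	CM001511.2	NC_018172.2	94.22	96.59
NC_044981.1	68.61	71.05	CM001494.2	NC_018155.2	69.37	71.65
NC_044996.1	40.49	42.78	CM001511.2	NC_018172.2	41.15	43.34
NC_044996.1	10.01	11.79	CM001511.2	NC_018172.2	10.20	12.06
NC_044996.1	31.80	33.37	CM001511.2	NC_018172.2	32.11	33.97
NC_044979.1	142.32	144.05	CM001493.2	NC_018154.2	141.96	143.71
NC_044996.1	90.77	92.54	CM001511.2	NC_018172.2	91.42	92.99
NC_044993.1	63.59	65.52	CM001510.2	NC_018171.2	62.31	63.73
NC_044991.1	26.79	28.49	CM001500.2	NC_018161.2	26.52	27.82
NC_044980.1	0.02	0.78	CM001496.2	NC_018157.2	0.02	1.26
NC_044979.1	0.00	0.73	CM001493.2	NC_018154.2	0.00	0.75
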