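taxon	marker	mz	peptide	n_hyd	note
Bos sp.	P1	1105.5748	GVQGPPGPAGPR	1	shared mammalian COL1A1 508-519; deamidation reference peptide
Bos sp.	A	1297.6131	GEAGPSGPAGPTGAR	1
Bos sp.	B	1610.8132	GLPGESGAVGPAGPIGSR	2
Bos sp.	C	1580.7960
Bos sp.	D	2131.0640
Bos sp.	E	2792.3600
Bos sp.	F	2853.3500
Bos sp.	G	3093.4800
Bison sp.	P1	1105.5748	GVQGPPGPAGPR	1	identical to Bos on all listed markers
Bison sp.	A	1297.6131	GEAGPSGPAGPTGAR	1
Bison sp.	B	1610.8132	GLPGESGAVGPAGPIGSR	2
Bison sp.	C	1580.7960
Bison sp.	D	2131.0640
Bison sp.	E	2792.3600
Bison sp.	F	2853.3500
Bison sp.	G	3093.4800
Ovibos moschatus	P1	1105.5748	GVQGPPGPAGPR	1	matches Bos/Bison below 2500 m/z
Ovibos moschatus	A	1297.6131	GEAGPSGPAGPTGAR	1
Ovibos moschatus	B	1610.8132	GLPGESGAVGPAGPIGSR	2
Ovibos moschatus	C	1580.7960
Ovibos moschatus	D	2131.0640
Ovibos moschatus	E	2808.3800
Ovibos moschatus	F	2869.3700
Ovibos moschatus	G	3059.4400
Rangifer tarandus	P1	1105.5748	GVQGPPGPAGPR	1
Rangifer tarandus	A	1180.5900
Rangifer tarandus	B	1439.7000
Rangifer tarandus	C	1550.7700
Rangifer tarandus	D	2131.0640
Rangifer tarandus	E	2792.3600
Rangifer tarandus	F	2883.3200
Rangifer tarandus	G	3017.4000
Cervus elaphus	P1	1105.5748	GVQGPPGPAGPR	1
Cervus elaphus	A	1180.5900
Cervus elaphus	B	1427.6960
Cervus elaphus	C	1550.7700
Cervus elaphus	D	2131.0640
Cervus elaphus	E	2792.3600
Cervus elaphus	F	2883.3200
Cervus elaphus	G	3033.4000
Equus caballus	P1	1105.5748	GVQGPPGPAGPR	1
Equus caballus	A	1182.6100
Equus caballus	B	1443.7100
Equus caballus	C	1576.8100
Equus caballus	D	2145.0800
Equus caballus	E	2808.4200
Equus caballus	F	2869.4100
Equus caballus	G	3067.4300
Homo sapiens	P1	1105.5748	GVQGPPGPAGPR	1
Homo sapiens	A	1161.6000
Homo sapiens	B	1453.7200
Homo sapiens	C	1562.7700
Homo sapiens	D	2115.0700
Homo sapiens	E	2776.3700
Homo sapiens	F	2837.3600
Homo sapiens	G	3077.4500
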