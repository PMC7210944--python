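layer	category	common_name	nisp	ribs	group
Pech I 4	Vulpes vulpes	fox	1	0
Pech I 4	Lepus sp.	hare	2	0
Pech I 4	Capreolus capreolus	roe deer	44	3
Pech I 4	Cervus elaphus	red deer	327	12
Pech I 4	Rangifer tarandus	reindeer	12	0
Pech I 4	Cervus/Rangifer	red deer/reindeer	12	0	medium ungulate
Pech I 4	Bison sp./Bos sp.	bison/aurochs	114	9	large bovid
Pech I 4	Equus caballus	horse	6	0
Pech I 4	small ungulate	ungulate size class 1	1	0
Pech I 4	ungulate size class 1/2	ungulate size class 1/2	2	1	medium ungulate
Pech I 4	medium ungulate	ungulate size class 2	59	30	medium ungulate
Pech I 4	ungulate size class 2/3	ungulate size class 2/3	16	14	medium ungulate
Pech I 4	ungulate size class 2/4	ungulate size class 2/4	15	0	medium ungulate
Pech I 4	large ungulate	ungulate size class 3/4	29	22	large bovid
Pech I 4	avifauna	avifauna	2	0
L-3A	Capreolus capreolus	roe deer	4	0
L-3A	Cervus elaphus	red deer	7	0
L-3A	Rangifer tarandus	reindeer	12	0
L-3A	Cervus/Rangifer	red deer/reindeer	22	2	medium ungulate
L-3A	Cervid	cervid (antler tips)	1	0
L-3A	Cervid/Saiga	cervid/saiga	1	0	medium ungulate
L-3A	Bison sp./Bos sp.	bison/aurochs	10	2	large bovid
L-3A	large ungulate	ungulate size class 3/4	10	1	large bovid
L-3A	large carnivore	large carnivore	1	0
L-3B	Lepus sp.	hare	3	0
L-3B	Capreolus capreolus	roe deer	1	0
L-3B	Rangifer tarandus	reindeer	264	2
L-3B	Cervus/Rangifer	red deer/reindeer	219	83	medium ungulate
L-3B	Cervid	cervid (antler tips)	1	0
L-3B	Bison sp./Bos sp.	bison/aurochs	16	7	large bovid
L-3B	large ungulate	ungulate size class 3/4	35	2	large bovid
L-3B	Rhinocerotid	rhinoceros	1	0
L-3B	medium carnivore	medium carnivore	1	0
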