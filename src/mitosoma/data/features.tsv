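# synthetic mitochondrial gene annotation; 1-based inclusive
# coordinates; start > end marks an origin-wrapping feature;
# strand L = reference plus strand, H = reverse complement
name	start	end	strand	class
D-loop	16024	576	L	D-loop
TF	577	647	L	tRNA
RNR1	648	1601	L	rRNA
TV	1602	1670	L	tRNA
RNR2	1671	3229	L	rRNA
TL1	3230	3304	L	tRNA
ND1	3307	4260	L	protein
TI	4263	4331	L	tRNA
TQ	4332	4400	H	tRNA
TM	4402	4469	L	tRNA
ND2	4470	5510	L	protein
TW	5512	5579	L	tRNA
TA	5587	5655	H	tRNA
TN	5657	5729	H	tRNA
TC	5761	5825	H	tRNA
TY	5826	5891	H	tRNA
CO1	5904	7445	L	protein
TS1	7446	7514	H	tRNA
TD	7518	7585	L	tRNA
CO2	7586	8269	L	protein
TK	8295	8364	L	tRNA
ATP8	8366	8572	L	protein
ATP6	8527	9207	L	protein
CO3	9207	9989	L	protein
TG	9991	10058	L	tRNA
ND3	10059	10403	L	protein
TR	10405	10469	L	tRNA
ND4L	10470	10766	L	protein
ND4	10760	12136	L	protein
TH	12138	12206	L	tRNA
TS2	12207	12265	L	tRNA
TL2	12266	12331	L	tRNA
ND5	12337	14148	L	protein
ND6	14149	14673	H	protein
TE	14674	14742	H	tRNA
CYB	14747	15886	L	protein
TT	15888	15953	L	tRNA
TP	15956	16023	H	tRNA
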