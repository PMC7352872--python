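gene	rank	variant	dna_change	consequence	dbsnp	freq_cluster1_pct	freq_cluster2_pct
ASIC1	27	X12.50467644.SNV	G > T	INTRONIC	rs706792	32	42
ASIC2	3	X17.31618732.SNV	A > G	REGULATORY	rs9893935	39	66
ASIC2	6	X17.31619500.SNV	T > C	REGULATORY	rs9906918	48	42
ASIC2	17	X17.31619744.Ins	* > C	INSERTION	rs981465862	21	38
ASIC2	26	X17.31340390.SNV	T > C	3PRIME_UTR	rs28936	39	56
ASIC4	37	X2.220402680.SNV	T > C	REGULATORY	rs11695248	45	40
TRPA1	21	X8.72966124.SNV	A > G	DOWNSTREAM INTRONIC	rs3735944	50	28
TRPA1	32	X8.72966002.SNV	G > A	SYNONYMOUS	rs3735943	30	50
TRPC1	38	X3.142526594.SNV	T > C	DOWNSTREAM	rs4627	20	30
TRPM3	11	X9.73150873.SNV	T > G	NON-SYNONYMOUS	rs17535963	24	34
TRPM3	28	X9.73461337.SNV	T > A	SYNONYMOUS	rs7862440	35	16
TRPM3	29	X9.73461558.SNV	G > C	INTRONIC	rs10868907	48	62
TRPM3	33	X9.73457832.SNV	G > A	INTRONIC	rs1337031	39	56
TRPM3	34	X9.73150918.SNV	C > T	NON-SYNONYMOUS	rs41287373	43	60
TRPM3	35	X9.73457861.SNV	A > G	INTRONIC	rs1337030	24	36
TRPM5	8	X11.2435956.SNV	C > T	NON-SYNONYMOUS	rs4929982	30	48
TRPM5	16	X11.2435931.SNV	C > T	INTRONIC	rs4929980	20	4
TRPM5	22	X11.2435809.SNV	T > C	INTRONIC	rs4930102	37	44
TRPM5	25	X11.2435946.SNV	A > C	SPLICE_SITE	rs4929981	45	54
TRPV1	2	X17.3469853.SNV	A > C	3PRIME UTR	rs4790522	15	36
TRPV1	9	X17.3480447.SNV	T > C	NON-SYNONYMOUS	rs8065080	46	62
TRPV2	15	X17.16318932.SNV	T > C	REGULATORY	rs3813769	30	42
TRPV2	24	X17.16325968.SNV	A > G	SYNONYMOUS	rs8121	31	50
TRPV2	30	X17.16323609.Del	TAGT > *	DELETION	rs5819569	43	30
TRPV2	36	X17.16323589.SNV	C > A	REGULATORY	rs4273076	49	32
TRPV3	1	X17.3433672.SNV	C > A	REGULATORY	rs376793	32	40
TRPV3	5	X17.3427442.SNV	A > G	INTRONIC	rs62069862	36	36
TRPV3	7	X17.3416555.SNV	C > A	INTRONIC	rs7208811	48	58
TRPV3	10	X17.3448331.SNV	A > T	INTRONIC	rs12945853	49	58
TRPV3	12	X17.3447914.SNV	C > T	SYNONYMOUS	rs1039519	46	34
TRPV3	18	X17.3436080.SNV	C > T	SYNONYMOUS	rs395357	43	30
TRPV3	19	X17.3430271.SNV	A > C	INTRONIC	rs11657715	46	62
TRPV3	20	X17.3415646.SNV	A > G	DOWNSTREAM INTRONIC	rs9303177	49	58
TRPV3	23	X17.3416309.SNV	A > G	DOWNSTREAM INTRONIC	rs9303177	32	16
TRPV3	31	X17.3414160.SNV	T > C	DOWNSTREAM INTRONIC	rs2271158	49	58
TRPV4	4	X12.110246383.SNV	T > C	INTRONIC	rs3742031	48	36
TRPV4	13	X12.110246369.SNV	A > G	INTRONIC	rs3742032	-	-
TRPV4	14	X12.110240838.SNV	T > A	NON-SYNONYMOUS	rs3825394	15	30
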