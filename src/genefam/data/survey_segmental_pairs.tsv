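gene_1	chr_1	start_1	end_1	len_1	gene_2	chr_2	start_2	end_2	len_2	evalue	ka_ks	ka	ks	t_years
BnRH-020	9	155278	156587	1309	BnRH-035	0	108823	111283	2460	0	0.5034	0.02242	0.044545	3395160.1
BnRH-019	9	374305	376452	2147	BnRH-024	10	69125	70432	1307	0	1.0232	0.3585	0.3504	26707317
BnRH-043	6	267642	269840	2198	BnRH-018	10	19064	20718	1654	0	0.9503	0.3277	0.3449	26288110
BnRH-004	5	451258	452136	878	BnRH-012	1	146054	149326	3272	0	0.9206	0.3519	0.3822	29131098
BnRH-005	3	1494980	1498357	3377	BnRH-003	7	209724	211043	1319	0	1.0456	0.4534	0.4336	33048780
BnRH-021	9	295276	301212	5936	BnRH-032	1	10280	12945	2665	0	0.9793	0.8722	0.8906	67881098
BnRH-037	7	3665918	3669619	3701	BnRH-034	2	491779	494667	2888	0	1.0309	0.2948	0.2859	21791159
BnRH-044	3	1134199	1134990	791	BnRH-049	3	896000	898879	2879	0	1.0882	0.2365	0.2173	16562500
BnRH-008	4	541313	545395	4082	BnRH-010	6	420376	423140	2764	0	1.0468	0.4405	0.4208	32073171
BnRH-041	2	591701	593387	1686	BnRH-002	9	208559	211653	3094	0	0.8414	0.04603	0.054706	4169643.3
BnRH-060	3	590717	593629	2912	BnRH-072	2	2633	5008	2375	0	0.9149	0.07868	0.085991	6554211.1
BnRH-061	3	590717	593629	2912	BnRH-077	2	2633	5008	2375	0	0.9473	0.07912	0.083519	6365742.4
BnRH-069	7	3053762	3054853	1091	BnRH-052	3	229605	232399	2794	0	0.907	0.2966	0.327	24923780
BnRH-066	5	1524365	1525636	1271	BnRH-058	3	153299	156485	3186	0	1.2125	0.3236	0.2669	20342988
BnRH-053	3	1138324	1139205	881	BnRH-050	3	896794	898879	2085	0	1.0637	0.2186	0.2055	15663110
BnRH-101	3	677191	678483	1292	BnRH-097	3	524321	526803	2482	0	1.0123	0.2922	0.2886	21996951
BnRH-082	8	462969	464615	1646	BnRH-102	4	68703	70360	1657	0	1.3324	0.3288	0.2467	18803354
BnRH-104	5	1747505	1749879	2374	BnRH-089	5	451258	452136	878	0	0.9073	0.5462	0.6021	45891768
BnRH-099	3	1103675	1105270	1595	BnRH-081	8	241092	242806	1714	0	0.8312	0.03467	0.04171	3179142.5
BnRH-096	1	472691	474941	2250	BnRH-092	1	94903	97128	2225	0	1.1518	0.2171	0.1885	14367378
BnRH-043	6	267642	269840	2198	BnRH-018	10	19064	20718	1654	0	0.9503	0.3277	0.3449	26288110
BnRH-100	3	1134199	1134990	791	BnRH-080	8	240722	242806	2084	0	1.0791	0.2371	0.2197	16745427
BnRH-087	9	1343959	1346143	2184	BnRH-083	8	462969	464615	1646	0	1.1999	0.2959	0.2466	18795732
BnRH-117	3	590714	593629	2915	BnRH-129	7	209724	211043	1319	0	1.222	0.5148	0.4213	32111280
BnRH-100	3	1134199	1134990	791	BnRH-080	8	240722	242806	2084	0	1.0791	0.2371	0.2197	16745427
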