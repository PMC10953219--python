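gene_1	chr_1	start_1	end_1	len_1	gene_2	chr_2	start_2	end_2	len_2	evalue	ka_ks	ka	ks	t_years
BnRH-007	6	233177	235993	2816	BnRH-030	1	1241658	1243017	1359	0	1.3118	0.2379	0.1813	13818598
BnRH-001	3	341531	342724	1193	BnRH-038	5	1247232	1248941	1709	0	1.09	0.1333	0.1223	9321646
BnRH-036	3	169756	172283	2527	BnRH-033	3	169756	172000	2244	0	0.8748	0.000875	0.000551	41967.23
BnRH-025	3	169756	172283	2527	BnRH-022	3	169756	172283	2527	0	0.8748	0.000875	0.000551	41967.23
BnRH-031	0	84287	85342	1055	BnRH-006	4	134261	136180	1919	0	1.1996	0.5231	0.4361	33239329
BnRH-027	1	168717	171031	2314	BnRH-023	1	433518	436114	2596	0	0.8217	0.002943	0.003581	272954.3
BnRH-013	5	306071	307747	1676	BnRH-009	7	1364611	1367118	2507	0	0.8486	0.1736	0.2046	15594512
BnRH-029	1	11494	12584	1090	BnRH-028	1	11494	12584	1090	0	1.3688	0.009476	0.006923	527629.6
BnRH-047	2	460676	462247	1571	BnRH-014	7	3053762	3055444	1682	0	1.3844	0.5952	0.4299	32766768
BnRH-050	3	896794	898879	2085	BnRH-048	3	896000	898879	2879	0	0.7491	0.1788	0.2387	18193598
BnRH-011	7	28076	33816	5740	BnRH-040	3	1311916	1314072	2156	0	0.9254	0.2289	0.2473	18849085
BnRH-075	2	2633	5008	2375	BnRH-074	2	2633	5008	2375	0	0	0	1E-10	0.007622
BnRH-065	2	2633	5008	2375	BnRH-062	3	590717	593629	2912	0	0	0	1E-10	0.007622
BnRH-073	2	2633	5008	2375	BnRH-059	3	590717	593629	2912	0	1.1429	0.001558	0.001363	103874.2
BnRH-064	2	2633	5008	2375	BnRH-076	2	2633	5008	2375	0	0	0	1E-10	0.007622
BnRH-055	3	655559	656710	1151	BnRH-067	5	1522842	1525636	2794	0	0.9334	0.3113	0.3336	25426829
BnRH-068	5	1978	4329	2351	BnRH-056	3	314013	315563	1550	0	0.9634	0.3171	0.3291	25083841
BnRH-078	2	2633	5008	2375	BnRH-054	3	655559	656710	1151	0	1.0013	0.298	0.2976	22682927
BnRH-057	3	153299	156485	3186	BnRH-071	2	1036267	1040371	4104	0	0.8342	0.1178	0.1412	10762195
BnRH-079	8	240734	242806	2072	BnRH-051	3	896803	898879	2076	0	1.0233	0.043114	0.042132	3211308
BnRH-090	5	451258	452136	878	BnRH-094	5	1247232	1248941	1709	0	1.0508	0.3283	0.3124	23810976
BnRH-098	1	10280	12945	2665	BnRH-106	5	200412	202272	1860	0	0.9622	0.1644	0.1709	13025915
BnRH-109	1	43353	45903	2550	BnRH-108	1	43353	45903	2550	0	0.288	0.000399	0.001387	105708.1
BnRH-103	4	68703	70360	1657	BnRH-107	5	200412	202272	1860	0	1.0846	0.3594	0.3313	25251524
BnRH-095	5	1248996	1250125	1129	BnRH-085	8	22190	25263	3073	0	1.2089	0.2711	0.2243	17096037
BnRH-105	5	200412	202272	1860	BnRH-091	3	498725	502353	3628	0	0.9408	0.3901	0.4147	31608232
BnRH-116	2	1146345	1150499	4154	BnRH-115	2	1146345	1150499	4154	0	0.5305	0.00053	0.000323	24590.7
BnRH-114	1	472691	474941	2250	BnRH-111	6	1333558	1338750	5192	0	0.9256	0.2283	0.2466	18795732
BnRH-126	8	239870	242806	2936	BnRH-112	9	1343959	1345272	1313	0	0.5712	0.037246	0.065207	4970027
BnRH-132	3	341531	342724	1193	BnRH-124	5	2024226	2028422	4196	0	0.9749	0.4566	0.4684	35701220
BnRH-133	4	541313	545395	4082	BnRH-110	6	1333558	1338750	5192	0	0.9538	0.3104	0.3254	24801829
BnRH-131	5	451258	452136	878	BnRH-130	5	451258	452136	878	0	0.4357	0.000436	1E-10	0.007622
BnRH-127	6	267642	269831	2189	BnRH-120	7	1364611	1367004	2393	0	1.149	0.3859	0.3358	25594512
BnRH-121	5	11924	14339	2415	BnRH-118	5	11939	13951	2012	0	1.659	0.008056	0.004856	370086.9
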