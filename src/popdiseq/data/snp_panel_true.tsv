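snp_id	chromosome	position_bp	bin
PUT-163a-91054912-4739	NA	NA	NA
PUT-163a-16922676-1070	NA	NA	NA
SYN6001	1	2208377	1.01
SYN27251	1	2432669	1.01
PUT-163a-5499487-2275	1	2536526	1.01
SYN38927	1	2691547	1.01
SYN6413	1	7961412	1.01
PZE-101014003	1	7993526	1.01
PZE-101014266	1	8095694	1.01
SYN11901	1	8510819	1.01
SYN11909	1	8512237	1.01
PZA-000175002	1	8553473	1.01
SYN20196	1	15512478	1.02
PUT-163a-16922676-1073	1	46070067	1.03
SYN11221	1	66980686	1.04
SYN11222	1	66981108	1.04
SYN17701	1	67062198	1.04
PZE-101083826	1	72067065	1.04
SYN38509	1	72105795	1.04
SYN38510	1	72105859	1.04
PZE-101120556	1	148525047	1.05
PZE-101120639	1	148566496	1.05
PZE-101120645	1	148566793	1.05
PZE-101131103	1	168256682	1.05
PZE-101131114	1	168257319	1.05
PZE-101131166	1	168429768	1.05
PZE-101162300	1	205544018	1.07
SYN422	1	236291257	1.08
SYN423	1	236296165	1.08
ZM011097-0676	1	236296417	1.08
SYNGENTA11666	2	205583015	2.08
PZE-102158721	2	206039441	2.08
PUT-163a-148951348-515	3	5789819	3.02
SYNGENTA17024	3	5854017	3.02
PZE-103010658	3	5854416	3.02
SYN33444	3	15137742	3.04
SYN33443	3	15222626	3.04
SYN33442	3	15222864	3.04
PZE-103160210	3	211405876	3.08
PZE-103160218	3	211408703	3.08
PZE-103160227	3	211410592	3.08
SYN33394	3	215456783	3.08
PZE-103165953	3	215462316	3.08
PUT-163a-149100944-925	3	215513343	3.08
PZE-104008299	4	5595386	4.02
PZE-104033459	4	41873008	4.05
PZE-104033791	4	42284265	4.05
PZE-104033817	4	42288134	4.05
PZE-104033826	4	42306869	4.05
SYN22745	4	154716125	4.06
PZE-104080384	4	154716758	4.06
SYN509	5	4219552	5.01
SYN524	5	4254273	5.01
SYN526	5	4254700	5.01
PZE-105018859	5	8560599	5.02
SYN4651	6	147905068	6.05
SYN4646	6	147909387	6.05
SYN4642	6	147909507	6.05
PZE-106100715	6	153502018	6.05
PZE-106100720	6	153502756	6.05
PZE-106100728	6	153508407	6.05
PZE-106115889	6	161854167	6.07
PZE-106116148	6	161924948	6.07
PZE-106116156	6	161990361	6.07
SYN12692	6	164180276	6.07
PZA02688.2	6	164183687	6.07
SYN12698	6	164186726	6.07
PZE-107083430	7	125723001	7.02
PZE-107083429	7	125723685	7.02
PZE-107105783	7	157912189	7.04
SYN36108	7	157914433	7.04
PZE-107105855	7	157934803	7.04
PZE-108004863	8	4967925	8.01
PZE-108004875	8	4969812	8.01
PZE-108004908	8	5025189	8.01
PZE-108052599	8	92730672	8.03
PZE-108052600	8	92730702	8.03
PZE-108052603	8	92732462	8.03
PZE-108134983	8	173931575	8.09
SYN20808	8	173953651	8.09
SYN20806	8	173973257	8.09
PZE-108135203	8	174257043	8.09
SYN17231	10	4990421	10.01
SYN17233	10	4992947	10.01
PZE-110006423	10	4993061	10.01
PZE-110007091	10	5485252	10.02
PZE-110007194	10	5537112	10.02
SYN16757	10	5592617	10.02
PZE-110012640	10	11088851	10.02
PZE-110012671	10	11184622	10.02
PZE-110012682	10	11195007	10.02
PZE-110045755	10	86439624	10.03
SYN37480	10	86528026	10.03
SYN16982	10	114875299	10.04
SYN16979	10	114876217	10.04
PZE-110060686	10	114892724	10.04
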