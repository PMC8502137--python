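# Synthetic ~200-gene model (approximate coordinates, for simulation); regenerate with `python -m gcsubtype.resources`.
gene	chrom	start	end	coding_length
ARID1A	1	27022522	27108601	6858
GENE155	1	54674486	54852552	1166
GENE001	1	87696631	87918286	529
GENE089	1	103730033	103777251	1253
GENE067	1	119463410	119588111	1540
GENE023	1	126998229	127129797	2350
GENE111	1	147784854	148003022	1049
SPTA1	1	158580496	158656505	7260
GENE045	1	175763813	175944296	619
GENE133	1	190254860	190486181	1677
GENE112	2	62811559	63098975	1994
GENE090	2	100115354	100165046	948
GENE002	2	105446272	105523429	2278
GENE156	2	113154457	113328555	2784
GENE024	2	138395535	138574999	359
LRP1B	2	140988996	142889270	13800
GENE134	2	152724015	152932249	968
GENE046	2	162708843	162906478	946
TTN	2	179390716	179695529	100000
GENE068	2	182679422	182841448	1973
FSIP2	2	186602934	186680898	20000
ITGAV	2	187454792	187545420	3144
GENE113	3	16544994	16653430	1253
MLH1	3	37034841	37107338	2271
GENE003	3	38909881	39184671	1167
CTNNB1	3	41236328	41301587	2346
GENE069	3	43726641	43888108	3748
RHOA	3	49396578	49412998	582
GENE135	3	76562806	76698374	2544
GENE025	3	80596438	80868541	1244
GENE091	3	101072483	101221234	1542
GENE047	3	108241948	108418487	575
GENE157	3	163031299	163294186	3264
PIK3CA	3	178866311	178957881	3207
MUC4	3	195473637	195538844	16000
GENE026	4	20091530	20117115	4702
GENE048	4	31447123	31574519	1634
GENE136	4	80799213	80907142	1478
GENE158	4	116358121	116582781	1643
FAT4	4	126237554	126414087	14946
GENE070	4	157879040	157901694	3848
GENE092	4	160891534	161119985	917
GENE004	4	170840138	171128827	3023
GENE114	4	194435666	194729620	1141
GENE071	5	9951132	10058986	2714
GENE005	5	12387250	12586288	2323
GENE115	5	52435867	52636115	1815
GENE049	5	64387501	64663375	597
GENE093	5	99371396	99501926	1358
GENE027	5	107090216	107346677	1630
APC	5	112043195	112181936	8532
GENE137	5	133309908	133544279	1323
GENE159	5	156520793	156543818	1068
CCND3	6	41902671	42018922	879
VEGFA	6	43737946	43754224	1239
HSP90AB1	6	44214824	44221613	2175
GENE116	6	48030913	48105264	621
GENE050	6	84394557	84476965	819
GENE028	6	104759718	104948384	4038
GENE072	6	108088399	108249007	1141
GENE006	6	145392567	145514397	1521
GENE138	6	146691277	146768392	851
SYNE1	6	152442819	152958936	26000
GENE094	6	153447729	153741893	1347
GENE160	6	168174690	168325406	1019
GENE073	7	44765360	44943421	1407
GENE051	7	47019858	47156573	1192
GENE139	7	51333263	51458846	738
EGFR	7	55086725	55324313	3633
GENE007	7	93080085	93189010	2993
GENE095	7	117528076	117557600	2433
GENE117	7	130075893	130108488	1714
KMT2C	7	151832010	152133090	14736
GENE029	7	161540835	161606015	1349
GENE052	8	25977541	26126443	1215
GENE140	8	35670297	35715628	1336
GENE096	8	59602267	59814494	819
PREX2	8	68864353	69149263	4824
CSMD3	8	113235157	114449328	11000
MYC	8	128748315	128753680	1320
GENE118	8	131932979	132065020	767
GENE074	8	140567047	140844392	1741
GENE008	8	164564276	164730346	1458
GENE030	8	197792728	197881476	661
CDKN2A	9	21967751	21995300	471
GENE075	9	27619289	27772252	521
GENE009	9	48913530	48993492	975
GENE097	9	53586018	53828079	960
GENE031	9	107420815	107697831	1531
GENE053	9	128780336	128861429	864
NOTCH1	9	139388896	139440314	7668
GENE141	9	152828780	153053169	655
GENE119	9	195760510	195905217	2632
GENE076	10	13092670	13310183	2763
GENE054	10	23519711	23542873	964
PTEN	10	89623195	89728532	1212
GENE120	10	91926710	92138858	550
GENE010	10	121637227	121866180	1926
GENE142	10	141152607	141228621	1750
GENE098	10	150237674	150274778	1555
GENE032	10	158183798	158271403	4064
GENE077	11	50969014	51160910	1985
CCND1	11	69455873	69469242	888
GENE055	11	80740632	80839757	473
GENE011	11	86609807	86705271	930
FAT3	11	92085262	92629618	13700
GENE099	11	95773825	95967795	1070
GENE033	11	119445879	119655991	1252
GENE143	11	134191826	134486076	2450
GENE121	11	151979726	152090365	4911
KRAS	12	25358180	25403870	570
KMT2D	12	49412758	49453557	16614
GENE100	12	52673875	52706946	4540
CDK4	12	58141510	58149796	912
MDM2	12	69201956	69239214	1494
TRHDE	12	72666074	73059422	3060
GENE034	12	72835569	72953175	1979
GENE144	12	93416477	93586609	770
GENE012	12	118902480	119085575	1371
GENE078	12	120543832	120659245	1408
GENE122	12	151662396	151784497	996
GENE056	12	159640667	159830573	845
GENE035	13	45546250	45846039	961
GENE145	13	54593439	54816467	4132
GENE123	13	113453807	113588606	3248
GENE079	13	149310152	149542557	572
GENE057	13	151434240	151472491	970
GENE013	13	156165669	156262077	1767
GENE101	13	176286071	176479351	1193
GENE124	14	4228019	4472700	3522
GENE014	14	14200409	14235827	2772
GENE036	14	63119238	63400703	2285
GENE080	14	93465638	93598743	3380
GENE146	14	106509778	106775806	1038
GENE102	14	138603227	138715539	999
GENE058	14	140434839	140548473	4104
GENE059	15	32093168	32144418	738
GENE125	15	35797921	35842633	3427
GENE015	15	36808389	36836314	3198
GENE103	15	66321546	66481726	1139
GENE081	15	66497674	66684763	1209
GENE037	15	67290485	67327292	1524
GENE147	15	121484133	121574312	2225
CDH1	16	68771195	68869444	2649
GENE060	16	72616993	72650491	2118
PIEZO1	16	88776541	88851260	7566
GENE148	16	141274232	141329432	1577
GENE104	16	155844724	155933862	757
GENE126	16	178392310	178431281	806
GENE038	16	183606924	183871736	632
GENE016	16	188771605	189046891	1469
GENE082	16	190948504	191126117	1506
TP53	17	7571720	7590868	1182
ERBB2	17	37844393	37884915	3768
BRCA1	17	41196312	41277500	5592
GENE127	17	52776923	52901189	1096
GENE039	17	89890444	90013728	543
GENE061	17	96210297	96379141	857
GENE017	17	132779725	132991838	4606
GENE083	17	143513814	143718069	897
GENE149	17	147784846	147982651	1870
GENE105	17	167734175	167942843	1692
GENE018	18	4587110	4669595	1898
GENE062	18	22841496	23066842	2058
GENE128	18	37877004	38075363	1100
SMAD4	18	48556583	48611411	1659
GENE040	18	57611261	57821922	1288
GENE084	18	87150460	87412211	572
GENE150	18	93843353	93926599	3022
GENE106	18	131302871	131417530	1395
SMARCA4	19	11071598	11176958	4944
CCNE1	19	30302805	30315215	1233
GENE107	19	45661140	45774568	3127
GENE019	19	62430139	62673586	1806
GENE085	19	132120597	132265919	588
GENE063	19	133318437	133616822	4471
GENE151	19	137285548	137339906	4835
GENE041	19	193119226	193298871	1610
GENE129	19	198325892	198495322	767
GENE086	20	17655402	17950089	3267
GENE020	20	52353236	52542697	2810
GENE108	20	103283552	103413276	3374
GENE152	20	125148534	125266662	1328
GENE042	20	136622490	136697328	3442
GENE130	20	152135827	152188983	3279
GENE064	20	163976928	164131796	1810
GENE043	21	28953453	29237246	6863
GENE109	21	61316753	61398624	1155
GENE087	21	64404655	64437084	2178
GENE021	21	110407357	110578804	2197
GENE153	21	128350777	128454676	1608
GENE065	21	132791698	132947991	630
GENE131	21	197136260	197429814	4287
GENE110	22	2740336	2860481	4011
GENE022	22	27083008	27138761	649
GENE132	22	44701325	44942951	1531
GENE088	22	73320937	73507426	1137
GENE066	22	95746667	95918905	522
GENE044	22	186170668	186447937	773
GENE154	22	193828289	193910255	1197
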