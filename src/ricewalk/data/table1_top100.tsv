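rank	gene	p_score	pmids	reconstructed
1	LOC_Os06g09390	0.001487617	20713616;27555860	0
2	LOC_Os06g50480	0.001475286		0
3	LOC_Os02g02480	0.00146746		0
4	LOC_Os08g42470	0.001461294		0
5	LOC_Os01g03340	0.000941415		0
6	LOC_Os01g03390	0.00080268	12972663	0
7	LOC_Os01g04040	0.00080268		0
8	LOC_Os01g04050	0.00080268		0
9	LOC_Os07g02350	0.000775571	16240106;11416158	0
10	LOC_Os08g02640	0.000669873		0
11	LOC_Os04g37619	0.000640376	24634194	0
12	LOC_Os11g35500	0.00062345	29813124;29402905	0
13	LOC_Os05g41970	0.000594578	1731968	0
14	LOC_Os12g16890	0.000594578		0
15	LOC_Os01g03680	0.000584668		0
16	LOC_Os07g10580	0.000564849	28158863;22108719	0
17	LOC_Os06g50340	0.000561268	19704753;16511358	0
18	LOC_Os10g14150	0.000555163	19201764	0
19	LOC_Os01g55540	0.000551598	15753104	0
20	LOC_Os10g22860	0.00054974	23384860;28101092	0
21	LOC_Os10g32990	0.000547737	23384860;28101092	0
22	LOC_Osm1g00450	0.000540982		0
23	LOC_Os01g60670	0.000536737		0
24	LOC_Os07g11410	0.00053512		0
25	LOC_Os01g13800	0.000533159		0
26	LOC_Os02g13780	0.000533159		0
27	LOC_Os10g06760	0.000533159	23384860;28101092	0
28	LOC_Os10g13970	0.000533159	23384860;28101092	0
29	LOC_Os10g19160	0.000533159	23384860;28101092	0
30	LOC_Os02g57530	0.000532385	14754915	0
31	LOC_Os10g21810	0.000529529		0
32	LOC_Os01g47730	0.000507068		0
33	LOC_Os07g11920	0.000505391	28158863;22108719	0
34	LOC_Os01g07870	0.00049357		0
35	LOC_Os03g54790	0.000492652		0
36	LOC_Os01g18670	0.000492651		0
37	LOC_Os07g42300	0.000483507	24466124	0
38	LOC_Os11g10100	0.000478643		0
39	LOC_Os11g40150	0.000478361	28071676	0
40	LOC_Os12g31370	0.000478361	28071676	0
41	LOC_Os03g05740	0.000472443		0
42	LOC_Os08g38720	0.000468006		0
43	LOC_Os03g50330	0.000462237		0
44	LOC_Os04g08740	0.000461766	19417056	0
45	LOC_Os01g42650	0.000461755	16263700	0
46	LOC_Os03g27290	0.000460621	19217306;15672456	0
47	LOC_Os10g39670	0.000460227		0
48	LOC_Os01g65230	0.000459159		0
49	LOC_Os03g54780	0.000456546		0
50	LOC_Os08g03640	0.000456163		0
51	LOC_Os01g14830	0.000454589		0
52	LOC_Os01g10820	0.000453601		0
53	LOC_Os10g42110	0.000449388		0
54	LOC_Os03g26860	0.000448345		0
55	LOC_Os07g41750	0.000448221		0
56	LOC_Os03g17580	0.000448145		0
57	LOC_Os10g42940	0.000447386	24715026;10873582	0
58	LOC_Os03g03570	0.000446501	10364408	0
59	LOC_Os12g43550	0.000445728		0
60	LOC_Os03g49500	0.000444206	29767552	0
61	LOC_Os10g04674	0.000442469	24145853;17986178	0
62	LOC_Os10g06740	0.000442469	28154240	0
63	LOC_Os01g05980	0.000442411		0
64	LOC_Os10g33650	0.000440094		0
65	LOC_Os01g18150	0.000438562		0
66	LOC_Os01g22490	0.000436139		0
67	LOC_Os02g18550	0.000436139		0
68	SYNTHETIC_RANK_068	0.000434987	NA	1
69	SYNTHETIC_RANK_069	0.000433835	NA	1
70	SYNTHETIC_RANK_070	0.000432683		1
71	SYNTHETIC_RANK_071	0.000431531	NA	1
72	SYNTHETIC_RANK_072	0.000430379	NA	1
73	SYNTHETIC_RANK_073	0.000429227	NA	1
74	SYNTHETIC_RANK_074	0.000428075		1
75	SYNTHETIC_RANK_075	0.000426923		1
76	SYNTHETIC_RANK_076	0.000425771		1
77	SYNTHETIC_RANK_077	0.000424619		1
78	SYNTHETIC_RANK_078	0.000423467		1
79	SYNTHETIC_RANK_079	0.000422315		1
80	SYNTHETIC_RANK_080	0.000421163		1
81	SYNTHETIC_RANK_081	0.000420011	NA	1
82	SYNTHETIC_RANK_082	0.000418859	NA	1
83	SYNTHETIC_RANK_083	0.000417707	NA	1
84	SYNTHETIC_RANK_084	0.000416555	NA	1
85	SYNTHETIC_RANK_085	0.000415403	NA	1
86	SYNTHETIC_RANK_086	0.000414251	NA	1
87	SYNTHETIC_RANK_087	0.000413099		1
88	SYNTHETIC_RANK_088	0.000411947		1
89	SYNTHETIC_RANK_089	0.000410795		1
90	SYNTHETIC_RANK_090	0.000409643		1
91	LOC_Os05g50930	0.000408491		0
92	LOC_Os10g39440	0.000408336	24372780;18335199	0
93	LOC_Os08g06630	0.000407594		0
94	LOC_Osp1g00820	0.000407028	25658309	0
95	LOC_Osp1g01050	0.000407028	25658309	0
96	LOC_Osp1g00420	0.00040642	25658309	0
97	LOC_Os05g49320	0.000404017		0
98	LOC_Os12g07720	0.000400566	14756303	0
99	LOC_Os10g06930	0.000399998	29356995	0
100	LOC_Os03g06410	0.000399411	1731968	0
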