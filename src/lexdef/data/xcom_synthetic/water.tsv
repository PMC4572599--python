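# Synthetic XCOM-style mass attenuation table (cm^2/g);
# reconstructed from standard parametrizations, not a
# verbatim database export. See scripts/build_attenuation_tables.py
energy_keV	pe	coherent	incoherent	pair	total
10	4.94	0.27	0.119	0	5.329
11	3.65422	0.233877	0.170475	0	4.05857
12	2.775	0.205135	0.185049	0	3.16519
12.5	2.43885	0.192896	0.18497	0	2.81671
13	2.15429	0.181826	0.181979	0	2.5181
13.6	1.86776	0.169874	0.175879	0	2.21351
14.5	1.52508	0.154237	0.163851	0	1.84317
15	1.37	0.146555	0.156445	0	1.673
16	1.11361	0.132973	0.17502	0	1.4216
18	0.762966	0.111347	0.181819	0	1.05613
20	0.544	0.095	0.1706	0	0.8096
25	0.2687	0.0652466	0.19658	0	0.530527
30	0.151	0.048	0.1766	0	0.3756
35	0.0901786	0.0373135	0.186152	0	0.313644
40	0.0577	0.03	0.1806	0	0.2683
45	0.0387201	0.0238912	0.182973	0	0.245585
50	0.0271	0.0194888	0.180311	0	0.2269
55	0.0191876	0.0162095	0.180271	0	0.215668
60	0.014	0.0137	0.1782	0	0.2059
65	0.0108061	0.0118768	0.176784	0	0.199467
70	0.00850254	0.0104059	0.174782	0	0.19369
75	0.00680166	0.0092007	0.17246	0	0.188462
80	0.00552	0.0082	0.16998	0	0.1837
85	0.00452689	0.00735682	0.168189	0	0.180073
90	0.00375478	0.00664141	0.166323	0	0.176719
95	0.00314603	0.00602883	0.16443	0	0.173604
100	0.00266	0.0055	0.16254	0	0.1707
110	0.00195646	0.00461185	0.159152	0	0.16572
120	0.00147801	0.00392688	0.155897	0	0.161302
130	0.00114193	0.00338698	0.152812	0	0.157341
140	0.000899301	0.00295353	0.149907	0	0.15376
150	0.00072	0.0026	0.14718	0	0.1505
160	0.000587128	0.00229817	0.144475	0	0.14736
180	0.000404612	0.00183476	0.139558	0	0.141798
200	0.00029	0.0015	0.13521	0	0.137
250	0.000144707	0.000980154	0.125421	0	0.126546
300	8.2e-05	0.000692316	0.117826	0	0.1186
350	5.11617e-05	0.000515994	0.111162	0	0.111729
400	3.4e-05	0.0004	0.105666	0	0.1061
450	2.39458e-05	0.000317302	0.100799	0	0.10114
500	1.75e-05	0.000257926	0.0966246	0	0.0969
600	1.02e-05	0.000180215	0.0894096	0	0.0896
800	4.7e-06	0.000102355	0.0784929	0	0.0786
1000	2.7e-06	6.6e-05	0.0706313	0	0.0707
1022	2.56844e-06	6.32559e-05	0.0698652	0	0.069931
1250	1.61775e-06	4.27002e-05	0.0631007	5.5e-05	0.0632
1500	1.06452e-06	2.99166e-05	0.057299	0.00017	0.0575
2000	5.5e-07	1.70649e-05	0.0489824	0.0004	0.0494
2500	3.40396e-07	1.10405e-05	0.0433906	0.000697979	0.0441
3000	2.3e-07	7.7352e-06	0.038592	0.0011	0.0397
4000	1.31681e-07	4.41226e-06	0.0321955	0.0018	0.034
5000	8.54382e-08	2.85461e-06	0.0277971	0.0025	0.0303
6000	6e-08	2e-06	0.0245979	0.0031	0.0277
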