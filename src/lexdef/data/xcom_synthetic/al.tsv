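# Synthetic XCOM-style mass attenuation table (cm^2/g);
# reconstructed from standard parametrizations, not a
# verbatim database export. See scripts/build_attenuation_tables.py
energy_keV	pe	coherent	incoherent	pair	total
10	25.4	0.52	0.31	0	26.23
11	19.05	0.444074	0.321142	0	19.8152
12	14.6499	0.384482	0.304878	0	15.3392
12.5	12.9515	0.359349	0.292144	0	13.603
13	11.5056	0.33675	0.278006	0	12.1203
13.6	10.0406	0.312505	0.260235	0	10.6134
14.5	8.27487	0.281042	0.233588	0	8.7895
15	7.47	0.265698	0.219302	0	7.955
16	6.09656	0.238765	0.256271	0	6.59159
18	4.20779	0.196454	0.272889	0	4.67713
20	3.02	0.165	0.256	0	3.441
25	1.50993	0.112295	0.240349	0	1.86257
30	0.857	0.082	0.189	0	1.128
35	0.526715	0.0629061	0.191747	0	0.781368
40	0.3455	0.05	0.173	0	0.5685
45	0.23894	0.0403993	0.172614	0	0.451954
50	0.1718	0.0333845	0.162916	0	0.3681
55	0.126872	0.0280941	0.16277	0	0.317737
60	0.0962	0.024	0.1576	0	0.2778
65	0.074562	0.0206869	0.158913	0	0.254162
70	0.0588932	0.0180287	0.157152	0	0.234073
75	0.0472807	0.0158619	0.153659	0	0.216801
80	0.0385	0.0140714	0.149229	0	0.2018
85	0.0318238	0.012574	0.148339	0	0.192737
90	0.0265934	0.0113085	0.146664	0	0.184566
95	0.0224394	0.0102288	0.144487	0	0.177155
100	0.0191	0.0093	0.142	0	0.1704
110	0.0141928	0.00771958	0.140191	0	0.162103
120	0.0108226	0.00651249	0.137547	0	0.154882
130	0.00843384	0.00556949	0.134521	0	0.148524
140	0.00669497	0.00481859	0.131356	0	0.14287
150	0.0054	0.00421081	0.128189	0	0.1378
160	0.0044282	0.00371187	0.12602	0	0.13416
180	0.003083	0.0029487	0.121732	0	0.127763
200	0.00223	0.0024	0.11767	0	0.1223
250	0.00111221	0.00156032	0.109309	0	0.111981
300	0.00063	0.00109755	0.102472	0	0.1042
350	0.000392087	0.000815159	0.0966637	0	0.0978709
400	0.00026	0.00063	0.09181	0	0.0927
450	0.000183963	0.000497268	0.0875408	0	0.0882221
500	0.000135	0.000402418	0.0838626	0	0.0844
600	8.37695e-05	0.000279014	0.0775372	0	0.0779
800	3.94524e-05	0.000156553	0.068104	0	0.0683
1000	2.2e-05	0.0001	0.061278	0	0.0614
1022	2.10583e-05	9.58306e-05	0.0606275	0	0.0607444
1250	1.40479e-05	6.46164e-05	0.0548273	9.4e-05	0.055
1500	9.73726e-06	4.52253e-05	0.049655	0.00029	0.05
2000	5.4611e-06	2.57555e-05	0.0424888	0.00068	0.0432
2500	3.48712e-06	1.66423e-05	0.0376933	0.00118656	0.0389
3000	2.4171e-06	1.1648e-05	0.0334159	0.00187	0.0353
4000	1.35562e-06	6.63346e-06	0.027892	0.0031	0.031
5000	8.65615e-07	4.2863e-06	0.0241948	0.0042	0.0284
6000	6e-07	3e-06	0.0212964	0.0053	0.0266
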