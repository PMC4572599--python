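# Synthetic XCOM-style mass attenuation table (cm^2/g);
# reconstructed from standard parametrizations, not a
# verbatim database export. See scripts/build_attenuation_tables.py
energy_keV	pe	coherent	incoherent	pair	total
10	208	4.2	3.7	0	215.9
11	159.373	3.79265	4.71943	0	167.885
12	124.979	3.45537	5.00514	0	133.439
12.5	111.507	3.30764	4.99569	0	119.81
13	99.9338	3.17165	4.92382	0	108.029
13.6	88.0975	3.02211	4.78207	0	95.9017
14.5	73.6564	2.82178	4.50251	0	80.9807
15	67	2.72122	4.32878	0	74.05
16	56.239	2.53958	3.32033	0	62.0989
18	40.8574	2.23876	1.94192	0	45.038
20	30.7	2	1.09	0	33.79
25	16.1916	1.47491	0.480719	0	18.1472
30	9.6	1.15	0.17	0	10.92
35	6.12501	0.90144	0.0517887	0	7.07824
40	4.15	0.73	0.0263778	0	4.90638
45	2.89667	0.59448	0.0277509	0	3.5189
50	2.1	0.494718	0.028741	0	2.62346
55	1.56052	0.418975	0.0378787	0	2.01737
60	1.19	0.36	0.043	0	1.593
65	0.924353	0.31418	0.059444	0	1.29798
70	0.731583	0.276973	0.0652194	0	1.07378
75	0.588437	0.246306	0.0652601	0	0.900003
80	0.48	0.220701	0.0622993	0	0.763
85	0.397609	0.199078	0.0676775	0	0.664364
90	0.332925	0.180635	0.0695154	0	0.583076
95	0.281454	0.164765	0.0691391	0	0.515359
100	0.24	0.151	0.0674	0	0.4584
110	0.179649	0.127048	0.0797471	0	0.386444
120	0.137909	0.108515	0.0842398	0	0.330664
130	0.108132	0.0938633	0.0844932	0	0.286489
140	0.086328	0.0820677	0.0824732	0	0.250869
150	0.07	0.0724227	0.0792773	0	0.2217
160	0.0576645	0.0644292	0.0827675	0	0.204861
180	0.0404821	0.052046	0.0848301	0	0.177358
200	0.0295	0.043	0.0834	0	0.1559
250	0.0148736	0.028124	0.0868961	0	0.129894
300	0.0085	0.0198801	0.0835199	0	0.1119
350	0.00536401	0.0148265	0.0822528	0	0.102443
400	0.0036	0.0115	0.0798	0	0.0949
450	0.00256923	0.00912398	0.07712	0	0.0888132
500	0.0019	0.00741774	0.0743823	0	0.0837
600	0.0011989	0.0051842	0.0698169	0	0.0762
800	0.000579771	0.00294564	0.0623746	0	0.0659
1000	0.00033	0.0019	0.05667	0	0.0589
1022	0.000317289	0.00182192	0.0561576	0	0.0582968
1250	0.000220592	0.00123558	0.0513438	0.0002	0.053
1500	0.000158733	0.000869312	0.047062	0.00061	0.0487
2000	9.44391e-05	0.000499162	0.0411664	0.00144	0.0432
2500	6.31289e-05	0.000324607	0.0369995	0.00251272	0.0399
3000	4.54261e-05	0.000228383	0.0335662	0.00396	0.0378
4000	2.70265e-05	0.000131138	0.0285418	0.0065	0.0352
5000	1.80662e-05	8.52798e-05	0.0239967	0.009	0.0331
6000	1.3e-05	6e-05	0.020427	0.0112	0.0317
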