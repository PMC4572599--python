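# Synthetic XCOM-style mass attenuation table (cm^2/g);
# reconstructed from standard parametrizations, not a
# verbatim database export. See scripts/build_attenuation_tables.py
# edge: L3 11.564
# edge: L2 13.273
# edge: L1 13.88
# edge: K 78.4
energy_keV	pe	coherent	incoherent	pair	total
10	117.177	2.3	5.1735e-05	0	119.478
11	93.1296	2.09623	0.000149634	0	95.226
11.564	82.557	1.99665	0.000246458	0	84.5539
11.564	181.625	1.99665	0.000246458	0	183.622
12	166.127	1.92601	0.000348282	0	168.053
12.5	150.561	1.85098	0.000499031	0	152.413
13	136.982	1.78165	0.000690842	0	138.764
13.273	130.29	1.74597	0.000814507	0	132.037
13.273	182.406	1.74597	0.000814507	0	184.153
13.6	172.015	1.7051	0.00098137	0	173.721
13.88	163.771	1.67161	0.00114116	0	165.443
13.88	189.974	1.67161	0.00114116	0	191.647
14.5	170.984	1.602	0.00155305	0	172.588
15	157.57	1.55	0.00194566	0	159.122
16	134.873	1.44391	0.00289747	0	136.319
18	101.542	1.26866	0.00545717	0	102.816
20	78.7718	1.13	0.0087953	0	79.9106
25	46.0063	0.847519	0.0193305	0	46.8732
30	29.6477	0.67	0.0308557	0	30.3485
35	19.107	0.544528	0.0417204	0	19.6932
40	13.0592	0.455	0.051266	0	13.5654
45	9.33535	0.386733	0.0593625	0	9.78145
50	6.91388	0.334394	0.066106	0	7.31438
55	5.2693	0.293176	0.0716683	0	5.63414
60	4.11202	0.26	0.076231	0	4.44825
65	3.27328	0.226921	0.0799605	0	3.58016
70	2.65007	0.200059	0.0829995	0	2.93313
75	2.17702	0.177917	0.0854677	0	2.4404
78.4	1.9186	0.165	0.0868708	0	2.17048
78.4	8.25	0.165	0.0868708	0	8.50187
80	7.79785	0.161766	0.0874632	0	8.04708
85	6.58441	0.152438	0.089067	0	6.82592
90	5.61383	0.144136	0.0903448	0	5.84831
95	4.82777	0.1367	0.0913508	0	5.05582
100	4.18404	0.13	0.0921294	0	4.40617
110	3.20708	0.109773	0.0931441	0	3.41
120	2.51582	0.0940678	0.0936124	0	2.7035
130	2.01231	0.0816127	0.0936893	0	2.18761
140	1.63643	0.0715563	0.0934842	0	1.80147
150	1.3499	0.0633111	0.0930751	0	1.50628
160	1.12746	0.0564605	0.0925187	0	1.27644
180	0.811681	0.0458118	0.0911187	0	0.948612
200	0.604954	0.038	0.0895033	0	0.732457
250	0.324596	0.0245646	0.0852051	0	0.434366
300	0.195176	0.0171989	0.0810636	0	0.293439
350	0.126954	0.0127236	0.0772824	0	0.21696
400	0.0874678	0.0098	0.0738802	0	0.171148
450	0.0629699	0.00776334	0.0708242	0	0.141557
500	0.046932	0.00630293	0.0680711	0	0.121306
600	0.0282198	0.00439467	0.0633119	0	0.0959264
800	0.0126466	0.00248773	0.0559474	0	0.0710817
1000	0.00678572	0.0016	0.0504519	0	0.0588376
1022	0.00658927	0.00153405	0.0499286	0	0.058052
1250	0.00502073	0.00103913	0.0452067	0.00047	0.0517365
1500	0.0039253	0.00073032	0.0411347	0.00145	0.0472403
2000	0.00266198	0.000418647	0.0351425	0.0034	0.0416232
2500	0.00196959	0.000271894	0.0308852	0.00595026	0.0390769
3000	0.00153986	0.000191092	0.0276704	0.0094	0.0388014
4000	0.00104427	0.000109541	0.0230867	0.0153	0.0395405
5000	0.000772656	7.11422e-05	0.019939	0.021	0.0417828
6000	0.000604076	5e-05	0.0176235	0.026	0.0442776
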