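subject_id	mse_raw	mse_mean	red_mean_pct	mse_shrinkage	red_shrink_pct
1	0.2183	0.1342	38.50	0.1336	38.36
2	0.1929	0.0981	49.15	0.0975	49.43
3	0.1313	0.0854	34.95	0.0851	35.13
4	0.2520	0.1127	55.25	0.1114	55.78
5	0.2313	0.1137	50.80	0.1125	51.03
6	0.2317	0.1639	29.23	0.1629	29.66
7	0.1440	0.0985	33.45	0.0955	33.68
8	0.2052	0.1082	47.24	0.1081	47.30
9	0.2149	0.1241	42.22	0.1237	42.43
10	0.1725	0.1033	40.06	0.1030	40.26
11	0.4163	0.1572	62.22	0.1570	62.28
12	0.1961	0.0876	55.34	0.0873	55.49
13	0.2199	0.1411	35.83	0.1406	36.03
14	0.2625	0.1566	38.02	0.1553	38.52
15	0.1035	0.0641	38.07	0.0640	38.11
16	0.2858	0.0630	77.93	0.0629	77.99
17	0.1317	0.1157	12.11	0.1151	12.60
18	0.3384	0.1032	69.48	0.1022	69.79
19	0.1861	0.0753	59.49	0.0751	59.62
20	0.2052	0.1372	33.13	0.1366	33.42
21	0.2025	0.1074	46.93	0.1070	47.16
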