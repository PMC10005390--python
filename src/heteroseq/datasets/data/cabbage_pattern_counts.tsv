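hybrid	P1	P2	P3	P4	P5	P6	P7	P8	P9	P10	P11	P12
AE	575	689	806	2139	385	2039	75	4	15	77	15	19
AF	519	427	951	1234	638	1394	233	3	75	99	21	6
AG	386	476	1177	1192	539	1412	60	4	12	116	14	12
AH	477	481	1302	1781	675	1453	67	12	12	174	22	50
BE	771	700	1166	2289	360	1342	28	4	6	90	21	15
BF	399	327	504	1789	312	1613	59	2	24	199	15	9
BG	428	450	996	1162	412	1101	17	1	0	23	1	7
BH	548	468	992	2703	525	1522	71	4	12	127	9	51
CE	376	405	1726	964	1538	801	257	47	15	602	50	124
CF	180	230	1089	712	1399	986	503	22	67	485	30	32
CG	102	132	1510	470	1046	477	255	42	6	380	9	61
CH	196	192	1531	1047	1242	595	292	145	19	524	35	208
DE	623	728	736	1753	342	1966	127	4	28	122	25	7
DF	209	175	881	903	166	667	8	2	4	80	8	5
DG	253	371	1464	910	541	794	28	2	3	116	9	12
DH	366	380	1462	1203	591	774	59	7	9	147	10	36
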